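"""The synthetic generators: planted structure, moments, and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistranskit.config import REGULATION_CLASSES, SimulationConfig
from cistranskit import simulate as sim


# ---------------------------------------------------------------- genomes

def test_variant_count_within_poisson_interval():
    cfg = SimulationConfig(seed=123)  # density 1/150 over 100 kb
    _, variants = sim.simulate_strain_genomes(cfg)
    lam = cfg.snp_density * cfg.genome_length
    lo, hi = stats.poisson.interval(0.99, lam)
    # non-overlap thinning removes a few percent of anchors, so allow the
    # same relative loss below the Poisson floor
    for vt in variants.values():
        assert 0.9 * lo <= len(vt) <= hi


def test_indel_fraction_and_alphabet():
    cfg = SimulationConfig(seed=5)
    _, variants = sim.simulate_strain_genomes(cfg)
    vt = variants["strainA"].df
    is_indel = (vt["ref"].str.len() > 1) | (vt["alt"].str.len() > 1)
    # 10% planted; binomial noise around it
    assert 0.05 < is_indel.mean() < 0.16
    assert vt["ref"].str.fullmatch("[ACGT]+").all()
    assert vt["alt"].str.fullmatch("[ACGT]+").all()
    assert (vt["alt"].str.len() <= cfg.max_indel_len + 1).all()


def test_zero_density_yields_empty_tables_and_low_density_raises():
    cfg = SimulationConfig(snp_density=0.0, seed=1)
    _, variants = sim.simulate_strain_genomes(cfg)
    assert all(len(vt) == 0 for vt in variants.values())
    with pytest.raises(ValueError, match="no variants"):
        sim.simulate_strain_genomes(SimulationConfig(snp_density=1e-9, seed=1))


# ------------------------------------------------------------------ reads

def test_spanning_fraction_matches_binomial_expectation():
    """With variants in one strain only and no indels, the chance that a 40-bp
    read is discriminable is 1 - (1 - density)^40 (about 0.235 at 1/150)."""
    cfg = SimulationConfig(indel_fraction=0.0, seed=17)
    reference, variants = sim.simulate_strain_genomes(cfg)
    from cistranskit.genome import VariantTable

    single = {"strainA": variants["strainA"], "strainB": VariantTable()}
    features = sim.simulate_features(cfg)
    reads, _, _ = sim.simulate_reads(reference, single, features, cfg, n_reads=10_000)
    # oracle from the realized variant count rather than the nominal density
    density = len(single["strainA"]) / cfg.genome_length
    expected = 1.0 - (1.0 - density) ** cfg.read_length
    assert expected == pytest.approx(1 - (149 / 150) ** 40, abs=0.03)
    observed = reads["spans_variant"].mean()
    margin = 4 * np.sqrt(expected * (1 - expected) / len(reads)) + 0.01
    assert abs(observed - expected) < margin


def test_reads_match_their_source_haplotype(genome_bundle):
    cfg = genome_bundle["config"]
    features = sim.simulate_features(cfg)
    reads, genomes, _ = sim.simulate_reads(
        genome_bundle["reference"], genome_bundle["variants"], features, cfg, n_reads=300
    )
    for _, row in reads.iterrows():
        seq = genomes[row["strain"]]["chr1"]
        s = int(row["strain_start"])
        assert seq[s : s + cfg.read_length] == row["seq"]


def test_error_rate_perturbs_reported_sequence_only():
    cfg = SimulationConfig(genome_length=20_000, n_features=20, error_rate=0.05, seed=9)
    reference, variants = sim.simulate_strain_genomes(cfg)
    features = sim.simulate_features(cfg)
    reads, genomes, _ = sim.simulate_reads(reference, variants, features, cfg, n_reads=500)
    mismatch = 0
    total = 0
    for _, row in reads.iterrows():
        true = genomes[row["strain"]]["chr1"][
            int(row["strain_start"]) : int(row["strain_start"]) + cfg.read_length
        ]
        mismatch += sum(a != b for a, b in zip(true, row["seq"]))
        total += cfg.read_length
    assert 0.03 < mismatch / total < 0.07


# ------------------------------------------------------------------ counts

def test_truth_table_partitions_features_exactly():
    cfg = SimulationConfig(n_features=203, seed=2)
    truth = sim.make_truth_table(cfg)
    assert len(truth) == 203
    counts = truth["true_class"].value_counts()
    assert set(counts.index) <= set(REGULATION_CLASSES)
    assert counts.sum() == 203
    for c in REGULATION_CLASSES:
        assert abs(counts.get(c, 0) - 203 * 0.2) <= 1
    assert (truth.loc[truth["true_class"] == "same", "true_direction"] == "none").all()


def test_design_counts_realize_class_bias_semantics():
    cfg = SimulationConfig(n_features=400, n_replicates=6, seed=4)
    truth = sim.make_truth_table(cfg)
    counts, design = sim.simulate_design_counts(truth, cfg)
    truth = truth.set_index("feature_id")

    def group_lfc(arm, cls):
        d = design[design["arm"] == arm]
        a = counts.loc[:, d[d["strain_or_allele"] == "A"]["sample"]].mean(axis=1)
        b = counts.loc[:, d[d["strain_or_allele"] == "B"]["sample"]].mean(axis=1)
        mask = truth["true_class"] == cls
        favored_a = truth["true_direction"] == "A"
        lfc = np.log2(a / b)
        oriented = np.where(favored_a, lfc, -lfc)
        return float(np.mean(oriented[mask.to_numpy()]))

    f = cfg.effect_log2fc
    # cis carries the effect in every arm; trans_environmental only in F0;
    # mixed only in the allelic arms; same nowhere
    assert group_lfc("F0", "cis") == pytest.approx(f, abs=0.3)
    assert group_lfc("F1_allele", "cis") == pytest.approx(f, abs=0.3)
    assert group_lfc("F0", "trans_environmental") == pytest.approx(f, abs=0.3)
    assert group_lfc("F0_NSG", "trans_environmental") == pytest.approx(0, abs=0.3)
    assert group_lfc("F0_NSG", "trans_cellautonomous") == pytest.approx(f, abs=0.3)
    assert group_lfc("F1_NSG_allele", "trans_cellautonomous") == pytest.approx(0, abs=0.3)
    assert group_lfc("F0", "mixed") == pytest.approx(0, abs=0.3)
    assert group_lfc("F1_allele", "mixed") == pytest.approx(f, abs=0.3)
    assert group_lfc("F0", "same") == pytest.approx(0, abs=0.3)


def test_nb_draw_moments():
    rng = np.random.default_rng(12)
    mu, alpha = 200.0, 0.1
    x = sim.nb_draw(rng, np.full(20_000, mu), alpha)
    assert np.isclose(x.mean(), mu, rtol=0.02)
    assert np.isclose(x.var(), mu + alpha * mu**2, rtol=0.1)
    y = sim.nb_draw(rng, np.full(20_000, mu), 0.0)
    assert np.isclose(y.var(), mu, rtol=0.1)


# ------------------------------------------------------------------ LPS arms

def test_lps_truth_composition():
    cfg = SimulationConfig(seed=13)
    truth = sim.make_lps_truth(2000, cfg)
    resp = truth["responsive_strain"]
    specific = resp.isin(["A", "B"]).mean()
    assert 0.25 < specific < 0.35
    assert 0.06 < (resp == "both").mean() < 0.14
    cats = truth.loc[resp.isin(["A", "B"]), "basal_category"]
    assert set(cats) == {"low_basal", "equal_basal", "high_basal"}
    regs = truth.loc[resp.isin(["A", "B"]), "reg_class"]
    assert set(regs) == {"cis", "trans"}
    # planted dependence: cis is common at low basal, rare at high basal
    p_cis = truth[resp.isin(["A", "B"])].groupby("basal_category")["reg_class"].apply(
        lambda s: (s == "cis").mean()
    )
    assert p_cis["low_basal"] > p_cis["equal_basal"] > p_cis["high_basal"]


def test_lps_archetype_means():
    cfg = SimulationConfig(seed=14, n_replicates=8)
    truth = sim.make_lps_truth(600, cfg)
    counts, design = sim.simulate_lps_counts(truth, cfg)
    truth = truth.set_index("feature_id")
    mu0, F = cfg.mean_depth, 2.0 ** cfg.effect_log2fc

    def mean_of(strain, treat, mask):
        d = design[(design["arm"] == "F0") & (design["strain_or_allele"] == strain) & (design["treatment"] == treat)]
        return float(counts.loc[mask, d["sample"]].to_numpy().mean())

    a_high = (truth["responsive_strain"] == "A") & (truth["basal_category"] == "high_basal")
    if a_high.sum() >= 5:
        # the non-responder B already sits at the induced level in both states
        assert mean_of("B", "basal", a_high) == pytest.approx(mu0 * F, rel=0.15)
        assert mean_of("B", "LPS", a_high) == pytest.approx(mu0 * F, rel=0.15)
        assert mean_of("A", "basal", a_high) == pytest.approx(mu0, rel=0.15)
        assert mean_of("A", "LPS", a_high) == pytest.approx(mu0 * F, rel=0.15)
    a_low = (truth["responsive_strain"] == "A") & (truth["basal_category"] == "low_basal")
    if a_low.sum() >= 5:
        assert mean_of("B", "basal", a_low) == pytest.approx(mu0 / F, rel=0.15)
        assert mean_of("B", "LPS", a_low) == pytest.approx(mu0 / F, rel=0.15)


# ------------------------------------------------------------------ motifs

def test_unmutated_pairs_are_identical_and_mutated_differ():
    cfg = SimulationConfig(seed=15)
    pwms = sim.make_random_pwms(cfg, 3)
    target = next(iter(pwms))
    pairs, truth = sim.simulate_motif_landscape(pwms, 80, 0.75, cfg, target=target)
    merged = pairs.merge(truth, on="pair_id")
    mutated = merged["planted_motif_mutation"] != "none"
    assert 0.6 < mutated.mean() <= 0.85
    same = merged["positive_seq"] == merged["negative_seq"]
    assert (same == ~mutated).all()


# ------------------------------------------------------------------ ligands

def test_ligand_network_structure():
    cfg = SimulationConfig(seed=16)
    net = sim.simulate_ligand_network(25, 20, cfg, strains=("A", "B"))
    assert net["active_ligand"] != "ligand000"
    assert len(net["targets"]["A"] & net["targets"]["B"]) == 0
    # ligand000 sits below the strict 10-TPM sender floor
    assert (net["sender_tpm"].loc["ligand000"] <= 10).all()


# -------------------------------------------------------------- determinism

def test_same_seed_reproduces_and_seeds_differ():
    a1 = sim.simulate_strain_genomes(SimulationConfig(seed=42))
    a2 = sim.simulate_strain_genomes(SimulationConfig(seed=42))
    b = sim.simulate_strain_genomes(SimulationConfig(seed=43))
    assert a1[0] == a2[0]
    assert all(a1[1][s] == a2[1][s] for s in a1[1])
    assert a1[0] != b[0]

    c1, _ = sim.simulate_design_counts(
        sim.make_truth_table(SimulationConfig(seed=42)), SimulationConfig(seed=42)
    )
    c2, _ = sim.simulate_design_counts(
        sim.make_truth_table(SimulationConfig(seed=42)), SimulationConfig(seed=42)
    )
    pd.testing.assert_frame_equal(c1, c2)
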