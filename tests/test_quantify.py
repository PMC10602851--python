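"""Normalization, BH correction, and the NB differential engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistranskit.config import SimulationConfig, Thresholds
from cistranskit.quantify import (
    benjamini_hochberg,
    call_accessible_active,
    call_strain_specific,
    compute_tpm,
    count_in_windows,
    nb_differential,
    normalize_tags,
    size_factors,
)
from cistranskit.simulate import nb_draw


# --------------------------------------------------------------- counting

def test_count_in_windows_uses_half_open_window():
    features = pd.DataFrame(
        {"peak_id": ["p"], "chrom": ["chr1"], "start": [100], "end": [300]}
    )
    # midpoint 200, window 100 -> reads counted iff pos in [150, 250)
    reads = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": [149, 150, 249, 250],
            "sample": "s1",
        }
    )
    out = count_in_windows(reads, features, window=100)
    assert out.loc["p", "s1"] == 2


def test_normalize_tags_scales_each_library_to_total():
    counts = pd.DataFrame({"a": [1, 3], "b": [10, 30]})
    norm = normalize_tags(counts, total=100)
    assert np.allclose(norm.sum(axis=0), 100)
    assert np.allclose(norm["a"], norm["b"])  # identical composition
    with pytest.raises(ValueError, match="zero-depth"):
        normalize_tags(pd.DataFrame({"a": [0, 0]}))


def test_tpm_closed_form():
    counts = pd.DataFrame({"s": [10, 20]}, index=["g1", "g2"])
    lengths = pd.Series([1.0, 2.0], index=["g1", "g2"])
    tpm = compute_tpm(counts, lengths)
    # length-normalized rates are equal (10 and 10), so both get 5e5
    assert np.allclose(tpm["s"], [5e5, 5e5])
    assert np.isclose(tpm["s"].sum(), 1e6)


def test_tpm_rejects_missing_or_nonpositive_lengths():
    counts = pd.DataFrame({"s": [10]}, index=["g1"])
    with pytest.raises(ValueError):
        compute_tpm(counts, pd.Series([0.0], index=["g1"]))
    with pytest.raises(ValueError):
        compute_tpm(counts, pd.Series([], dtype=float))


# ------------------------------------------------------------ size factors

def test_size_factors_recover_depth_ratio():
    rng = np.random.default_rng(0)
    base = rng.poisson(100, size=500).astype(float) + 1
    counts = pd.DataFrame({"a": base, "b": 2 * base})
    sf = size_factors(counts)
    # median-of-ratios against the geometric mean: sqrt(2) apart
    assert np.isclose(sf["b"] / sf["a"], 2.0)
    assert np.isclose(sf["a"] * sf["b"], 1.0)


# ------------------------------------------------------------------ BH

def test_benjamini_hochberg_matches_scipy_oracle():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=200)
    p[:20] = rng.uniform(0, 1e-4, size=20)
    expected = stats.false_discovery_control(p, method="bh")
    assert np.allclose(benjamini_hochberg(p), expected)


def test_benjamini_hochberg_propagates_nan():
    p = np.array([0.01, np.nan, 0.5])
    out = benjamini_hochberg(p)
    assert np.isnan(out[1])
    # NaN entries are excluded from the number of tests (m = 2 here)
    assert np.isclose(out[0], min(0.01 * 2 / 1, 1.0))


# ---------------------------------------------------------- nb_differential

def _design(samples, factor, levels):
    rows = []
    for s, lv in zip(samples, levels):
        rows.append((s, lv, int(s[-1])))
    return pd.DataFrame(rows, columns=["sample", factor, "replicate"])


def _simulated_counts(n_null, n_de, mu, fold, seed, nrep=3, alpha=0.05):
    rng = np.random.default_rng(seed)
    n = n_null + n_de
    mu1 = np.full(n, float(mu))
    mu2 = np.full(n, float(mu))
    sign = rng.random(n_de) < 0.5
    mu1[:n_de] = np.where(sign, mu * np.sqrt(fold), mu / np.sqrt(fold))
    mu2[:n_de] = np.where(sign, mu / np.sqrt(fold), mu * np.sqrt(fold))
    cols = {}
    for r in range(1, nrep + 1):
        cols[f"g1_rep{r}"] = nb_draw(rng, mu1, alpha)
        cols[f"g2_rep{r}"] = nb_draw(rng, mu2, alpha)
    counts = pd.DataFrame(cols, index=[f"f{i}" for i in range(n)])
    design = pd.DataFrame(
        {
            "sample": list(cols),
            "group": ["one"] * nrep + ["two"] * nrep,
            "replicate": list(range(1, nrep + 1)) * 2,
        }
    )
    design = design.sort_values("sample").reset_index(drop=True)
    design["group"] = ["one" if s.startswith("g1") else "two" for s in design["sample"]]
    design["replicate"] = [int(s[-1]) for s in design["sample"]]
    return counts, design


def test_planted_fold_changes_are_detected_with_correct_sign():
    counts, design = _simulated_counts(900, 100, mu=500, fold=4.0, seed=11)
    res = nb_differential(counts, design, ("group", "one", "two"))
    de = res.iloc[:100]
    assert de["significant"].mean() > 0.95
    # recovered |log2fc| is unbiased around the planted 2 (per-feature sd ~0.26)
    assert np.isclose(np.abs(de["log2fc"]).mean(), 2.0, atol=0.15)
    assert (np.abs(np.abs(de["log2fc"]) - 2.0) < 1.2).all()


def test_contrast_orientation_is_group1_over_group2():
    counts = pd.DataFrame(
        {
            "hi_rep1": [800],
            "hi_rep2": [820],
            "lo_rep1": [100],
            "lo_rep2": [110],
        },
        index=["f0"],
    )
    design = pd.DataFrame(
        {
            "sample": ["hi_rep1", "hi_rep2", "lo_rep1", "lo_rep2"],
            "group": ["hi", "hi", "lo", "lo"],
            "replicate": [1, 2, 1, 2],
        }
    )
    res = nb_differential(counts, design, ("group", "hi", "lo"))
    assert res.loc["f0", "log2fc"] > 0
    flipped = nb_differential(counts, design, ("group", "lo", "hi"))
    assert np.isclose(flipped.loc["f0", "log2fc"], -res.loc["f0", "log2fc"])


def test_too_few_replicates_raises():
    counts = pd.DataFrame({"a": [1], "b": [2]}, index=["f0"])
    design = pd.DataFrame(
        {"sample": ["a", "b"], "group": ["x", "y"], "replicate": [1, 1]}
    )
    with pytest.raises(ValueError, match="2 replicates"):
        nb_differential(counts, design, ("group", "x", "y"))


def test_all_zero_group_raises():
    counts = pd.DataFrame(
        {"a1": [0, 0], "a2": [0, 0], "b1": [5, 9], "b2": [7, 8]},
        index=["f0", "f1"],
    )
    design = pd.DataFrame(
        {
            "sample": ["a1", "a2", "b1", "b2"],
            "group": ["x", "x", "y", "y"],
            "replicate": [1, 2, 1, 2],
        }
    )
    with pytest.raises(ValueError, match="all zeros"):
        nb_differential(counts, design, ("group", "x", "y"))


def test_abundance_filter_excludes_features_from_bh():
    counts, design = _simulated_counts(50, 10, mu=500, fold=4.0, seed=21)
    abundance = pd.Series(100.0, index=counts.index)
    abundance.iloc[:5] = 8.0  # at the floor: strictly-greater filter excludes
    res = nb_differential(
        counts, design, ("group", "one", "two"), abundance=abundance, min_abundance=8.0
    )
    assert res["padj"].iloc[:5].isna().all()
    assert not res["significant"].iloc[:5].any()
    assert not res["filter_pass"].iloc[:5].any()
    assert res["filter_pass"].iloc[5:].all()


def test_paired_log2fc_is_mean_of_replicate_ratios():
    counts = pd.DataFrame(
        {
            "A_rep1": [100],
            "A_rep2": [400],
            "B_rep1": [100],
            "B_rep2": [100],
        },
        index=["f0"],
    )
    design = pd.DataFrame(
        {
            "sample": ["A_rep1", "A_rep2", "B_rep1", "B_rep2"],
            "allele": ["A", "A", "B", "B"],
            "replicate": [1, 2, 1, 2],
        }
    )
    res = nb_differential(counts, design, ("allele", "A", "B"), paired=True)
    # size factors are applied before ratios: recompute the expected value
    sub = counts.astype(float)
    sf = size_factors(sub)
    norm = sub / sf
    expected = np.mean(
        [
            np.log2((norm.loc["f0", "A_rep1"] + 0.5) / (norm.loc["f0", "B_rep1"] + 0.5)),
            np.log2((norm.loc["f0", "A_rep2"] + 0.5) / (norm.loc["f0", "B_rep2"] + 0.5)),
        ]
    )
    assert np.isclose(res.loc["f0", "log2fc"], expected)


def test_cross_check_against_pydeseq2():
    """Independent oracle: pydeseq2 on the same planted dataset."""
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    counts, design = _simulated_counts(270, 30, mu=500, fold=4.0, seed=31)
    res = nb_differential(counts, design, ("group", "one", "two"))

    meta = design.set_index("sample")[["group"]]
    dds = DeseqDataSet(
        counts=counts.T.loc[meta.index], metadata=meta, design="~group", quiet=True
    )
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["group", "one", "two"], quiet=True)
    ds.summary()
    ref = ds.results_df

    r = np.corrcoef(res["log2fc"], ref["log2FoldChange"])[0, 1]
    assert r > 0.95
    planted = res.index[:30]
    ours = res.loc[planted, "significant"]
    theirs = (ref.loc[planted, "padj"] < 0.05) & (
        ref.loc[planted, "log2FoldChange"].abs() > 1
    )
    assert ours.mean() > 0.9 and theirs.mean() > 0.9


# ---------------------------------------------------------------- calls

def test_accessible_active_thresholds_are_strict():
    thr = Thresholds()
    idx = ["p1", "p2", "p3", "p4"]
    atac = pd.DataFrame({"A": [16.0, 17.0, 16.0, 17.0]}, index=idx)
    k27 = pd.DataFrame({"A": [32.0, 32.0, 33.0, 33.0]}, index=idx)
    status = call_accessible_active(atac, k27, thr)
    assert list(status["A"]) == ["neither", "accessible", "active", "both"]


def test_strain_specific_requires_higher_than_both_others():
    idx = ["g1", "g2"]

    def diff(lfc, sig):
        return pd.DataFrame(
            {"log2fc": lfc, "significant": sig}, index=idx
        )

    pairwise = {
        ("A", "B"): diff([2.0, 2.0], [True, True]),
        ("A", "C"): diff([2.0, -2.0], [True, True]),
        ("B", "C"): diff([0.0, 0.0], [False, False]),
    }
    labels = call_strain_specific(pairwise)
    assert labels["g1"] == "A"     # higher than both B and C
    assert labels["g2"] == "none"  # higher than B but lower than C


def test_null_fraction_close_to_alpha_small_scale():
    counts, design = _simulated_counts(1500, 0, mu=500, fold=1.0, seed=41)
    res = nb_differential(counts, design, ("group", "one", "two"))
    frac = float((res["p"] < 0.05).mean())
    assert 0.02 < frac < 0.09
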