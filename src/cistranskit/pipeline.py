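"""End-to-end orchestration: fixture generation, staged execution, evaluation.

``generate_fixtures`` writes a complete synthetic dataset bundle (FASTA, VCF,
BED, count/design/truth tables, JASPAR PWMs, ligand prior) and
``run_pipeline`` consumes it stage by stage -- pseudogenome construction,
allele assignment, window counting, differential testing, cis/trans and
autonomy classification, stimulus-response analysis, motif-mutation testing,
variant-frequency tabulation and ligand scoring -- writing one results table
per stage plus a manifest.  The ``evaluate`` stage scores every recovery
benchmark against the planted truth and emits a scorecard.

Everything is deterministic under a fixed seed; each output table carries a
header comment with the seed and config hash so reruns are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cistranskit import io
from cistranskit.classify import (
    basal_cistrans_association,
    classify_autonomy,
    classify_cis_trans,
    classify_stimulus_response,
    combine_regulation_calls,
    partition_basal_state,
)
from cistranskit.config import SimulationConfig, Thresholds
from cistranskit.genome import VariantTable, assign_reads, build_pseudogenome
from cistranskit.ligands import (
    filter_candidate_ligands,
    score_ligand_activity,
    zscore_across_strains,
)
from cistranskit.motifs import PWM, motif_mutation_test, variant_frequency_by_foldchange
from cistranskit.quantify import count_in_windows, nb_differential
from cistranskit import simulate as sim

STAGES = (
    "simulate",
    "pseudogenome",
    "assign",
    "quantify",
    "diff",
    "cistrans",
    "autonomy",
    "lps",
    "motif",
    "varfreq",
    "ligand",
    "evaluate",
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and simulation knobs for one pipeline run."""

    outdir: Path
    seed: int = 0
    sim: SimulationConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: tuple[str, ...] = STAGES
    overwrite: bool = False
    # desk-scale sizes of the auxiliary simulations
    n_motif_pairs: int = 100
    motif_mutated_fraction: float = 0.75
    n_decoys: int = 10
    n_ligands: int = 30
    n_ligand_targets: int = 30
    n_lps_features: int = 300
    varfreq_snp_density: float = 1.0 / 1000.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = dataclasses.replace(SimulationConfig(), seed=self.seed)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @property
    def fixture_dir(self) -> Path:
        return self.outdir / "fixtures"

    @property
    def results_dir(self) -> Path:
        return self.outdir / "results"

    def header(self) -> str:
        return f"seed={self.seed} config={self.sim.config_hash()}"


# ------------------------------------------------------------------ fixtures

def generate_fixtures(cfg: PipelineConfig) -> dict[str, Path]:
    """Write the full synthetic input bundle under ``outdir/fixtures``."""
    fx = cfg.fixture_dir
    if fx.exists() and any(fx.iterdir()) and not cfg.overwrite:
        raise FileExistsError(f"{fx} exists and is not empty (pass overwrite=True)")
    fx.mkdir(parents=True, exist_ok=True)
    c = cfg.sim
    hdr = cfg.header()
    paths: dict[str, Path] = {}

    def table(name: str, df: pd.DataFrame, index: bool = False) -> None:
        paths[name] = fx / name
        io.write_table(paths[name], df, header_comment=hdr, index=index)

    # genomes, variants, features, reads
    reference, variants = sim.simulate_strain_genomes(c)
    paths["reference.fa"] = fx / "reference.fa"
    io.write_fasta(paths["reference.fa"], reference)
    contigs = {k: len(v) for k, v in reference.items()}
    for strain, vt in variants.items():
        name = f"variants_{strain}.vcf"
        paths[name] = fx / name
        io.write_vcf(paths[name], vt, contigs)
    features = sim.simulate_features(c)
    paths["features.bed"] = fx / "features.bed"
    io.write_bed(paths["features.bed"], features)
    reads, genomes, _maps = sim.simulate_reads(reference, variants, features, c)
    table("reads.tsv", reads)
    for strain, g in genomes.items():
        name = f"genome_{strain}.fa"
        paths[name] = fx / name
        io.write_fasta(paths[name], g.seqs)

    # design counts with planted regulation classes
    truth = sim.make_truth_table(c)
    counts, design = sim.simulate_design_counts(truth, c)
    table("truth.tsv", truth)
    table("counts.tsv", counts, index=True)
    table("design.tsv", design)

    # stimulus-response arms
    lps_truth = sim.make_lps_truth(cfg.n_lps_features, c)
    lps_counts, lps_design = sim.simulate_lps_counts(lps_truth, c)
    table("lps_truth.tsv", lps_truth)
    table("lps_counts.tsv", lps_counts, index=True)
    table("lps_design.tsv", lps_design)

    # variant-driven peak counts for the variant-frequency table
    vf_sim = dataclasses.replace(c, snp_density=cfg.varfreq_snp_density)
    _, vf_variants = sim.simulate_strain_genomes(vf_sim)
    vf_truth = sim.make_variant_driven_truth(features, vf_variants, vf_sim)
    vf_counts, vf_design = sim.simulate_design_counts(vf_truth, vf_sim, arms=("F0",))
    table("varfreq_truth.tsv", vf_truth)
    table("varfreq_counts.tsv", vf_counts, index=True)
    table("varfreq_design.tsv", vf_design)
    for strain, vt in vf_variants.items():
        name = f"varfreq_variants_{strain}.vcf"
        paths[name] = fx / name
        io.write_vcf(paths[name], vt, contigs)

    # motif landscape
    pwms = sim.make_random_pwms(c, cfg.n_decoys + 1)
    target = next(iter(pwms))
    pairs, motif_truth = sim.simulate_motif_landscape(
        pwms, cfg.n_motif_pairs, cfg.motif_mutated_fraction, c, target=target
    )
    paths["pwms.jaspar"] = fx / "pwms.jaspar"
    io.write_jaspar(paths["pwms.jaspar"], pwms)
    table("motif_pairs.tsv", pairs)
    motif_truth = motif_truth.assign(target_pwm=target)
    table("motif_truth.tsv", motif_truth)

    # ligand network
    net = sim.simulate_ligand_network(
        cfg.n_ligands, cfg.n_ligand_targets, c, strains=("A", "B", "C")
    )
    table("ligand_prior.tsv", net["prior"], index=True)
    table("receptor_map.tsv", net["receptor_map"])
    table("sender_tpm.tsv", net["sender_tpm"], index=True)
    table("receiver_tpm.tsv", net["receiver_tpm"].rename("tpm").to_frame(), index=True)
    targ_rows = [(s, g) for s, gs in net["targets"].items() for g in sorted(gs)]
    table("ligand_targets.tsv", pd.DataFrame(targ_rows, columns=["strain", "gene"]))
    table(
        "ligand_truth.tsv",
        pd.DataFrame(
            {"active_ligand": [net["active_ligand"]], "focal_strain": [net["focal_strain"]]}
        ),
    )
    return paths


# ------------------------------------------------------------------ stages

def _validate_inputs(cfg: PipelineConfig) -> None:
    """Fail before any stage runs if an enabled stage's inputs are missing."""
    fx = cfg.fixture_dir
    needs = {
        "pseudogenome": ["reference.fa", "variants_strainA.vcf", "variants_strainB.vcf"],
        "assign": ["reads.tsv"],
        "quantify": ["features.bed"],
        "diff": ["counts.tsv", "design.tsv"],
        "lps": ["lps_counts.tsv", "lps_design.tsv"],
        "motif": ["pwms.jaspar", "motif_pairs.tsv"],
        "varfreq": ["varfreq_counts.tsv", "varfreq_truth.tsv", "features.bed"],
        "ligand": ["ligand_prior.tsv", "receptor_map.tsv", "sender_tpm.tsv", "receiver_tpm.tsv"],
    }
    if "simulate" in cfg.stages:
        return  # simulate produces everything downstream
    missing = []
    for stage, files in needs.items():
        if stage in cfg.stages:
            missing += [f for f in files if not (fx / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs for enabled stages: {sorted(set(missing))}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    _validate_inputs(cfg)
    rs = cfg.results_dir
    rs.mkdir(parents=True, exist_ok=True)
    fx = cfg.fixture_dir
    hdr = cfg.header()
    thr = cfg.thresholds
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.sim.config_hash(),
        "thresholds": dataclasses.asdict(thr),
        "stages": {},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "complete", **info}

    def save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        io.write_table(rs / name, df, header_comment=hdr, index=index)

    try:
        if "simulate" in cfg.stages:
            paths = generate_fixtures(cfg)
            done("simulate", n_files=len(paths))

        genomes = maps = variants = None
        if "pseudogenome" in cfg.stages:
            reference = io.read_fasta(fx / "reference.fa")
            variants = {
                s: io.read_vcf(fx / f"variants_{s}.vcf") for s in ("strainA", "strainB")
            }
            genomes, maps = {}, {}
            for s, vt in variants.items():
                genomes[s], maps[s] = build_pseudogenome(reference, vt, strain=s)
            done("pseudogenome", n_variants={s: len(v) for s, v in variants.items()})

        assignments = None
        if "assign" in cfg.stages:
            if genomes is None:
                raise RuntimeError("assign requires the pseudogenome stage")
            reads = io.read_table(fx / "reads.tsv")
            assignments = assign_reads(reads, genomes, maps, variants)
            save("assignments.tsv", assignments, index=False)
            done("assign", n_reads=len(assignments), n_assigned=int((assignments["label"] != "unassigned").sum()))

        if "quantify" in cfg.stages and assignments is not None:
            reads = io.read_table(fx / "reads.tsv")
            features = io.read_bed(fx / "features.bed")
            merged = reads.merge(assignments, on="read_id")
            merged = merged[merged["label"] != "unassigned"]
            merged = merged.rename(columns={"ref_start": "pos", "label": "sample"})
            allelic = count_in_windows(merged, features, window=1000)
            save("allelic_counts.tsv", allelic)
            done("quantify", n_features=len(allelic))

        diffs: dict[str, pd.DataFrame] = {}
        if "diff" in cfg.stages:
            counts = io.read_counts(fx / "counts.tsv")
            design = io.read_table(fx / "design.tsv")
            for arm in ("F0", "F1_allele", "F0_NSG", "F1_NSG_allele"):
                d = design[design["arm"] == arm]
                diffs[arm] = nb_differential(
                    counts, d, ("strain_or_allele", "A", "B"), thr,
                    paired="allele" in arm,
                )
                save(f"diff_{arm}.tsv", diffs[arm])
            done("diff", n_features=len(counts))

        regulation = None
        if "cistrans" in cfg.stages:
            regulation = classify_cis_trans(diffs["F0"], diffs["F1_allele"])
            save("regulation.tsv", regulation)
            done("cistrans", class_counts=regulation["cls"].value_counts().to_dict())

        if "autonomy" in cfg.stages:
            calls, props = classify_autonomy(
                diffs["F0"], diffs["F0_NSG"], diffs["F1_NSG_allele"]
            )
            save("autonomy.tsv", calls)
            save("autonomy_proportions.tsv", props.rename("fraction").to_frame())
            done("autonomy", class_counts=calls["cls"].value_counts().to_dict())

        if "lps" in cfg.stages:
            lps_counts = io.read_counts(fx / "lps_counts.tsv")
            lps_design = io.read_table(fx / "lps_design.tsv")
            f0 = lps_design[lps_design["arm"] == "F0"]
            resp = {}
            for strain in ("A", "B"):
                d = f0[f0["strain_or_allele"] == strain]
                resp[strain] = nb_differential(
                    lps_counts, d, ("treatment", "LPS", "basal"), thr
                )
                save(f"lps_response_{strain}.tsv", resp[strain])
            labels = classify_stimulus_response(resp["A"], resp["B"])
            basal_f0 = f0[f0["treatment"] == "basal"]
            basal_diff = nb_differential(
                lps_counts, basal_f0, ("strain_or_allele", "A", "B"), thr
            )
            basal = partition_basal_state(labels, basal_diff)
            save("lps_labels.tsv", labels.rename("label").to_frame())
            save("lps_basal_partition.tsv", basal)
            # cis/trans per condition, then combined: low/equal-basal features
            # expose their strain difference after LPS, high-basal ones only
            # at baseline, so the informative condition supplies the call
            f1 = lps_design[lps_design["arm"] == "F1_allele"]
            reg_by_treat = {}
            for treat in ("LPS", "basal"):
                f0_t = f0[f0["treatment"] == treat]
                f1_t = f1[f1["treatment"] == treat]
                reg_by_treat[treat] = classify_cis_trans(
                    nb_differential(lps_counts, f0_t, ("strain_or_allele", "A", "B"), thr),
                    nb_differential(lps_counts, f1_t, ("strain_or_allele", "A", "B"), thr, paired=True),
                )
            reg_lps = combine_regulation_calls(reg_by_treat["LPS"], reg_by_treat["basal"])
            save("lps_regulation.tsv", reg_lps)
            assoc = basal_cistrans_association(basal, reg_lps)
            save("basal_cistrans_table.tsv", assoc["table"])
            io.write_table(
                rs / "basal_cistrans_chi2.tsv",
                pd.DataFrame(
                    {"chi2": [assoc["chi2"]], "dof": [assoc["dof"]], "p": [assoc["p"]]}
                ),
                header_comment=hdr,
            )
            done("lps", chi2=assoc["chi2"], p=assoc["p"])

        if "motif" in cfg.stages:
            pwms = {k: PWM(k, v) for k, v in io.read_jaspar(fx / "pwms.jaspar").items()}
            pairs = io.read_table(fx / "motif_pairs.tsv")
            motif_res = motif_mutation_test(pairs, pwms)
            save("motif_results.tsv", motif_res)
            done("motif", n_pwms=len(motif_res))

        if "varfreq" in cfg.stages:
            vf_counts = io.read_counts(fx / "varfreq_counts.tsv")
            vf_design = io.read_table(fx / "varfreq_design.tsv")
            features = io.read_bed(fx / "features.bed")
            vf_variants = [
                io.read_vcf(fx / f"varfreq_variants_{s}.vcf") for s in ("strainA", "strainB")
            ]
            vf_diff = nb_differential(vf_counts, vf_design, ("strain_or_allele", "A", "B"), thr)
            vt = variant_frequency_by_foldchange(
                features, {"ATAC": vf_diff}, vf_variants, thr
            )
            save("variant_frequency.tsv", vt)
            done("varfreq")

        if "ligand" in cfg.stages:
            prior = io.read_table(fx / "ligand_prior.tsv", index_col=0)
            rmap = io.read_table(fx / "receptor_map.tsv")
            sender = io.read_table(fx / "sender_tpm.tsv", index_col=0)
            receiver = io.read_table(fx / "receiver_tpm.tsv", index_col=0)["tpm"]
            targets = io.read_table(fx / "ligand_targets.tsv")
            kept = filter_candidate_ligands(prior, rmap, sender, receiver)
            background = set(prior.columns)
            scores = {}
            for strain, grp in targets.groupby("strain"):
                tset = set(grp["gene"])
                scores[strain] = score_ligand_activity(prior.loc[kept], tset, background)
            score_df = pd.DataFrame(scores)
            zs = zscore_across_strains(score_df)
            save("ligand_scores.tsv", score_df)
            save("ligand_zscores.tsv", zs)
            done("ligand", n_candidates=len(kept))

        if "evaluate" in cfg.stages:
            card = evaluate(cfg)
            io.write_table(rs / "scorecard.tsv", card, header_comment=hdr, index=False)
            done("evaluate", metrics=len(card))
    except Exception as exc:  # record the failure point, then re-raise
        manifest["failed"] = {"error": str(exc)}
        (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# ------------------------------------------------------------------ evaluate

def evaluate(cfg: PipelineConfig) -> pd.DataFrame:
    """Score recovery benchmarks against the planted truth -> scorecard."""
    fx, rs = cfg.fixture_dir, cfg.results_dir
    rows: list[tuple[str, float]] = []

    # allele assignment
    if (rs / "assignments.tsv").exists():
        reads = io.read_table(fx / "reads.tsv")
        asg = io.read_table(rs / "assignments.tsv").set_index("read_id")
        reads = reads.set_index("read_id")
        label_of = {"strainA": "allele_A", "strainB": "allele_B"}
        truth_label = reads["strain"].map(label_of)
        assigned = asg["label"] != "unassigned"
        correct = asg.loc[assigned, "label"] == truth_label[assigned.index[assigned]]
        precision = float(correct.mean()) if assigned.any() else np.nan
        spanning = reads["spans_variant"].astype(bool)
        recall = float((asg.loc[spanning[spanning].index, "label"] == truth_label[spanning[spanning].index]).mean())
        rows += [("assignment_precision", precision), ("assignment_recall", recall)]

    # cis/trans recovery
    if (rs / "regulation.tsv").exists():
        truth = io.read_table(fx / "truth.tsv").set_index("feature_id")
        reg = io.read_table(rs / "regulation.tsv", index_col=0)
        merged_cls = truth["true_class"].map(
            {"cis": "cis", "trans_environmental": "trans", "trans_cellautonomous": "trans",
             "mixed": "mixed", "same": "same"}
        )
        recalls = []
        for c in ("cis", "trans", "mixed", "same"):
            m = merged_cls == c
            if m.any():
                recalls.append(float((reg.loc[m[m].index, "cls"] == c).mean()))
        rows.append(("cistrans_macro_recall", float(np.mean(recalls))))

    # autonomy recovery
    if (rs / "autonomy.tsv").exists():
        truth = io.read_table(fx / "truth.tsv").set_index("feature_id")
        calls = io.read_table(rs / "autonomy.tsv", index_col=0)
        common = truth.index.intersection(calls.index)
        t = truth.loc[common, "true_class"]
        c = calls.loc[common, "cls"]
        for lbl in ("trans_environmental", "trans_cellautonomous", "cis"):
            m = t == lbl
            if m.any():
                rows.append((f"autonomy_recall_{lbl}", float((c[m] == lbl).mean())))
        props = io.read_table(rs / "autonomy_proportions.tsv", index_col=0)["fraction"]
        rows.append(("autonomy_environmental_pct", 100.0 * float(props["trans_environmental"])))
        rows.append(("autonomy_cellautonomous_pct", 100.0 * float(props["trans_cellautonomous"])))

    # basal partition accuracy
    if (rs / "lps_basal_partition.tsv").exists():
        lt = io.read_table(fx / "lps_truth.tsv").set_index("feature_id")
        bp = io.read_table(rs / "lps_basal_partition.tsv", index_col=0)
        truth_cat = lt.loc[lt["basal_category"] != "none", "basal_category"]
        common = truth_cat.index.intersection(bp.index)
        if len(common):
            rows.append(
                ("basal_partition_accuracy", float((bp.loc[common, "category"] == truth_cat[common]).mean()))
            )
        chi = io.read_table(rs / "basal_cistrans_chi2.tsv")
        rows.append(("basal_cistrans_p", float(chi["p"].iloc[0])))

    # motif detection
    if (rs / "motif_results.tsv").exists():
        mt = io.read_table(fx / "motif_truth.tsv")
        target = mt["target_pwm"].iloc[0]
        res = io.read_table(rs / "motif_results.tsv", index_col=0)
        rank = int(res["p"].rank(method="min")[target])
        rows += [
            ("motif_target_rank", float(rank)),
            ("motif_target_neglog10p", float(-np.log10(max(res.loc[target, "p"], 1e-300)))),
        ]

    # variant-frequency rows
    if (rs / "variant_frequency.tsv").exists():
        vt = io.read_table(rs / "variant_frequency.tsv", index_col=0)
        for row in vt.index:
            rows.append((f"variant_freq_{row}", float(vt.loc[row].iloc[0])))

    # ligand ranking
    if (rs / "ligand_scores.tsv").exists():
        lt = io.read_table(fx / "ligand_truth.tsv")
        active, focal = lt["active_ligand"].iloc[0], lt["focal_strain"].iloc[0]
        scores = io.read_table(rs / "ligand_scores.tsv", index_col=0)
        if active in scores.index and focal in scores.columns:
            rank = int(scores[focal].rank(ascending=False, method="min")[active])
            rows.append(("ligand_active_rank", float(rank)))
    return pd.DataFrame(rows, columns=["metric", "value"])
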