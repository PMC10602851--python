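"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: diploid strain
genomes differing by SNPs/short indels, error-free reads drawn from either
haplotype, negative-binomial count matrices realizing the full F0 / F1-allele
/ F0-NSG / F1-NSG experimental design with planted cis, trans-environmental,
trans-cell-autonomous, mixed and unchanged regulation, paired peak sequences
with motif-destroying substitutions, stimulus-response archetypes with low /
equal / high basal states, and a ligand--target prior with one planted
active ligand.

The generators draw from ``numpy.random.default_rng`` seeded from
``SimulationConfig.seed`` through fixed per-generator stream keys, so a seed
fully determines every output.  Counts use the NB parameterization
var = mu + alpha * mu**2 (numpy's ``negative_binomial(n=1/alpha,
p=n/(n+mu))``).  Sequencing errors are off by default; fragment-length
models, GC bias and duplicates are deliberately not emulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cistranskit.config import REGULATION_CLASSES, SimulationConfig
from cistranskit.genome import (
    CoordinateMap,
    PseudoGenome,
    VariantTable,
    build_pseudogenome,
)

BASES = np.array(list("ACGT"))

# fixed stream keys so each generator has an independent, reproducible stream
_STREAM = {
    "genome": 11,
    "variants": 12,
    "features": 13,
    "reads": 14,
    "truth": 15,
    "counts": 16,
    "motifs": 17,
    "ligands": 18,
    "lps": 19,
}


def _rng(config: SimulationConfig, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM[stream], extra]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def nb_draw(rng: np.random.Generator, mu, alpha: float, size=None):
    """NB draw with var = mu + alpha mu^2; falls back to Poisson at alpha=0."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size=size)


# ------------------------------------------------------------------ genomes

def simulate_strain_genomes(
    config: SimulationConfig, strains: tuple[str, str] = ("strainA", "strainB"),
    chrom: str = "chr1",
) -> tuple[dict[str, str], dict[str, VariantTable]]:
    """Random reference plus per-strain SNP/indel tables.

    Variant count per strain is Poisson(snp_density * genome_length); a
    configured fraction are anchored indels of 1..max_indel_len bases.
    Variants are non-overlapping within each strain.  ``snp_density == 0``
    yields empty tables; a positive density expecting < 1 variant raises.
    """
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    expected = config.snp_density * config.genome_length
    if config.snp_density > 0 and expected < 1:
        raise ValueError("no variants plantable: snp_density * genome_length < 1")
    rng = _rng(config, "genome")
    reference = {chrom: _random_seq(rng, config.genome_length)}
    tables: dict[str, VariantTable] = {}
    for k, strain in enumerate(strains):
        vrng = _rng(config, "variants", extra=k)
        if config.snp_density == 0:
            tables[strain] = VariantTable()
            continue
        n = vrng.poisson(expected)
        # candidate anchor positions, leaving headroom for the longest deletion
        pad = config.max_indel_len + 2
        candidates = np.sort(
            vrng.choice(np.arange(1, config.genome_length - pad), size=min(n, config.genome_length - pad - 1), replace=False)
        )
        # enforce non-overlap: successive anchors at least pad apart
        keep, last = [], -pad
        for p in candidates:
            if p - last >= pad:
                keep.append(int(p))
                last = int(p)
        rows = []
        seq = reference[chrom]
        for p0 in keep:  # p0 is a 0-based anchor
            anchor = seq[p0]
            if vrng.random() < config.indel_fraction:
                ilen = int(vrng.integers(1, config.max_indel_len + 1))
                if vrng.random() < 0.5:  # insertion
                    ins = _random_seq(vrng, ilen)
                    rows.append((chrom, p0 + 1, anchor, anchor + ins, strain))
                else:  # deletion
                    rows.append((chrom, p0 + 1, seq[p0 : p0 + 1 + ilen], anchor, strain))
            else:  # SNP
                alt = str(vrng.choice([b for b in "ACGT" if b != anchor]))
                rows.append((chrom, p0 + 1, anchor, alt, strain))
        tables[strain] = VariantTable(rows)
    return reference, tables


def simulate_features(
    config: SimulationConfig, width: int = 500, chrom: str = "chr1"
) -> pd.DataFrame:
    """Evenly spaced non-overlapping windows serving as peaks/features."""
    n = config.n_features
    if n * width > config.genome_length:
        raise ValueError("features do not fit in the genome")
    spacing = config.genome_length // n
    starts = np.arange(n) * spacing + (spacing - width) // 2
    return pd.DataFrame(
        {
            "peak_id": [f"peak{i:05d}" for i in range(n)],
            "chrom": chrom,
            "start": starts.astype(int),
            "end": (starts + width).astype(int),
        }
    )


def simulate_reads(
    reference: dict[str, str],
    variants: dict[str, VariantTable],
    features: pd.DataFrame,
    config: SimulationConfig,
    n_reads: int | None = None,
) -> tuple[pd.DataFrame, dict[str, PseudoGenome], dict[str, CoordinateMap]]:
    """Error-free reads drawn uniformly from either haplotype over the features.

    Returns (reads, pseudogenomes, coordinate maps).  Each read records its
    source haplotype, its 5' anchor in both frames, and whether its span is
    discriminable between the haplotypes (the homologous windows differ) --
    the planted truth for assignment benchmarks.  An optional uniform
    substitution error rate perturbs the reported sequence only.
    """
    strains = list(variants)
    genomes: dict[str, PseudoGenome] = {}
    maps: dict[str, CoordinateMap] = {}
    for s in strains:
        genomes[s], maps[s] = build_pseudogenome(reference, variants[s], strain=s)
    L = config.read_length
    widths = (features["end"] - features["start"]).to_numpy()
    if (widths <= L).any():
        raise ValueError("read_length must be smaller than every feature width")
    chrom_len = {c: len(s) for c, s in reference.items()}
    for chrom, start, end in features[["chrom", "start", "end"]].itertuples(index=False):
        if start < 0 or end > chrom_len[chrom]:
            raise ValueError(f"feature outside genome bounds: {chrom}:{start}-{end}")

    if n_reads is None:
        n_reads = int(round(config.mean_depth * len(features)))
    rng = _rng(config, "reads")
    if n_reads == 0:
        empty = pd.DataFrame(
            columns=["read_id", "chrom", "ref_start", "strain", "strain_start", "seq", "spans_variant"]
        )
        return empty, genomes, maps

    feat_idx = rng.integers(0, len(features), size=n_reads)
    hap_idx = rng.integers(0, 2, size=n_reads)
    offs = rng.random(size=n_reads)
    rows = []
    feats = features[["chrom", "start", "end"]].to_numpy(dtype=object)
    for i in range(n_reads):
        chrom, fstart, fend = feats[feat_idx[i]]
        src = strains[hap_idx[i]]
        other = strains[1 - hap_idx[i]]
        cmap, omap = maps[src], maps[other]
        # pick a start in the source-strain frame within the lifted feature
        s_lo, _ = cmap.ref_to_strain(chrom, int(fstart))
        s_hi, _ = cmap.ref_to_strain(chrom, int(fend) - 1)
        start = s_lo + int(offs[i] * max(1, s_hi - L - s_lo + 1))
        ref_anchor, deleted = cmap.strain_to_ref(chrom, start)
        if deleted:  # started inside inserted sequence: slide left to the anchor base
            start, _ = cmap.ref_to_strain(chrom, ref_anchor)
        seq = genomes[src][chrom][start : start + L]
        o_start, _ = omap.ref_to_strain(chrom, ref_anchor)
        other_window = genomes[other][chrom][o_start : o_start + L]
        spans = other_window != seq
        out_seq = seq
        if config.error_rate > 0:
            arr = np.array(list(seq))
            hit = rng.random(L) < config.error_rate
            for j in np.nonzero(hit)[0]:
                arr[j] = rng.choice([b for b in "ACGT" if b != arr[j]])
            out_seq = "".join(arr)
        rows.append((f"read{i:07d}", chrom, ref_anchor, src, start, out_seq, spans))
    reads = pd.DataFrame(
        rows, columns=["read_id", "chrom", "ref_start", "strain", "strain_start", "seq", "spans_variant"]
    )
    return reads, genomes, maps


# ------------------------------------------------------------------ counts

def make_truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Assign each feature one regulation class (per class_proportions) and a
    favored direction."""
    rng = _rng(config, "truth")
    labels = list(config.class_proportions)
    unknown = set(labels) - set(REGULATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    probs = np.array([config.class_proportions[c] for c in labels])
    n = config.n_features
    # exact proportions up to integer rounding (remainder padded left-to-right)
    counts = np.floor(probs * n).astype(int)
    short = n - counts.sum()
    if short:
        counts[:short] += 1
    classes = np.repeat(labels, counts)
    rng.shuffle(classes)
    direction = np.where(rng.random(n) < 0.5, "A", "B")
    direction = np.where(classes == "same", "none", direction)
    return pd.DataFrame(
        {
            "feature_id": [f"gene{i:05d}" for i in range(n)],
            "true_class": classes,
            "true_direction": direction,
            "planted_motif_mutation": "none",
        }
    )


# per-class bias semantics: which contrasts carry the planted fold change.
# Keys are design arms; True means the A:B (or alleleA:alleleB) means are split
# by the planted effect, False means both groups share the same mean.
_CLASS_BIAS = {
    "cis": {"F0": True, "F1_allele": True, "F0_NSG": True, "F1_NSG_allele": True},
    "trans_environmental": {"F0": True, "F1_allele": False, "F0_NSG": False, "F1_NSG_allele": False},
    "trans_cellautonomous": {"F0": True, "F1_allele": False, "F0_NSG": True, "F1_NSG_allele": False},
    "mixed": {"F0": False, "F1_allele": True, "F0_NSG": False, "F1_NSG_allele": True},
    "same": {"F0": False, "F1_allele": False, "F0_NSG": False, "F1_NSG_allele": False},
}

ARMS = ("F0", "F1_allele", "F0_NSG", "F1_NSG_allele")


def simulate_design_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    arms: tuple[str, ...] = ARMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for every design arm, realizing the planted class semantics.

    Returns (counts, design).  Counts are features x samples; design maps each
    sample id to (arm, strain_or_allele, replicate, treatment).  Allelic arms
    halve the baseline mean (each allele contributes half a diploid library).
    Bias splits the planted |log2FC| symmetrically: the favored group's mean
    is mu * 2^(f/2), the other mu * 2^(-f/2).
    """
    bad = set(truth["true_class"]) - set(_CLASS_BIAS)
    if bad:
        raise ValueError(f"unknown class label(s): {sorted(bad)}")
    rng = _rng(config, "counts")
    nrep = config.n_replicates
    if nrep < 2:
        raise ValueError("need >= 2 replicates per arm")
    mu0 = config.mean_depth
    n = len(truth)
    classes = truth["true_class"].to_numpy()
    direction = truth["true_direction"].to_numpy()
    if "true_log2fc" in truth.columns:
        f = truth["true_log2fc"].to_numpy(dtype=float)
    else:
        f = np.full(n, config.effect_log2fc)
    up = 2.0 ** (f / 2.0)
    dn = 2.0 ** (-f / 2.0)

    cols: dict[str, np.ndarray] = {}
    design_rows = []
    for arm in arms:
        allelic = "allele" in arm
        base = mu0 / 2.0 if allelic else mu0
        biased = np.array([_CLASS_BIAS[c][arm] for c in classes])
        for side in ("A", "B"):
            mult = np.ones(n)
            favored = direction == side
            sel_up = biased & favored
            sel_dn = biased & ~favored & (direction != "none")
            mult[sel_up] = up[sel_up]
            mult[sel_dn] = dn[sel_dn]
            mu = base * mult
            for r in range(1, nrep + 1):
                name = f"{arm}_{side}_rep{r}"
                cols[name] = nb_draw(rng, mu, config.nb_dispersion)
                design_rows.append((name, arm, side, r, "basal"))
    counts = pd.DataFrame(cols, index=truth["feature_id"].to_numpy())
    counts.index.name = "feature_id"
    design = pd.DataFrame(
        design_rows, columns=["sample", "arm", "strain_or_allele", "replicate", "treatment"]
    )
    return counts, design


# ------------------------------------------------------------------ LPS arms

BASAL_CATEGORIES = ("low_basal", "equal_basal", "high_basal")


def make_lps_truth(
    n_features: int,
    config: SimulationConfig,
    p_responsive: float = 0.3,
    p_shared: float = 0.1,
    basal_probs: dict[str, float] | None = None,
    reg_given_basal: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Truth for stimulus-response simulation.

    Strain-specific responders get a basal category (low/equal/high) and a
    regulation class drawn conditional on that category (``reg_given_basal``
    gives P(cis | category); the rest are trans), which plants the
    basal-state x cis/trans dependence the association test should detect.
    """
    rng = _rng(config, "lps")
    basal_probs = basal_probs or {"low_basal": 1 / 3, "equal_basal": 1 / 3, "high_basal": 1 / 3}
    reg_given_basal = reg_given_basal or {"low_basal": 0.8, "equal_basal": 0.5, "high_basal": 0.2}
    rows = []
    for i in range(n_features):
        u = rng.random()
        if u < p_responsive:
            responsive = "A" if rng.random() < 0.5 else "B"
            cat = str(rng.choice(BASAL_CATEGORIES, p=[basal_probs[c] for c in BASAL_CATEGORIES]))
            reg = "cis" if rng.random() < reg_given_basal[cat] else "trans"
        elif u < p_responsive + p_shared:
            responsive, cat, reg = "both", "none", "none"
        else:
            responsive, cat, reg = "none", "none", "none"
        rows.append((f"gene{i:05d}", responsive, cat, reg))
    return pd.DataFrame(rows, columns=["feature_id", "responsive_strain", "basal_category", "reg_class"])


def simulate_lps_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for basal and LPS-treated arms of both strains plus F1 alleles.

    Archetypes for a strain-specific responder (say responsive in A), with
    mu0 = mean_depth and fold step F = 2^effect_log2fc:

    - equal_basal: both strains basal at mu0; A induced to mu0*F.
    - low_basal:   non-responder B sits at mu0/F basally and stays there;
                   A basal mu0, induced mu0*F.
    - high_basal:  B already at mu0*F basally and stays; A basal mu0,
                   induced to mu0*F (catches up).

    Shared responders double in both strains; non-responders are flat.  F1
    allelic counts under both treatments mirror the strain means for "cis"
    features and average them for "trans" features.
    """
    rng = _rng(config, "lps", extra=1)
    nrep = config.n_replicates
    mu0 = config.mean_depth
    F = 2.0 ** config.effect_log2fc
    n = len(truth)

    mus: dict[tuple[str, str], np.ndarray] = {}  # (strain, treatment) -> per-feature mean
    for key in [("A", "basal"), ("A", "LPS"), ("B", "basal"), ("B", "LPS")]:
        mus[key] = np.full(n, mu0)
    for i, (resp, cat) in enumerate(truth[["responsive_strain", "basal_category"]].itertuples(index=False)):
        if resp == "both":
            mus[("A", "LPS")][i] = mus[("B", "LPS")][i] = mu0 * F
        elif resp in ("A", "B"):
            other = "B" if resp == "A" else "A"
            mus[(resp, "basal")][i] = mu0
            mus[(resp, "LPS")][i] = mu0 * F
            level = {"low_basal": mu0 / F, "equal_basal": mu0, "high_basal": mu0 * F}[cat]
            mus[(other, "basal")][i] = level
            mus[(other, "LPS")][i] = level

    cols: dict[str, np.ndarray] = {}
    design_rows = []
    for (strain, treat), mu in mus.items():
        for r in range(1, nrep + 1):
            name = f"F0_{strain}_{treat}_rep{r}"
            cols[name] = nb_draw(rng, mu, config.nb_dispersion)
            design_rows.append((name, "F0", strain, r, treat))
    # F1 allelic arms (per treatment): cis mirrors strain means, trans averages
    reg = truth["reg_class"].to_numpy()
    for treat in ("basal", "LPS"):
        muA, muB = mus[("A", treat)], mus[("B", treat)]
        avg = (muA + muB) / 2.0
        aA = np.where(reg == "cis", muA, avg) / 2.0
        aB = np.where(reg == "cis", muB, avg) / 2.0
        for side, mu in (("A", aA), ("B", aB)):
            for r in range(1, nrep + 1):
                name = f"F1_allele{side}_{treat}_rep{r}"
                cols[name] = nb_draw(rng, mu, config.nb_dispersion)
                design_rows.append((name, "F1_allele", side, r, treat))
    counts = pd.DataFrame(cols, index=truth["feature_id"].to_numpy())
    counts.index.name = "feature_id"
    design = pd.DataFrame(
        design_rows, columns=["sample", "arm", "strain_or_allele", "replicate", "treatment"]
    )
    return counts, design


# ------------------------------------------------------------------ motifs

def random_pwm(rng: np.random.Generator, width: int, sharpness: float = 5.0) -> np.ndarray:
    """A sharply-peaked random PWM: 4 x width base-probability matrix."""
    mat = rng.dirichlet(np.full(4, 1.0 / sharpness), size=width).T
    return mat


def consensus(pwm: np.ndarray) -> str:
    return "".join(BASES[np.argmax(pwm, axis=0)])


def simulate_motif_landscape(
    pwms: dict[str, np.ndarray],
    n_pairs: int,
    mutated_fraction: float,
    config: SimulationConfig,
    target: str | None = None,
    seq_length: int = 200,
    n_background_snps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired positive/negative sequences with motif-destroying substitutions.

    Every positive sequence carries an intact planted match of the target PWM
    (a site sampled from the PWM, so instances vary across pairs) at a random
    offset.  In ``mutated_fraction`` of pairs the negative copy carries a
    consensus-destroying substitution at an informative motif position, plus
    ``n_background_snps`` random substitutions outside the planted site --
    emulating the linked background variation a comparator strain carries at
    a differential locus.  Unmutated pairs are identical, so they score
    equally for every PWM.  Returns (pairs, truth).
    """
    if target is None:
        target = next(iter(pwms))
    pwm = np.asarray(pwms[target], dtype=float)
    pwm = pwm / pwm.sum(axis=0, keepdims=True)
    w = pwm.shape[1]
    if w >= seq_length:
        raise ValueError("PWM width must be smaller than sequence length")
    rng = _rng(config, "motifs")
    # informative positions (top half): a substitution there destroys the match
    info = pwm.max(axis=0) - pwm.min(axis=0)
    informative = np.nonzero(info >= np.median(info))[0]
    rows, truth_rows = [], []
    for i in range(n_pairs):
        bg = _random_seq(rng, seq_length)
        off = int(rng.integers(0, seq_length - w + 1))
        # sample a site from the PWM so planted instances vary across pairs
        site = "".join(
            str(BASES[rng.choice(4, p=pwm[:, k])]) for k in range(w)
        )
        pos = bg[:off] + site + bg[off + w :]
        mutated = bool(rng.random() < mutated_fraction)
        if mutated:
            crit = int(rng.choice(informative))
            # any substitution at an informative position of a peaked PWM
            # destroys the match; the replacement base is random so the
            # mutation context varies across pairs
            sub = str(rng.choice([b for b in "ACGT" if b != site[crit]]))
            j = off + crit
            neg = pos[:j] + sub + pos[j + 1 :]
            # linked background variation outside the planted site
            outside = np.setdiff1d(np.arange(seq_length), np.arange(off, off + w))
            for k in rng.choice(outside, size=min(n_background_snps, len(outside)), replace=False):
                k = int(k)
                b = str(rng.choice([x for x in "ACGT" if x != neg[k]]))
                neg = neg[:k] + b + neg[k + 1 :]
        else:
            neg = pos
        rows.append((f"pair{i:05d}", pos, neg, "A_vs_B"))
        truth_rows.append((f"pair{i:05d}", target if mutated else "none"))
    pairs = pd.DataFrame(rows, columns=["pair_id", "positive_seq", "negative_seq", "comparison"])
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "planted_motif_mutation"])
    return pairs, truth


def make_random_pwms(
    config: SimulationConfig, n: int, width_range: tuple[int, int] = (8, 12),
    prefix: str = "MA", sharpness: float = 5.0,
) -> dict[str, np.ndarray]:
    rng = _rng(config, "motifs", extra=99)
    return {
        f"{prefix}{i:04d}.1": random_pwm(rng, int(rng.integers(*width_range)), sharpness)
        for i in range(n)
    }


# ------------------------------------------------------------------ ligands

def simulate_ligand_network(
    n_ligands: int,
    n_targets: int,
    config: SimulationConfig,
    n_background: int = 500,
    enrichment: float = 2.0,
    senders: tuple[str, ...] = ("hepatocyte", "LSEC", "stellate"),
    strains: tuple[str, ...] = ("A",),
) -> dict:
    """Ligand--target prior with one planted active ligand.

    The prior is exponential noise; the active ligand's scores on the first
    strain's DE target set get an additional exponential bump of mean
    ``enrichment`` (``enrichment = 0`` leaves it indistinguishable from the
    decoys).  With several strains, each strain gets its own disjoint target
    set, so cross-strain z-scores should single out the first strain.
    Sender/receiver TPM tables straddle the 10-TPM expression filter:
    ligand 0 is forced below it (to exercise exclusion) while the active
    ligand and its receptor are comfortably above.
    """
    if n_ligands < 2:
        raise ValueError("need at least 2 ligands")
    rng = _rng(config, "ligands")
    n_genes = n_targets * len(strains) + n_background
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    targets = {
        s: set(genes[i * n_targets : (i + 1) * n_targets]) for i, s in enumerate(strains)
    }
    ligands = [f"ligand{i:03d}" for i in range(n_ligands)]
    active = ligands[int(rng.integers(1, n_ligands))]  # ligand000 reserved for the low-TPM case
    prior = pd.DataFrame(
        rng.exponential(1.0, size=(n_ligands, n_genes)), index=ligands, columns=genes
    )
    focal = strains[0]
    if enrichment > 0:
        prior.loc[active, sorted(targets[focal])] += rng.exponential(enrichment, size=n_targets)
    receptors = {lig: f"receptor{i:03d}" for i, lig in enumerate(ligands)}
    # sender expression: mostly expressed, some below the filter
    sender_tpm = pd.DataFrame(
        rng.uniform(2.0, 80.0, size=(n_ligands, len(senders))), index=ligands, columns=senders
    )
    sender_tpm.iloc[0] = 9.0  # below the strict >10 TPM floor in every sender
    sender_tpm.loc[active] = rng.uniform(30.0, 80.0, size=len(senders))
    receptor_tpm = pd.Series(
        rng.uniform(2.0, 80.0, size=n_ligands), index=[receptors[l] for l in ligands]
    )
    receptor_tpm[receptors[active]] = float(rng.uniform(30.0, 80.0))
    return {
        "prior": prior,
        "receptor_map": pd.DataFrame(
            {"ligand": ligands, "receptor": [receptors[l] for l in ligands]}
        ),
        "sender_tpm": sender_tpm,
        "receiver_tpm": receptor_tpm,
        "targets": targets,
        "target_genes": sorted(targets[focal]),
        "background_genes": genes,
        "active_ligand": active,
        "focal_strain": focal,
    }


def make_variant_driven_truth(
    features: pd.DataFrame,
    variants: dict[str, VariantTable],
    config: SimulationConfig,
    effect_fraction: float = 0.5,
    window: int = 200,
) -> pd.DataFrame:
    """Truth for the variant-frequency analysis: effects only at variant peaks.

    Peaks with >= 1 variant (either strain) within the central ``window`` bp
    are eligible; a fraction of them is planted with a parental-strain effect
    ("cis" class), everything else is unchanged.  Thus every differential
    peak harbors local variation by construction, while similar peaks carry
    variants at the genomic background rate.
    """
    rng = _rng(config, "truth", extra=7)
    half = window // 2
    central = []
    for chrom, start, end in features[["chrom", "start", "end"]].itertuples(index=False):
        mid = (int(start) + int(end)) // 2
        central.append(
            any(vt.count_overlapping(chrom, mid - half, mid + half) > 0 for vt in variants.values())
        )
    central = np.array(central)
    eligible = np.nonzero(central)[0]
    n_effect = int(round(effect_fraction * len(eligible)))
    chosen = set(rng.choice(eligible, size=n_effect, replace=False)) if n_effect else set()
    cls = np.array(["cis" if i in chosen else "same" for i in range(len(features))])
    direction = np.where(cls == "cis", np.where(rng.random(len(features)) < 0.5, "A", "B"), "none")
    # spread of effect sizes so every fold-change stratum is populated
    effect = np.where(cls == "cis", rng.choice([1.5, 2.5, 3.5], size=len(features)), 0.0)
    return pd.DataFrame(
        {
            "feature_id": features["peak_id"].astype(str).to_numpy(),
            "true_class": cls,
            "true_direction": direction,
            "true_log2fc": effect,
            "planted_motif_mutation": "none",
            "has_central_variant": central,
        }
    )
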