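"""Tag counting, normalization, and the negative-binomial differential test.

The differential engine is a deliberate simplification of DESeq2: median-of-
ratios size factors, method-of-moments per-feature dispersion shrunk toward a
fitted mean--dispersion trend, and a delta-method Wald test on the log2 fold
change, with Benjamini-Hochberg correction applied over features passing an
abundance floor.  It is calibration-tested, not numerically identical to
DESeq2.  All threshold comparisons are strict inequalities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cistranskit.config import Thresholds

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0
_PSEUDO = 0.5  # pseudo normalized count stabilizing log fold changes


# ------------------------------------------------------------------ counting

def count_in_windows(
    reads: pd.DataFrame, features: pd.DataFrame, window: int
) -> pd.DataFrame:
    """Count reads whose 5' position falls in a fixed window around each feature midpoint.

    ``reads`` needs columns ``chrom, pos, sample`` (pos = 0-based 5' end);
    ``features`` needs ``peak_id, chrom, start, end``.  A read contributes to
    a feature iff pos lies in [mid - window/2, mid + window/2); windows of
    different features may overlap, in which case the read counts once per
    feature.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    samples = sorted(reads["sample"].unique()) if len(reads) else []
    out = pd.DataFrame(
        0, index=features["peak_id"].astype(str), columns=samples, dtype=int
    )
    out.index.name = "feature_id"
    half = window // 2
    for sample in samples:
        sub = reads[reads["sample"] == sample]
        for chrom, grp in sub.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            feats = features[features["chrom"] == chrom]
            mids = ((feats["start"] + feats["end"]) // 2).to_numpy()
            lo = np.searchsorted(pos, mids - half, side="left")
            hi = np.searchsorted(pos, mids - half + window, side="left")
            out.loc[feats["peak_id"].astype(str), sample] += hi - lo
    return out


def normalize_tags(counts: pd.DataFrame, total: float = 1e7) -> pd.DataFrame:
    """Scale each sample (column) so its library total equals ``total``."""
    depths = counts.sum(axis=0)
    if (depths <= 0).any():
        bad = list(depths.index[depths <= 0])
        raise ValueError(f"zero-depth sample(s): {bad}")
    return counts * (total / depths)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized columns summing to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    rate = counts.div(lengths, axis=0)
    tot = rate.sum(axis=0)
    if (tot <= 0).any():
        raise ValueError(f"all-zero sample(s): {list(tot.index[tot <= 0])}")
    return rate * (1e6 / tot)


# ------------------------------------------------------------------ differential

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors."""
    logc = np.log(counts.where(counts > 0))
    log_gmean = logc.mean(axis=1)
    usable = np.isfinite(log_gmean)
    if not usable.any():
        # no feature observed in every sample: fall back to library-size ratios
        depths = counts.sum(axis=0).astype(float)
        return depths / np.exp(np.log(depths).mean())
    ratios = logc.loc[usable].sub(log_gmean[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf


def _dispersion(norm: pd.DataFrame, groups: list[list[str]], shrink_weight: float = 0.8
                ) -> np.ndarray:
    """Per-feature NB dispersion: method-of-moments within groups, shrunk in
    log space toward a fitted a0 + a1/mu trend."""
    mus, alphas, weights = [], [], []
    for cols in groups:
        sub = norm[cols]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        mus.append(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(np.maximum(m, 1e-12))
        alphas.append(a)
        weights.append(len(cols) - 1)
    mu_bar = np.average(np.column_stack(mus), axis=1)
    alpha_raw = np.average(np.column_stack(alphas), axis=1, weights=weights)
    alpha_raw = np.clip(np.nan_to_num(alpha_raw, nan=DISPERSION_FLOOR), DISPERSION_FLOOR, DISPERSION_CEIL)

    # parametric trend alpha(mu) = a0 + a1/mu on moderately expressed features
    ok = mu_bar > 1
    trend = np.full_like(alpha_raw, np.median(alpha_raw[ok]) if ok.any() else DISPERSION_FLOOR)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu_bar[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
        a0 = max(coef[0], DISPERSION_FLOOR)
        a1 = max(coef[1], 0.0)
        trend = a0 + a1 / np.maximum(mu_bar, 1e-12)
    trend = np.clip(trend, DISPERSION_FLOOR, DISPERSION_CEIL)
    w = shrink_weight
    alpha = (1 - w) * alpha_raw + w * trend
    return np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values; NaN inputs propagate as NaN and are not counted."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    m = mask.sum()
    if m == 0:
        return out
    ps = p[mask]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def nb_differential(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    thresholds: Thresholds | None = None,
    paired: bool = False,
    abundance: pd.Series | None = None,
    min_abundance: float | None = None,
    shrink_weight: float = 0.8,
) -> pd.DataFrame:
    """NB Wald test of group1 vs group2 (log2fc = log2(group1/group2)).

    Parameters
    ----------
    counts : DataFrame
        Raw counts, features x samples.
    design : DataFrame
        Sample metadata with at least columns ``sample`` and the contrast
        factor; a ``replicate`` column is required for paired designs.  Only
        samples belonging to the two contrast levels are used.
    contrast : (factor, level1, level2)
        Column of ``design`` and the two levels to compare.
    paired : bool
        Pair samples by replicate (used for F1 allelic contrasts, where the
        two alleles of one animal share a library).
    abundance, min_abundance :
        Optional per-feature abundance (e.g. mean TPM or mean normalized
        tags) and a strict floor; features at or below the floor are excluded
        from BH correction (padj = NaN) and can never be significant.

    Returns a DataFrame indexed by feature with columns ``base_mean, log2fc,
    p, padj, significant, filter_pass``.
    """
    thr = thresholds or Thresholds()
    factor, lv1, lv2 = contrast
    g1 = design.loc[design[factor] == lv1, "sample"].tolist()
    g2 = design.loc[design[factor] == lv2, "sample"].tolist()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both contrast groups need >= 2 replicates")
    sub = counts[g1 + g2].astype(float)
    if sub[g1].to_numpy().sum() <= 0 or sub[g2].to_numpy().sum() <= 0:
        raise ValueError("degenerate contrast: a group is all zeros for every feature")
    sf = size_factors(sub)
    norm = sub / sf

    alpha_disp = _dispersion(norm, [g1, g2], shrink_weight=shrink_weight)

    m1 = norm[g1].mean(axis=1).to_numpy() + _PSEUDO
    m2 = norm[g2].mean(axis=1).to_numpy() + _PSEUDO
    if paired:
        d1 = design.set_index("sample")
        reps1 = {d1.loc[s, "replicate"]: s for s in g1}
        reps2 = {d1.loc[s, "replicate"]: s for s in g2}
        common = sorted(set(reps1) & set(reps2))
        if len(common) < 2:
            raise ValueError("paired design needs >= 2 shared replicates")
        a = norm[[reps1[r] for r in common]].to_numpy() + _PSEUDO
        b = norm[[reps2[r] for r in common]].to_numpy() + _PSEUDO
        diffs = np.log2(a / b)
        lfc = diffs.mean(axis=1)
        var_model = ((1.0 / a + alpha_disp[:, None]) + (1.0 / b + alpha_disp[:, None])) / LN2**2
        var_lfc = var_model.mean(axis=1) / len(common)
    else:
        lfc = np.log2(m1 / m2)
        v1 = (1.0 / m1 + alpha_disp) / len(g1)
        v2 = (1.0 / m2 + alpha_disp) / len(g2)
        var_lfc = (v1 + v2) / LN2**2
    z = lfc / np.sqrt(var_lfc)
    p = 2.0 * stats.norm.sf(np.abs(z))

    base_mean = norm.mean(axis=1).to_numpy()
    if abundance is not None and min_abundance is not None:
        filter_pass = abundance.reindex(counts.index).to_numpy() > min_abundance
    else:
        filter_pass = np.ones(len(counts), dtype=bool)
    p_for_bh = np.where(filter_pass, p, np.nan)
    padj = benjamini_hochberg(p_for_bh)
    significant = (
        filter_pass
        & (np.abs(lfc) > thr.fc_threshold)
        & np.nan_to_num(padj < thr.alpha, nan=False)
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "p": p,
            "padj": padj,
            "significant": significant,
            "filter_pass": filter_pass,
        },
        index=counts.index,
    )


# ------------------------------------------------------------------ calls

def call_strain_specific(
    pairwise: dict[tuple[str, str], pd.DataFrame], strains: tuple[str, ...] | None = None
) -> pd.Series:
    """Per-gene strain label: significantly higher in one strain than in BOTH others.

    ``pairwise`` maps ordered strain pairs (X, Y) to DiffResults with
    log2fc = log2(X/Y).  Genes not higher in any strain vs both others get
    ``"none"``.
    """
    if strains is None:
        strains = tuple(sorted({s for pair in pairwise for s in pair}))
    universes = [set(df.index) for df in pairwise.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("pairwise results must share one feature universe")

    def higher_in(x: str, y: str) -> pd.Series:
        if (x, y) in pairwise:
            df = pairwise[(x, y)]
            return df["significant"] & (df["log2fc"] > 0)
        if (y, x) in pairwise:
            df = pairwise[(y, x)]
            return df["significant"] & (df["log2fc"] < 0)
        raise KeyError(f"missing pairwise comparison between {x} and {y}")

    idx = next(iter(pairwise.values())).index
    label = pd.Series("none", index=idx, dtype=object)
    for x in strains:
        others = [s for s in strains if s != x]
        mask = pd.Series(True, index=idx)
        for y in others:
            mask &= higher_in(x, y)
        label[mask] = x
    return label


def call_accessible_active(
    atac_tags: pd.DataFrame,
    k27ac_tags: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-peak, per-strain status from mean normalized tag matrices.

    ``atac_tags`` / ``k27ac_tags``: features x strains mean normalized tags.
    A locus is accessible where ATAC tags strictly exceed ``min_tags`` and
    active where H3K27ac tags strictly exceed ``active_tags``; status is one
    of {"both", "accessible", "active", "neither"}.
    """
    thr = thresholds or Thresholds()
    if not atac_tags.index.equals(k27ac_tags.index) or list(atac_tags.columns) != list(
        k27ac_tags.columns
    ):
        raise ValueError("matrices must share feature universe and strain columns")
    acc = atac_tags > thr.min_tags
    act = k27ac_tags > thr.active_tags
    status = pd.DataFrame("neither", index=atac_tags.index, columns=atac_tags.columns)
    status = status.mask(acc & ~act, "accessible").mask(~acc & act, "active").mask(
        acc & act, "both"
    )
    return status
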