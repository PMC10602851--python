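"""PWM scanning, the paired motif-mutation statistic, and variant frequency.

A PWM is scored as the summed log-odds of a window against a uniform
background, maximized over every window on both strands.  The motif-mutation
statistic pairs, for each differential peak, the sequence from the
higher-signal strain (positive) with the homologous sequence from the
comparator strain (negative), computes the difference of maximal PWM scores,
and tests the nonzero differences against a null centered on zero with a
two-sided Wilcoxon signed-rank test; BH q-values are reported across PWMs.
Motifs whose matches are destroyed by variants in the lower-signal strain
surface with positive median differences and small p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cistranskit.config import Thresholds
from cistranskit.genome import CoordinateMap, PseudoGenome, VariantTable, extract_peak_sequences
from cistranskit.quantify import benjamini_hochberg

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PWM:
    """Position weight matrix with a derived log-odds matrix.

    Built from a 4 x width count or probability matrix (rows A, C, G, T).  A
    pseudocount is added per cell before normalization; log-odds are taken
    against a uniform 0.25 background.  N bases contribute 0 log-odds.
    """

    def __init__(self, name: str, matrix: np.ndarray, pseudocount: float = 0.01):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != 4 or matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x width")
        probs = matrix + pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.name = name
        self.width = matrix.shape[1]
        self.probs = probs
        logodds = np.log2(probs / 0.25)
        # row 5 = N: background expectation, contributes zero
        self.logodds = np.vstack([logodds, np.zeros((1, self.width))])

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=0))

    def max_logodds(self) -> float:
        return float(self.logodds[:4].max(axis=0).sum())


_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def _seq_to_idx(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def _revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def max_pwm_score(sequence: str, pwm: PWM) -> float:
    """Maximal summed log-odds over all windows on both strands."""
    w = pwm.width
    if len(sequence) < w:
        raise ValueError(f"sequence shorter than PWM width {w}")
    best = -np.inf
    for s in (sequence, _revcomp(sequence)):
        idx = _seq_to_idx(s)
        windows = np.lib.stride_tricks.sliding_window_view(idx, w)
        scores = pwm.logodds[windows, np.arange(w)].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def build_sequence_pairs(
    differential_peaks: dict[tuple[str, str], pd.DataFrame],
    genomes: dict[str, PseudoGenome],
    maps: dict[str, CoordinateMap],
    width: int = 200,
) -> pd.DataFrame:
    """Positive/negative sequence pairs for every ordered strain comparison.

    ``differential_peaks`` maps an ordered pair (X, Y) -- peaks with higher
    signal in X than in Y -- to a peak table (``peak_id, chrom, start, end``,
    reference frame).  For each peak the positive sequence comes from X's
    genome frame and the negative from Y's, both of fixed ``width`` centered
    on the lifted midpoint.  All comparisons are concatenated into one list
    (three strains give six, two strains give two).
    """
    rows = []
    for (x, y), peaks in differential_peaks.items():
        pos_seqs = extract_peak_sequences(genomes[x], maps[x], peaks, width)
        neg_seqs = extract_peak_sequences(genomes[y], maps[y], peaks, width)
        for pid in peaks["peak_id"].astype(str):
            if pid in pos_seqs and pid in neg_seqs:
                rows.append((f"{x}_gt_{y}:{pid}", pos_seqs[pid], neg_seqs[pid], f"{x}_gt_{y}"))
    return pd.DataFrame(rows, columns=["pair_id", "positive_seq", "negative_seq", "comparison"])


def motif_mutation_test(
    pairs: pd.DataFrame, pwms: dict[str, PWM | np.ndarray], pseudocount: float = 0.01
) -> pd.DataFrame:
    """Paired max-score difference statistic per PWM.

    For each PWM, difference_i = max score of positive_i minus max score of
    negative_i; zero differences are dropped (their count is reported) and
    the remainder tested two-sided by Wilcoxon signed-rank.  PWMs with no
    nonzero difference are untestable (p = NaN).  BH q is computed across
    PWMs within the run.
    """
    if not len(pairs):
        raise ValueError("need at least one sequence pair")
    rows = []
    for name, mat in pwms.items():
        pwm = mat if isinstance(mat, PWM) else PWM(name, mat, pseudocount=pseudocount)
        diffs = np.array(
            [
                max_pwm_score(p, pwm) - max_pwm_score(n, pwm)
                for p, n in pairs[["positive_seq", "negative_seq"]].itertuples(index=False)
            ]
        )
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            rows.append((name, len(diffs), 0, 0.0, np.nan, np.nan))
            continue
        res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided")
        rows.append(
            (name, len(diffs), len(nz), float(np.median(diffs)), float(res.statistic), float(res.pvalue))
        )
    out = pd.DataFrame(
        rows,
        columns=["pwm", "n_pairs_total", "n_nonzero_pairs", "median_diff", "statistic", "p"],
    ).set_index("pwm")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def variant_frequency_by_foldchange(
    peaks: pd.DataFrame,
    diffs: dict[str, pd.DataFrame],
    variants: VariantTable | list[VariantTable],
    thresholds: Thresholds | None = None,
    window: int = 200,
    cutoffs: tuple[float, ...] = (2.0, 4.0, 8.0),
) -> pd.DataFrame:
    """Percent of peaks harboring local variation, by fold-change stratum.

    Rows: "similar" (|log2fc| <= fc_threshold AND not significant) and one
    per fold-change cutoff (fold change > cutoff AND significant); columns:
    one per assay in ``diffs``.  A peak "harbors local variation" if >= 1
    SNP/indel falls within the central ``window`` bp around its midpoint.
    Empty strata yield NaN.
    """
    thr = thresholds or Thresholds()
    if isinstance(variants, VariantTable):
        variants = [variants]
    half = window // 2
    has_var = pd.Series(False, index=peaks["peak_id"].astype(str))
    for pid, chrom, start, end in peaks[["peak_id", "chrom", "start", "end"]].itertuples(index=False):
        mid = (int(start) + int(end)) // 2
        has_var[str(pid)] = any(
            vt.count_overlapping(chrom, mid - half, mid + half) > 0 for vt in variants
        )
    row_names = ["similar"] + [f">{c:g}" for c in cutoffs]
    out = pd.DataFrame(index=row_names, columns=list(diffs), dtype=float)
    for assay, diff in diffs.items():
        common = has_var.index.intersection(diff.index)
        d = diff.loc[common]
        hv = has_var.loc[common]
        strata = {
            "similar": (~d["significant"]) & (d["log2fc"].abs() <= thr.fc_threshold)
        }
        for c in cutoffs:
            strata[f">{c:g}"] = d["significant"] & (2.0 ** d["log2fc"].abs() > c)
        for row, mask in strata.items():
            n = int(mask.sum())
            out.loc[row, assay] = 100.0 * hv[mask].mean() if n else np.nan
    out.index.name = "fold_change"
    return out
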