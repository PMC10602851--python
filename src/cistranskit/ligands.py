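"""Ligand activity scoring from a ligand--target prior matrix.

Given a prior matrix of regulatory-potential scores (ligands x genes), the
activity of a ligand for a strain is the Pearson correlation between its
prior scores and the binary indicator of membership in that strain's
differentially expressed target set, computed over the union of targets and
an expressed-gene background.  Candidate ligands must be expressed by a
sender cell of the hepatic niche and their receptor by the receiver cells,
both strictly above a 10-TPM floor; selected hormonal/metabolic ligands
without expression data can be flagged exempt.  Scores are normalized to
z-scores across strains for display.

The prior matrix is an input, not computed here: the bespoke analysis is the
filtering and correlation scoring, not the network propagation behind the
prior.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from cistranskit.config import Thresholds


def filter_candidate_ligands(
    prior: pd.DataFrame,
    receptor_map: pd.DataFrame,
    sender_tpm: pd.DataFrame,
    receiver_tpm: pd.Series,
    tpm_floor: float = 10.0,
    exempt: set[str] | None = None,
) -> list[str]:
    """Ligands passing the sender and receiver expression filters.

    A ligand is retained iff some sender cell type expresses it at strictly
    more than ``tpm_floor`` TPM AND its mapped receptor is expressed by the
    receiver at strictly more than ``tpm_floor`` TPM.  Exempt ligands are
    always retained (if present in the prior).  Ligands absent from the
    prior are skipped with a warning; ligands without a mapped receptor are
    excluded unless exempt.
    """
    exempt = exempt or set()
    rmap = dict(zip(receptor_map["ligand"], receptor_map["receptor"]))
    keep = []
    for lig in pd.unique(pd.concat([receptor_map["ligand"], pd.Series(sorted(exempt))], ignore_index=True)):
        if lig not in prior.index:
            warnings.warn(f"ligand {lig!r} absent from prior matrix; skipped")
            continue
        if lig in exempt:
            keep.append(lig)
            continue
        sender_ok = lig in sender_tpm.index and bool((sender_tpm.loc[lig] > tpm_floor).any())
        rec = rmap.get(lig)
        receiver_ok = rec is not None and rec in receiver_tpm.index and receiver_tpm[rec] > tpm_floor
        if sender_ok and receiver_ok:
            keep.append(lig)
    return keep


def define_target_and_background(
    diffs: list[pd.DataFrame],
    receiver_tpm: pd.Series,
    thresholds: Thresholds | None = None,
    target_lfc: float = 2.0,
    tpm_floor: float = 10.0,
) -> tuple[set[str], set[str]]:
    """Target and background gene sets for one strain.

    Targets: genes significantly higher in the strain (padj < alpha and
    log2fc > ``target_lfc``) in ANY of the supplied pairwise comparisons
    (log2fc oriented strain-over-other), expressed above ``tpm_floor`` in the
    receiver.  Background: every receiver gene above ``tpm_floor``.
    """
    thr = thresholds or Thresholds()
    expressed = set(receiver_tpm.index[receiver_tpm > tpm_floor])
    targets: set[str] = set()
    for d in diffs:
        hit = d.index[
            (d["padj"] < thr.alpha).fillna(False) & (d["log2fc"] > target_lfc)
        ]
        targets |= set(hit)
    targets &= expressed
    if not targets:
        raise ValueError("empty target set after filtering")
    return targets, expressed


def score_ligand_activity(
    prior: pd.DataFrame, targets: set[str], background: set[str]
) -> pd.Series:
    """Pearson activity score per ligand.

    Over the union of background and targets, r = Pearson(prior scores,
    target-membership indicator).  Ligands with zero-variance prior vectors
    score NaN.
    """
    if len(background) < 10:
        raise ValueError("background must contain >= 10 genes")
    universe = sorted(set(background) | set(targets))
    genes = [g for g in universe if g in prior.columns]
    indicator = np.array([g in targets for g in genes], dtype=float)
    mat = prior[genes].to_numpy(dtype=float)
    ind_c = indicator - indicator.mean()
    mat_c = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((mat_c**2).sum(axis=1) * (ind_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mat_c @ ind_c) / denom
    r[denom == 0] = np.nan
    return pd.Series(r, index=prior.index, name="pearson")


def zscore_across_strains(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-score each ligand's activity across strains (rows: ligands, columns: strains).

    Per ligand, z = (score - mean over strains) / sd over strains.  Ligands
    scored in fewer than two strains, or with zero spread, get NaN with a
    warning.
    """
    if scores.shape[1] < 2:
        warnings.warn("z-scores need >= 2 strains; returning NaN")
        return scores * np.nan
    mean = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    degenerate = (sd == 0) | scores.isna().any(axis=1)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} ligand(s) with degenerate score spread; NaN z-scores")
    z = scores.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    return z
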