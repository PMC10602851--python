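"""Cis/trans classification, autonomy decomposition, and basal-state analysis.

The core inference of the package.  A feature with a parental (F0) strain
difference that is reproduced as allelic imbalance inside an F1 hybrid
nucleus is *cis*-regulated (the causal variant travels with the allele); an
F0 difference without allelic imbalance is *trans*; allelic imbalance without
an F0 difference is "mixed" (compensated or context-dependent); neither is
"same".  Features significant in both comparisons but with opposite signs
get an explicit "discordant" class rather than being mislabeled cis.

Trans effects are then decomposed using chimera designs in which donor cells
of different genotypes share one host liver: a strain difference that
disappears when both genotypes experience the same environment (F0-NSG) is
environmental (non-cell-autonomous); one that persists in F0-NSG but shows
no allelic imbalance in F1-NSG donor cells is cell-autonomous (intracellular
signaling or transcription-factor activity).

Stimulus responses are classed per strain, and strain-specific responses are
partitioned by the non-responding strain's baseline (low / equal / high
basal); the association between basal state and cis/trans regulation is
tested with a Pearson chi-squared statistic (no continuity correction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

REGULATION_CLASS_ORDER = ("cis", "trans", "mixed", "same", "discordant")
AUTONOMY_CLASS_ORDER = ("cis", "trans_environmental", "trans_cellautonomous", "unresolved")


def _direction(sig: pd.Series, lfc: pd.Series, labels: tuple[str, str]) -> pd.Series:
    d = pd.Series("none", index=sig.index, dtype=object)
    d[sig & (lfc > 0)] = labels[0]
    d[sig & (lfc < 0)] = labels[1]
    return d


def classify_cis_trans(
    f0: pd.DataFrame,
    f1_allelic: pd.DataFrame,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Classify features by the F0-vs-F1-allelic two-axis scheme.

    Both inputs are DiffResults (``log2fc``, ``significant``) with log2fc
    oriented the same way (strain/allele A over B).  Features missing from
    either input are excluded with a warning.  Classes:

    - cis: significant in F0 AND in F1 alleles, same sign
    - trans: significant in F0 only
    - mixed: significant in F1 alleles only
    - same: significant in neither
    - discordant: significant in both, opposite signs

    Returns a DataFrame with ``cls, direction, f0_log2fc, f1_allelic_log2fc``
    plus a magnitude-ratio annotation (allelic / parental |log2fc|).
    """
    common = f0.index.intersection(f1_allelic.index)
    dropped = len(f0.index.union(f1_allelic.index)) - len(common)
    if dropped:
        warnings.warn(f"{dropped} feature(s) missing from one input; excluded")
    a = f0.loc[common]
    b = f1_allelic.loc[common]
    sig0 = a["significant"].astype(bool)
    sig1 = b["significant"].astype(bool)
    same_sign = np.sign(a["log2fc"]) == np.sign(b["log2fc"])

    cls = pd.Series("same", index=common, dtype=object)
    cls[sig0 & ~sig1] = "trans"
    cls[~sig0 & sig1] = "mixed"
    cls[sig0 & sig1 & same_sign] = "cis"
    cls[sig0 & sig1 & ~same_sign] = "discordant"

    direction = pd.Series("none", index=common, dtype=object)
    use_f0 = cls.isin(["cis", "trans"])
    use_f1 = cls == "mixed"
    direction[use_f0] = _direction(sig0, a["log2fc"], labels)[use_f0]
    direction[use_f1] = _direction(sig1, b["log2fc"], labels)[use_f1]

    with np.errstate(divide="ignore", invalid="ignore"):
        mag_ratio = np.abs(b["log2fc"]) / np.abs(a["log2fc"])
    out = pd.DataFrame(
        {
            "cls": cls,
            "direction": direction,
            "f0_log2fc": a["log2fc"],
            "f1_allelic_log2fc": b["log2fc"],
            "allelic_magnitude_ratio": mag_ratio,
        }
    )
    out.index.name = "feature_id"
    return out


def combine_regulation_calls(
    primary: pd.DataFrame, fallback: pd.DataFrame
) -> pd.DataFrame:
    """Merge cis/trans calls made under two conditions of a stimulus design.

    A strain-specific response can surface its parental difference in either
    condition: low- and equal-basal features differ between strains after
    treatment, while high-basal features differ only at baseline (the
    non-responder sits at the induced level from the start).  For each
    feature the call from ``primary`` (typically the treated condition) is
    kept whenever it is informative (cis, trans or discordant — i.e. the F0
    contrast was significant); otherwise the ``fallback`` (baseline) call is
    used if informative; otherwise the primary call stands.  An extra
    ``condition`` column records which input supplied each call.
    """
    informative = ("cis", "trans", "discordant")
    common = primary.index.intersection(fallback.index)
    out = primary.loc[common].copy()
    use_fb = (~out["cls"].isin(informative)) & fallback.loc[common, "cls"].isin(informative)
    out.loc[use_fb] = fallback.loc[common].loc[use_fb]
    out["condition"] = np.where(use_fb, "fallback", "primary")
    return out


def classify_autonomy(
    f0: pd.DataFrame,
    f0_nsg: pd.DataFrame,
    f1_nsg_allelic: pd.DataFrame,
    strain_specific: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Decompose strain-specific F0 features into cis / environmental /
    cell-autonomous.

    Evaluated as a decision list, resolving cis first via allelic imbalance:

    1. cis: significant allelic bias in F1-NSG donor cells, same sign as F0
    2. trans_environmental: no significant difference in F0-NSG (the strain
       difference vanished once both genotypes shared one environment)
    3. trans_cellautonomous: significant in F0-NSG but no allelic imbalance
       in F1-NSG (the difference persists yet is not allele-linked)
    4. unresolved: everything else

    Only features significant in F0 (or listed in ``strain_specific``) are
    classified.  Returns (calls, proportions of environmental vs
    cell-autonomous among trans calls).
    """
    for name, df in [("f0_nsg", f0_nsg), ("f1_nsg_allelic", f1_nsg_allelic)]:
        if df is None or not len(df):
            raise ValueError(f"missing design arm: {name}")
    if strain_specific is None:
        eligible = f0.index[f0["significant"].astype(bool)]
    else:
        eligible = pd.Index(strain_specific[strain_specific].index)
    eligible = eligible.intersection(f0_nsg.index).intersection(f1_nsg_allelic.index)

    a = f0.loc[eligible]
    nsg = f0_nsg.loc[eligible]
    al = f1_nsg_allelic.loc[eligible]
    sig_nsg = nsg["significant"].astype(bool)
    sig_al = al["significant"].astype(bool)
    same_sign = np.sign(al["log2fc"]) == np.sign(a["log2fc"])

    cls = pd.Series("unresolved", index=eligible, dtype=object)
    is_cis = sig_al & same_sign
    cls[is_cis] = "cis"
    env = ~is_cis & ~sig_nsg
    cls[env] = "trans_environmental"
    cauto = ~is_cis & sig_nsg & ~sig_al
    cls[cauto] = "trans_cellautonomous"

    calls = pd.DataFrame(
        {
            "cls": cls,
            "f0_log2fc": a["log2fc"],
            "f0_nsg_log2fc": nsg["log2fc"],
            "f1_nsg_allelic_log2fc": al["log2fc"],
        }
    )
    calls.index.name = "feature_id"
    n_env = int((cls == "trans_environmental").sum())
    n_cauto = int((cls == "trans_cellautonomous").sum())
    n_trans = n_env + n_cauto
    props = pd.Series(
        {
            "trans_environmental": n_env / n_trans if n_trans else np.nan,
            "trans_cellautonomous": n_cauto / n_trans if n_trans else np.nan,
        }
    )
    return calls, props


def classify_stimulus_response(
    response_a: pd.DataFrame,
    response_b: pd.DataFrame,
    strains: tuple[str, str] = ("A", "B"),
) -> pd.Series:
    """Per-feature stimulus-response label from per-strain treated-vs-basal tests.

    ``response_a`` / ``response_b`` are DiffResults of treated over basal in
    each strain.  Labels: ``shared_response`` (significant in both, same
    sign), ``{strain}_specific`` (significant in exactly one), and
    ``nonresponsive``.  Both-significant opposite-sign features are labeled
    ``shared_discordant``.
    """
    common = response_a.index.intersection(response_b.index)
    a, b = response_a.loc[common], response_b.loc[common]
    siga, sigb = a["significant"].astype(bool), b["significant"].astype(bool)
    same_sign = np.sign(a["log2fc"]) == np.sign(b["log2fc"])
    lab = pd.Series("nonresponsive", index=common, dtype=object)
    lab[siga & ~sigb] = f"{strains[0]}_specific"
    lab[~siga & sigb] = f"{strains[1]}_specific"
    lab[siga & sigb & same_sign] = "shared_response"
    lab[siga & sigb & ~same_sign] = "shared_discordant"
    return lab


def partition_basal_state(
    response_labels: pd.Series,
    basal_between_strains: pd.DataFrame,
    strains: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Partition strain-specific responders by the non-responder's baseline.

    ``basal_between_strains`` is a DiffResult of untreated strain A over
    strain B.  For a feature responsive only in strain X with non-responder
    Y:

    - equal_basal: no significant basal difference
    - high_basal: Y significantly higher than X at baseline
    - low_basal: Y significantly lower than X at baseline

    Features that are not strain-specific responders are rejected.
    """
    specific = response_labels.isin([f"{s}_specific" for s in strains])
    idx = response_labels.index[specific].intersection(basal_between_strains.index)
    if len(idx) == 0:
        raise ValueError("no strain-specific responsive features supplied")
    basal = basal_between_strains.loc[idx]
    sig = basal["significant"].astype(bool)
    lfc = basal["log2fc"]  # log2(A / B)
    responsive = response_labels.loc[idx].str.replace("_specific", "", regex=False)

    # orient log2fc as (non-responder over responder): flip where A responds
    a_resp = (responsive == strains[0]).to_numpy()
    oriented = np.where(a_resp, -lfc.to_numpy(), lfc.to_numpy())
    nonresp_higher = sig.to_numpy() & (oriented > 0)
    nonresp_lower = sig.to_numpy() & (oriented < 0)

    cat = pd.Series("equal_basal", index=idx, dtype=object)
    cat[nonresp_higher] = "high_basal"
    cat[nonresp_lower] = "low_basal"
    out = pd.DataFrame({"category": cat, "responsive_strain": responsive})
    out.index.name = "feature_id"
    return out


def basal_cistrans_association(
    basal: pd.DataFrame, regulation: pd.DataFrame,
    reg_classes: tuple[str, ...] = ("cis", "trans"),
) -> dict:
    """Pearson chi-squared test of basal category x regulation class.

    ``basal`` comes from :func:`partition_basal_state` (column ``category``)
    and ``regulation`` from :func:`classify_cis_trans` (column ``cls``;
    restricted to ``reg_classes``).  Returns the contingency table, chi2,
    degrees of freedom and p (no continuity correction).
    """
    common = basal.index.intersection(regulation.index)
    reg = regulation.loc[common, "cls"]
    keep = reg.isin(reg_classes)
    common = common[keep]
    if len(common) == 0:
        raise ValueError("empty intersection of basal and regulation feature sets")
    table = pd.crosstab(basal.loc[common, "category"], regulation.loc[common, "cls"])
    table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 non-empty rows and columns for the chi-squared test")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"table": table, "chi2": float(chi2), "dof": int(dof), "p": float(p)}
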