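"""Gene-signature scoring and percentile stratification of samples.

Two scoring conventions are supported: the sum of ln(TPM+1) over a gene set
(optionally min-max rescaled to 0–100 across the cohort), and the mean of
per-gene cohort z-scores. Stratification uses type-7 (linearly interpolated)
quantiles with strict-above/strict-below membership, which reproduces the
52-of-208 and 21-of-208 extreme-group sizes of a quartile/decile split.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ScoreVector

__all__ = [
    "sumlog_score",
    "scale_0_100",
    "meanz_score",
    "stratify_extremes",
    "four_group_labels",
    "threshold_overlap",
    "TiesAtCutError",
]

FOUR_GROUPS = ("APUC6hi_ARhi", "APUC6hi_ARlo", "APUC6lo_ARhi", "APUC6lo_ARlo")


class TiesAtCutError(ValueError):
    """Raised when tied scores sit exactly on a percentile cut."""


def _present_genes(m: ExpressionMatrix, gene_set: list[str], set_name: str) -> list[str]:
    present = [g for g in gene_set if g in m.values.index]
    missing = [g for g in gene_set if g not in m.values.index]
    if not present:
        raise ValueError(f"no genes of set {set_name!r} present in the matrix")
    if missing:
        warnings.warn(f"genes of set {set_name!r} missing from matrix: {missing}")
    return present


def sumlog_score(
    m: ExpressionMatrix, gene_set: list[str], set_name: str = ""
) -> ScoreVector:
    """Per-sample signature score: Σ_g∈set ln(TPM_g + 1)."""
    if m.unit != "TPM":
        raise ValueError(f"sumlog_score expects TPM, got {m.unit}")
    present = _present_genes(m, gene_set, set_name)
    scores = np.log1p(m.values.loc[present]).sum(axis=0)
    return ScoreVector(scores=scores, kind="sumlog_raw", gene_set_name=set_name)


def scale_0_100(s: ScoreVector) -> ScoreVector:
    """Min-max rescale scores to [0, 100] across the cohort."""
    lo, hi = float(s.scores.min()), float(s.scores.max())
    if hi == lo:
        raise ValueError("constant scores cannot be scaled to 0-100")
    scaled = (s.scores - lo) / (hi - lo) * 100.0
    return ScoreVector(
        scores=scaled,
        kind="scaled_0_100",
        gene_set_name=s.gene_set_name,
        scaling_meta={"min": lo, "max": hi},
    )


def meanz_score(m: ExpressionMatrix, gene_set: list[str], set_name: str = "") -> ScoreVector:
    """Per-sample mean of per-gene cohort z-scores over the set.

    Each gene is standardised across samples (ddof=1); the score is the mean
    of these z-scores within the set, so it averages ≈ 0 over the cohort.
    """
    present = _present_genes(m, gene_set, set_name)
    sub = m.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant genes in set {set_name!r}: {bad}")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return ScoreVector(scores=z.mean(axis=0), kind="mean_z", gene_set_name=set_name)


def _check_cut(scores: pd.Series, q: float) -> None:
    tied = scores.index[scores == q]
    if len(tied) > 1:
        raise TiesAtCutError(f"tied scores at cut value {q!r}: {list(tied)}")


def stratify_extremes(s: ScoreVector, pct: float = 0.25) -> pd.Series:
    """Label samples HIGH / LOW / MID by the extreme percentiles of the score.

    HIGH = strictly above the type-7 (1 − pct) quantile; LOW = strictly below
    the pct quantile; everything else MID. Ties sitting exactly on a cut are
    an error rather than an arbitrary inclusion.
    """
    if not 0 < pct < 0.5:
        raise ValueError(f"pct must be in (0, 0.5), got {pct}")
    x = s.scores
    q_lo = float(np.quantile(x.to_numpy(), pct))
    q_hi = float(np.quantile(x.to_numpy(), 1 - pct))
    _check_cut(x, q_lo)
    _check_cut(x, q_hi)
    labels = pd.Series("MID", index=x.index, dtype=object)
    labels[x > q_hi] = "HIGH"
    labels[x < q_lo] = "LOW"
    return labels


def four_group_labels(apuc: ScoreVector, ar: ScoreVector, pct: float = 0.25) -> pd.Series:
    """Combine two HIGH/LOW stratifications into four expression groups.

    Samples with a MID call on either score are UNASSIGNED. Group names
    follow the module-score × AR-score convention (e.g. ``APUC6hi_ARlo``).
    """
    if set(apuc.scores.index) != set(ar.scores.index):
        raise ValueError("score vectors cover different sample sets")
    ar_scores = ScoreVector(
        scores=ar.scores.reindex(apuc.scores.index), kind=ar.kind, gene_set_name=ar.gene_set_name
    )
    la = stratify_extremes(apuc, pct)
    lb = stratify_extremes(ar_scores, pct)
    name = {
        ("HIGH", "HIGH"): "APUC6hi_ARhi",
        ("HIGH", "LOW"): "APUC6hi_ARlo",
        ("LOW", "HIGH"): "APUC6lo_ARhi",
        ("LOW", "LOW"): "APUC6lo_ARlo",
    }
    out = pd.Series(
        [name.get((a, b), "UNASSIGNED") for a, b in zip(la, lb)], index=la.index, dtype=object
    )
    return out


def threshold_overlap(
    a: ScoreVector, b: ScoreVector, pct: float = 0.25
) -> tuple[int, int, int]:
    """Counts of samples above each score's (1 − pct) quantile and above both."""
    if set(a.scores.index) != set(b.scores.index):
        raise ValueError("score vectors cover different sample sets")
    xb = b.scores.reindex(a.scores.index)
    q_a = float(np.quantile(a.scores.to_numpy(), 1 - pct))
    q_b = float(np.quantile(xb.to_numpy(), 1 - pct))
    _check_cut(a.scores, q_a)
    _check_cut(xb, q_b)
    in_a = a.scores > q_a
    in_b = xb > q_b
    return int(in_a.sum()), int(in_b.sum()), int((in_a & in_b).sum())
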