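"""Survival analysis: claims-gap event imputation, Kaplan-Meier, log-rank,
and Cox proportional hazards.

Real-world overall survival from claims data: day 0 is treatment initiation;
a patient with no claim for more than ``gap_days`` (default 100) before the
data cutoff is assumed dead at their last claim, otherwise they are censored
at the last claim. Months are days / 30.44.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .containers import ClinicalTable

__all__ = [
    "impute_events_from_claims",
    "km_estimate",
    "logrank",
    "cox_hr",
    "compare_groups_os",
    "KMResult",
    "SurvivalFit",
    "DAYS_PER_MONTH",
]

DAYS_PER_MONTH = 30.44


def impute_events_from_claims(
    claims: list[datetime.date],
    day0: datetime.date,
    data_cutoff: datetime.date,
    gap_days: int = 100,
) -> tuple[float, int]:
    """Apply the claims-gap rule to one patient's claim history.

    Returns (os_months, event): death is assumed (event = 1, at the last
    claim) when the gap from last claim to cutoff strictly exceeds
    ``gap_days``; otherwise the patient is censored at the last claim.
    """
    if not claims:
        raise ValueError("empty claim list")
    claims = sorted(claims)
    if claims[0] < day0:
        raise ValueError(f"claim {claims[0]} precedes day 0 ({day0})")
    last = claims[-1]
    if data_cutoff < last:
        raise ValueError(f"data cutoff {data_cutoff} precedes last claim {last}")
    gap = (data_cutoff - last).days
    event = 1 if gap > gap_days else 0
    os_months = (last - day0).days / DAYS_PER_MONTH
    return os_months, event


@dataclass
class KMResult:
    curve: pd.DataFrame  # columns: time, n_at_risk, survival
    median_os: float | None  # None when the curve never reaches 0.5


def km_estimate(t, e) -> KMResult:
    """Kaplan-Meier product-limit estimate with median OS.

    The median is the first time at which survival drops to ≤ 0.5 and is
    ``None`` ("not reached") when the curve never gets there.
    """
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    curve = pd.DataFrame(
        {"time": surv.index.to_numpy(), "n_at_risk": at_risk.to_numpy(),
         "survival": surv.to_numpy()}
    )
    med = kmf.median_survival_time_
    median_os = None if np.isinf(med) else float(med)
    return KMResult(curve=curve, median_os=median_os)


def logrank(t, e, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    ga = group == levels[0]
    res = logrank_test(t[ga], t[~ga], event_observed_A=e[ga], event_observed_B=e[~ga])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(t, e, group) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox PH hazard ratio for a binary covariate (Efron ties).

    Returns (hr, (ci_lo, ci_hi), p) with hr = exp(β) for group == 1 relative
    to group == 0 and the 95% CI = exp(β ± 1.96·se).
    """
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=int)
    g = np.asarray(group, dtype=int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be coded 0/1")
    for level in (0, 1):
        if e[g == level].sum() == 0:
            raise ValueError(
                f"no events in group {level}: partial likelihood is monotone"
            )
    df = pd.DataFrame({"T": t, "E": e, "g": g})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    beta = float(cph.params_["g"])
    se = float(cph.standard_errors_["g"])
    p = float(cph.summary.loc["g", "p"])
    return float(np.exp(beta)), (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))), p


@dataclass
class SurvivalFit:
    contrast: tuple[str, str]
    stratum: str
    n: dict = field(default_factory=dict)
    km: dict = field(default_factory=dict)  # label -> KMResult
    median_os: dict = field(default_factory=dict)
    hr: float = np.nan
    hr_ci: tuple[float, float] = (np.nan, np.nan)
    hr_p: float = np.nan
    logrank_chi2: float = np.nan
    logrank_p: float = np.nan


def compare_groups_os(
    clin: ClinicalTable,
    labels: pd.Series | dict,
    contrasts: list[tuple[str, str]],
    strata: str | None = None,
) -> list[SurvivalFit]:
    """KM + log-rank + Cox for each (label_a, label_b) contrast.

    The hazard ratio is for label_a relative to label_b. When ``strata``
    names a clinical column (biopsy_site, histology, hormone_status), each
    contrast is refit separately within every stratum level.
    """
    labels = pd.Series(labels)
    df = clin.table.copy()
    df = df.loc[[s for s in df.index if s in labels.index]]
    df["_label"] = labels.reindex(df.index)

    if strata is not None:
        if strata not in df.columns:
            raise ValueError(f"unknown stratification column {strata!r}")
        strata_levels = [(str(v), df[df[strata] == v]) for v in df[strata].unique()]
    else:
        strata_levels = [("all", df)]

    fits: list[SurvivalFit] = []
    for stratum_name, sub in strata_levels:
        for la, lb in contrasts:
            mask_a = sub["_label"] == la
            mask_b = sub["_label"] == lb
            if mask_a.sum() == 0 or mask_b.sum() == 0:
                raise ValueError(
                    f"contrast ({la}, {lb}) missing a group in stratum {stratum_name!r}"
                )
            pair = sub[mask_a | mask_b]
            t = pair["os_months"].to_numpy(dtype=float)
            e = pair["event"].to_numpy(dtype=int)
            g = (pair["_label"] == la).to_numpy(dtype=int)
            fit = SurvivalFit(contrast=(la, lb), stratum=stratum_name)
            for label, mask in ((la, g == 1), (lb, g == 0)):
                km = km_estimate(t[mask], e[mask])
                fit.km[label] = km
                fit.median_os[label] = km.median_os
                fit.n[label] = int(mask.sum())
            fit.logrank_chi2, fit.logrank_p = logrank(t, e, g)
            fit.hr, fit.hr_ci, fit.hr_p = cox_hr(t, e, g)
            fits.append(fit)
    return fits
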