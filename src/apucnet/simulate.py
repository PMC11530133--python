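"""Synthetic multi-cohort RNA-seq and claims-based survival generator.

Expression follows a Gaussian copula: a latent multivariate normal with a
block target correlation — a planted gene module whose mutual correlation
rises across disease stages (benign → primary → metastatic), a steroid
hormone receptor (SHR) group positively cross-correlated with the module, an
AR-axis group uncorrelated (or anti-correlated) with it, and independent
background genes — pushed through exp() to log-normal abundances and
rescaled to TPM. Because exp() is monotone, the latent correlations survive
as Spearman correlations in the observed data.

Survival emulates an insurance-claims repository: exponential death times
per expression-defined group, claims emitted at a fixed cadence until death
or the data cutoff. The recorded (os, event) are what the claims-gap rule
can observe — deaths within the gap of the cutoff are indistinguishable from
live patients and are recorded as censored, exactly as in real claims data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TPM_SUM, ClinicalTable, ExpressionMatrix
from .expression_io import write_clinical, write_expression
from .survival import DAYS_PER_MONTH

__all__ = [
    "SimulationConfig",
    "generate_expression",
    "generate_clinical",
    "simulate_survival",
    "generate_study_bundle",
    "STAGES",
]

STAGES = ("benign", "primary", "metastatic")

APUC6 = ["HSD3B1", "HSD3B2", "CYP11A1", "CYP11B1", "CYP17A1", "CYP3A43"]
SHR3 = ["ESR1", "ESR2", "PGR"]
AR_AXIS = ["AR", "FOXA1", "HOXB13"]

LN2 = float(np.log(2.0))


def _per_stage(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in STAGES}
    return {s: float(value) for s in STAGES}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Stage sample sizes and the module correlation ladder mirror the public
    cohorts the analysis is designed for (benign n=245, primary n=493,
    metastatic n=208; latent module rho 0.1 / 0.4 / 0.8). Group hazards are
    monthly exponential rates whose medians (ln 2 / rate) reproduce the
    40.4 / 21.3 / 9.4-month ordering of the protective, adverse and
    neuroendocrine groups.
    """

    n_genes: int = 60
    n_samples: dict = field(
        default_factory=lambda: {"benign": 245, "primary": 493, "metastatic": 208}
    )
    module_genes: list = field(default_factory=lambda: list(APUC6))
    module_rho: dict = field(
        default_factory=lambda: {"benign": 0.1, "primary": 0.4, "metastatic": 0.8}
    )
    shr_genes: list = field(default_factory=lambda: list(SHR3))
    shr_within_rho: float = 0.5
    shr_module_rho: dict = field(
        default_factory=lambda: {"benign": 0.1, "primary": 0.3, "metastatic": 0.5}
    )
    ar_genes: list = field(default_factory=lambda: list(AR_AXIS))
    ar_within_rho: float = 0.5
    ar_module_rho: dict = field(
        default_factory=lambda: {"benign": 0.0, "primary": 0.0, "metastatic": 0.0}
    )
    background_rho: float = 0.2  # weak global co-expression among background genes
    log_mu_mean: float = 2.0
    log_mu_sd: float = 1.0
    log_sigma: float = 1.0
    hazard_monthly: dict = field(
        default_factory=lambda: {
            "APUC6hi_ARlo": LN2 / 40.4,
            "APUC6lo_ARhi": LN2 / 21.3,
            "NEPC": LN2 / 9.4,
            "APUC6hi_ARhi": LN2 / 30.0,
            "APUC6lo_ARlo": LN2 / 30.0,
            "UNASSIGNED": LN2 / 30.0,
        }
    )
    censor_rate: float = 0.2
    claims_interval_days: int = 30
    gap_days: int = 100
    accrual_months: float = 36.0
    followup_months: float = 84.0
    base_date: datetime.date = datetime.date(2015, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        self.module_rho = _per_stage(self.module_rho)
        self.shr_module_rho = _per_stage(self.shr_module_rho)
        self.ar_module_rho = _per_stage(self.ar_module_rho)
        if any(h < 0 for h in self.hazard_monthly.values()):
            raise ValueError("hazards must be >= 0")
        n_special = len(self.module_genes) + len(self.shr_genes) + len(self.ar_genes)
        if self.n_genes < n_special:
            raise ValueError(
                f"n_genes ({self.n_genes}) smaller than the named gene groups ({n_special})"
            )
        for stage in STAGES:  # fail fast on an invalid correlation target
            self.target_correlation(stage)

    @property
    def gene_ids(self) -> list[str]:
        n_bg = self.n_genes - len(self.module_genes) - len(self.shr_genes) - len(self.ar_genes)
        background = [f"BG{i + 1:04d}" for i in range(n_bg)]
        return list(self.module_genes) + list(self.shr_genes) + list(self.ar_genes) + background

    def target_correlation(self, stage: str) -> np.ndarray:
        """Latent block correlation matrix for one stage; validated PSD."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        g = self.n_genes
        nm, ns, na = len(self.module_genes), len(self.shr_genes), len(self.ar_genes)
        sigma = np.eye(g)

        def fill_block(rows, cols, value):
            sigma[np.ix_(rows, cols)] = value

        mod = range(0, nm)
        shr = range(nm, nm + ns)
        ar = range(nm + ns, nm + ns + na)
        bg = range(nm + ns + na, g)
        fill_block(bg, bg, self.background_rho)
        fill_block(mod, mod, self.module_rho[stage])
        fill_block(shr, shr, self.shr_within_rho)
        fill_block(ar, ar, self.ar_within_rho)
        fill_block(mod, shr, self.shr_module_rho[stage])
        fill_block(shr, mod, self.shr_module_rho[stage])
        fill_block(mod, ar, self.ar_module_rho[stage])
        fill_block(ar, mod, self.ar_module_rho[stage])
        np.fill_diagonal(sigma, 1.0)
        if np.linalg.eigvalsh(sigma).min() < -1e-8:
            raise ValueError(
                f"target correlation for stage {stage!r} is not positive semi-definite"
            )
        return sigma


def generate_expression(cfg: SimulationConfig, stage: str) -> ExpressionMatrix:
    """TPM matrix for one stage: log-normal with the stage's latent blocks."""
    sigma = cfg.target_correlation(stage)
    n = cfg.n_samples[stage]
    rng = np.random.default_rng([cfg.seed, STAGES.index(stage)])
    # jitter keeps Cholesky stable when a block is exactly singular
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(cfg.n_genes))
    z = chol @ rng.standard_normal((cfg.n_genes, n))
    mu = rng.normal(cfg.log_mu_mean, cfg.log_mu_sd, size=cfg.n_genes)
    expr = np.exp(mu[:, None] + cfg.log_sigma * z)
    expr = expr / expr.sum(axis=0, keepdims=True) * TPM_SUM
    samples = [f"{stage[:3].upper()}{i + 1:04d}" for i in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(expr, index=cfg.gene_ids, columns=samples), unit="TPM"
    )


def simulate_survival(
    n: int, hazard_monthly: float, censor_rate: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential death times with independent exponential censoring.

    The censoring rate is chosen so the expected censored fraction equals
    ``censor_rate``. Returns (time in months, event flag).
    """
    rng = np.random.default_rng(seed)
    t_death = rng.exponential(1.0 / hazard_monthly, size=n)
    if censor_rate > 0:
        c_rate = hazard_monthly * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t = np.minimum(t_death, t_cens)
    e = (t_death <= t_cens).astype(int)
    return t, e


def generate_clinical(cfg: SimulationConfig, group_labels: pd.Series | dict) -> ClinicalTable:
    """Claims-backed clinical table for labelled samples.

    Each patient enters uniformly over the accrual window; death is
    exponential at the group's monthly hazard; claims arrive every
    ``claims_interval_days`` until death or the data cutoff. The recorded
    (os_months, event) apply the claims-gap rule at generation time, since a
    repository cannot observe deaths within the gap of the cutoff.
    """
    group_labels = pd.Series(group_labels)
    unknown = sorted(set(group_labels.unique()) - set(cfg.hazard_monthly))
    if unknown:
        raise ValueError(f"groups without a configured hazard: {unknown}")
    rng = np.random.default_rng([cfg.seed, 1000])
    cutoff = cfg.base_date + datetime.timedelta(
        days=round((cfg.accrual_months + cfg.followup_months) * DAYS_PER_MONTH)
    )
    sites = ["prostate", "bone", "lymph node", "liver", "bladder", "lung"]
    rows = {}
    for sid, group in group_labels.items():
        hazard = cfg.hazard_monthly[group]
        t_death_m = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        entry_days = int(rng.integers(0, round(cfg.accrual_months * DAYS_PER_MONTH) + 1))
        day0 = cfg.base_date + datetime.timedelta(days=entry_days)
        horizon = (cutoff - day0).days
        death_day = t_death_m * DAYS_PER_MONTH
        last_obs = min(death_day, horizon)
        n_claims = int(last_obs // cfg.claims_interval_days) + 1
        claims = [
            day0 + datetime.timedelta(days=k * cfg.claims_interval_days)
            for k in range(n_claims)
        ]
        gap = (cutoff - claims[-1]).days
        event = 1 if gap > cfg.gap_days else 0
        os_months = (claims[-1] - day0).days / DAYS_PER_MONTH
        rows[sid] = {
            "os_months": os_months,
            "event": event,
            "biopsy_site": sites[int(rng.integers(len(sites)))],
            "histology": "NEPC" if group == "NEPC" else "adenocarcinoma",
            "hormone_status": "sensitive" if rng.random() < 0.6 else "castration-resistant",
            "group": group,
            "day0": day0.isoformat(),
            "data_cutoff": cutoff.isoformat(),
            "claim_dates": claims,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return ClinicalTable(table=table)


def generate_study_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a self-contained fixture: 3 stage TPM matrices, gene sets,
    labels and a claims-backed clinical table for the metastatic cohort.

    Group labels come from the generated metastatic expression itself
    (quartile stratification of the module and AR scores), with a tenth of
    the unassigned samples relabelled as NEPC so the three-way outcome
    comparison is exercised.
    """
    from .scoring import four_group_labels, sumlog_score

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mats = {}
    for stage in STAGES:
        m = generate_expression(cfg, stage)
        mats[stage] = m
        paths[stage] = outdir / f"{stage}.tsv"
        write_expression(m, paths[stage])

    gmt = outdir / "genesets.gmt"
    with open(gmt, "w") as fh:
        fh.write("APUC6\tplanted module\t" + "\t".join(cfg.module_genes) + "\n")
        fh.write("SHR\tsteroid hormone receptors\t" + "\t".join(cfg.shr_genes) + "\n")
        fh.write("AR_AXIS\tAR and cofactors\t" + "\t".join(cfg.ar_genes) + "\n")
    paths["gene_sets"] = gmt

    met = mats["metastatic"]
    apuc = sumlog_score(met, cfg.module_genes, "APUC6")
    ar = sumlog_score(met, [cfg.ar_genes[0]], "AR")
    labels = four_group_labels(apuc, ar, pct=0.25)
    rng = np.random.default_rng([cfg.seed, 2000])
    unassigned = list(labels.index[labels == "UNASSIGNED"])
    n_nepc = max(1, len(unassigned) // 10)
    for sid in rng.choice(unassigned, size=n_nepc, replace=False):
        labels[sid] = "NEPC"
    labels.rename("label").to_frame().to_csv(
        outdir / "labels.tsv", sep="\t", index_label="sample_id"
    )
    paths["labels"] = outdir / "labels.tsv"

    clin = generate_clinical(cfg, labels)
    paths["clinical"] = outdir / "clinical.tsv"
    write_clinical(clin, paths["clinical"])
    return paths
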