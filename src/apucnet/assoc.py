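"""Correlation analyses, group comparisons, BH-FDR and quartile-contrast
differential expression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "correlate",
    "correlation_matrix",
    "StratumCorrelation",
    "bh_adjust",
    "group_compare",
    "differential_expression",
]


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    method: str
    n: int
    q: float | None = None


def correlate(
    x, y, method: str = "spearman", x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Pairwise correlation with a two-sided p-value (q left unset)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 observations, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x_name, y_name, float(r), float(p), method, len(x))


@dataclass
class StratumCorrelation:
    """Gene × gene correlation matrices for one sample stratum."""

    stratum: str
    n: int
    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    def long(self) -> pd.DataFrame:
        """Upper-triangle pairs as a long table (x, y, r, p, q)."""
        genes = list(self.r.index)
        rows = []
        for i, gi in enumerate(genes):
            for gj in genes[i + 1 :]:
                rows.append(
                    {"stratum": self.stratum, "x": gi, "y": gj, "n": self.n,
                     "r": self.r.loc[gi, gj], "p": self.p.loc[gi, gj],
                     "q": self.q.loc[gi, gj]}
                )
        return pd.DataFrame(rows)


def correlation_matrix(
    m, genes: list[str], method: str = "spearman", strata: pd.Series | dict | None = None
) -> dict[str, StratumCorrelation]:
    """Per-stratum gene × gene correlation with BH adjustment.

    BH is applied within each stratum's upper triangle (one analysis family
    per matrix). Strata with fewer than 3 samples are skipped with a warning.
    """
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    if strata is None:
        groups = {"all": list(m.sample_ids)}
    else:
        strata = pd.Series(strata)
        groups = {
            str(label): list(strata.index[strata == label]) for label in strata.unique()
        }
    out: dict[str, StratumCorrelation] = {}
    for label, samples in groups.items():
        samples = [s for s in samples if s in m.values.columns]
        if len(samples) < 3:
            warnings.warn(f"stratum {label!r} has {len(samples)} samples (< 3); skipped")
            continue
        sub = m.values.loc[genes, samples]
        k = len(genes)
        r = np.eye(k)
        p = np.ones((k, k))
        pv_list, idx = [], []
        for i in range(k):
            for j in range(i + 1, k):
                res = correlate(
                    sub.iloc[i], sub.iloc[j], method=method, x_name=genes[i], y_name=genes[j]
                )
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p
                pv_list.append(res.p)
                idx.append((i, j))
        q = np.ones((k, k))
        if pv_list:
            qv = bh_adjust(np.array(pv_list))
            for (i, j), v in zip(idx, qv):
                q[i, j] = q[j, i] = v
        np.fill_diagonal(q, np.nan)
        np.fill_diagonal(p, np.nan)
        mk = lambda a: pd.DataFrame(a, index=genes, columns=genes)
        out[label] = StratumCorrelation(label, len(samples), mk(r), mk(p), mk(q))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_compare(a, b, test: str = "mannwhitney") -> tuple[float, float]:
    """Two-group comparison; returns (statistic, two-sided p).

    ``mannwhitney`` is exact (full enumeration) for small tie-free groups
    (both n ≤ 20) and uses the tie-corrected normal approximation otherwise.
    ``chi2`` expects ``a`` to be a 2×k contingency table (``b`` ignored).
    """
    if test == "chi2":
        table = np.asarray(a, dtype=float)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if test == "mannwhitney":
        pooled = np.concatenate([a, b])
        exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon_paired":
        if len(a) != len(b):
            raise ValueError("paired test requires matched vectors")
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(res.statistic):
            raise ValueError("t statistic undefined (degenerate input)")
        return float(res.statistic), float(res.pvalue)
    if test == "ttest_paired":
        if len(a) != len(b):
            raise ValueError("paired test requires matched vectors")
        res = stats.ttest_rel(a, b)
        if not np.isfinite(res.statistic):
            raise ValueError("t statistic undefined (zero-variance differences)")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def differential_expression(
    m,
    labels: pd.Series | dict,
    group_a: str = "Q1",
    group_b: str = "Q4",
    q_thresh: float = 0.001,
    lfc_thresh: float = 1.5,
) -> pd.DataFrame:
    """Per-gene quartile-contrast differential expression (group B vs A).

    logFC = log2((mean TPM in B + 1) / (mean TPM in A + 1)); p from a
    two-sided Mann-Whitney U per gene; q by BH over all genes. Genes are
    ranked by signed −log10(q) (sign of logFC), logFC breaking ties, so rank
    1 is the gene most enriched in group B — the "snake plot" order.
    """
    labels = pd.Series(labels)
    sa = [s for s in labels.index[labels == group_a] if s in m.values.columns]
    sb = [s for s in labels.index[labels == group_b] if s in m.values.columns]
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError(
            f"each group needs >= 3 samples ({group_a}: {len(sa)}, {group_b}: {len(sb)})"
        )
    va = m.values[sa].to_numpy()
    vb = m.values[sb].to_numpy()
    logfc = np.log2((vb.mean(axis=1) + 1.0) / (va.mean(axis=1) + 1.0))
    res = stats.mannwhitneyu(vb, va, axis=1, alternative="two-sided", method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    q = bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0))
    score = -np.log10(np.maximum(q, 1e-300)) * np.sign(logfc)
    df = pd.DataFrame(
        {"gene_id": m.gene_ids, "logFC": logfc, "p": p, "q": q,
         "significant": (q < q_thresh) & (np.abs(logfc) > lfc_thresh)}
    )
    order = np.lexsort((-logfc, -score))
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(1, len(df) + 1)
    df["rank"] = rank
    return df.set_index("gene_id").sort_values("rank")
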