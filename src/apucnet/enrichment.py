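"""Gene-set enrichment analysis from scratch.

Classic weighted Kolmogorov-Smirnov running-sum enrichment: walking down a
ranked gene list, the running sum rises by |stat|^w / Σ_hits |stat|^w at set
members and falls by 1/(N − N_hits) elsewhere; the enrichment score (ES) is
the signed extremum. The null is built by permutation — either random gene
sets of the same size (gene permutation) or relabelled phenotypes with
re-ranking (phenotype permutation). NES normalises each ES by the mean
magnitude of same-sign permuted ES, and the FDR compares tail fractions of
the pooled permuted NES against the observed NES, per sign family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "rank_genes",
    "snr_ranking",
    "enrichment_score",
    "gsea",
    "EnrichmentScore",
    "EnrichmentResult",
]


def rank_genes(stats: pd.Series) -> pd.Series:
    """Sort a gene → statistic series descending, tie-broken by gene id."""
    if stats.index.has_duplicates:
        dups = stats.index[stats.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in ranking: {dups}")
    if not np.isfinite(stats.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistics must be finite")
    order = sorted(stats.index, key=lambda g: (-stats[g], g))
    return stats.reindex(order)


def snr_ranking(m, labels: pd.Series | dict, group_a: str, group_b: str) -> pd.Series:
    """Signal-to-noise ranking statistic: (mean_B − mean_A) / (sd_A + sd_B).

    Standard deviations are floored at 0.2·|mean| (and at 0.2 absolute) as in
    the classic implementation, to keep low-variance genes from dominating.
    """
    labels = pd.Series(labels)
    sa = [s for s in labels.index[labels == group_a] if s in m.values.columns]
    sb = [s for s in labels.index[labels == group_b] if s in m.values.columns]
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("each phenotype needs >= 3 samples")
    va, vb = m.values[sa], m.values[sb]

    def _sd(v):
        sd = v.std(axis=1, ddof=1)
        floor = np.maximum(0.2 * v.mean(axis=1).abs(), 0.2)
        return np.maximum(sd, floor)

    stat = (vb.mean(axis=1) - va.mean(axis=1)) / (_sd(va) + _sd(vb))
    return rank_genes(stat)


@dataclass
class EnrichmentScore:
    es: float
    running: pd.Series
    leading_edge: list[str]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    fdr: float
    size: int
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)


def _es_from_arrays(stats: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, np.ndarray, int]:
    """Running-sum ES for a descending stat vector and boolean hit mask."""
    n = len(stats)
    n_hits = int(hit.sum())
    inc = np.zeros(n)
    w = np.abs(stats[hit]) ** weight
    denom = w.sum()
    if denom == 0:  # all-zero stats at hits: fall back to equal weights
        inc[hit] = 1.0 / n_hits
    else:
        inc[hit] = w / denom
    inc[~hit] = -1.0 / (n - n_hits)
    run = np.cumsum(inc)
    i_max = int(np.argmax(run))
    i_min = int(np.argmin(run))
    es = run[i_max] if abs(run[i_max]) >= abs(run[i_min]) else run[i_min]
    extremum = i_max if abs(run[i_max]) >= abs(run[i_min]) else i_min
    return float(es), run, extremum


def enrichment_score(
    ranked: pd.Series, gene_set: list[str], weight: float = 1.0
) -> EnrichmentScore:
    """Weighted KS enrichment score of a gene set against a ranked list.

    The leading edge is the set members at or before the signed extremum
    (after it, walking upward, for negative ES).
    """
    ranked = rank_genes(ranked)
    genes = np.asarray(ranked.index)
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    es, run, extremum = _es_from_arrays(ranked.to_numpy(dtype=float), hit, weight)
    if es >= 0:
        lead = [g for g, h in zip(genes[: extremum + 1], hit[: extremum + 1]) if h]
    else:
        lead = [g for g, h in zip(genes[extremum:], hit[extremum:]) if h]
    return EnrichmentScore(es=es, running=pd.Series(run, index=genes), leading_edge=lead)


def _normalize(es: float, perm: np.ndarray) -> float:
    """NES: ES divided by the mean |permuted ES| of matching sign."""
    same = perm[perm >= 0] if es >= 0 else perm[perm < 0]
    if same.size == 0:
        same = perm
    denom = np.abs(same).mean()
    return float(es / denom) if denom > 0 else 0.0


def gsea(
    ranked_or_expr,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    mode: str = "gene_perm",
    seed: int = 0,
    weight: float = 1.0,
    labels: pd.Series | None = None,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    ``gene_perm`` takes a preranked gene → statistic series and builds the
    null from random same-size gene sets; ``phenotype_perm`` takes an
    expression matrix plus two-group sample labels, ranks genes by the
    signal-to-noise statistic, and re-ranks under label permutations.
    Deterministic given ``seed``. Returns one row per set with ES, NES,
    permutation FDR, set size and leading-edge genes.
    """
    if not sets:
        raise ValueError("empty gene-set collection")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)

    if mode == "gene_perm":
        ranked = rank_genes(ranked_or_expr)
        perm_rankings = None
    elif mode == "phenotype_perm":
        if labels is None or groups is None:
            raise ValueError("phenotype_perm requires labels and groups")
        m = ranked_or_expr
        labels = pd.Series(labels)
        ranked = snr_ranking(m, labels, groups[0], groups[1])
        perm_rankings = []
        lab_values = labels.to_numpy().copy()
        for _ in range(n_perm):
            shuffled = pd.Series(rng.permutation(lab_values), index=labels.index)
            perm_rankings.append(snr_ranking(m, shuffled, groups[0], groups[1]))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    stats_arr = ranked.to_numpy(dtype=float)
    genes = np.asarray(ranked.index)
    n = len(genes)

    observed: list[EnrichmentScore] = []
    names, sizes = [], []
    perm_es: list[np.ndarray] = []
    for name, members in sets.items():
        obs = enrichment_score(ranked, members, weight=weight)
        k = int(np.isin(genes, list(members)).sum())
        names.append(name)
        sizes.append(k)
        observed.append(obs)
        pe = np.empty(n_perm)
        if mode == "gene_perm":
            for b in range(n_perm):
                hit = np.zeros(n, dtype=bool)
                hit[rng.choice(n, size=k, replace=False)] = True
                pe[b], _, _ = _es_from_arrays(stats_arr, hit, weight)
        else:
            for b, pr in enumerate(perm_rankings):
                phit = np.isin(np.asarray(pr.index), list(members))
                pe[b], _, _ = _es_from_arrays(pr.to_numpy(dtype=float), phit, weight)
        perm_es.append(pe)

    nes_obs = np.array([_normalize(o.es, pe) for o, pe in zip(observed, perm_es)])
    nes_perm = np.concatenate(
        [np.array([_normalize(e, pe) for e in pe]) for pe in perm_es]
    )

    fdr = np.empty(len(names))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            num_pool = nes_perm[nes_perm >= 0]
            obs_pool = nes_obs[nes_obs >= 0]
            num = (num_pool >= nes).mean() if num_pool.size else 0.0
            den = (obs_pool >= nes).mean()
        else:
            num_pool = nes_perm[nes_perm < 0]
            obs_pool = nes_obs[nes_obs < 0]
            num = (num_pool <= nes).mean() if num_pool.size else 0.0
            den = (obs_pool <= nes).mean()
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0

    return pd.DataFrame(
        {
            "set_name": names,
            "es": [o.es for o in observed],
            "nes": nes_obs,
            "fdr": fdr,
            "size": sizes,
            "n_perm": n_perm,
            "leading_edge": [";".join(o.leading_edge) for o in observed],
        }
    ).set_index("set_name")
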