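"""Gene Set Enrichment Analysis on ranked phenotype scores.

Genes are ranked by a per-gene phenotype score (e.g. mean day-0 acetylation,
day-5 acetylation change, day-5 expression change); a weighted
Kolmogorov-Smirnov running sum measures whether a gene set concentrates at
the top or bottom of the ranking. Walking down the list, hitting a set
member increments the sum by its |score|^alpha (normalized over set
members), a miss decrements by 1/(N - N_hit); the enrichment score ES is
the signed extremum. Significance is an empirical permutation p-value over
random same-size gene sets (equivalent to gene-label permutation when each
gene carries a single score), with the add-one convention so p is never 0.

The default is the weighted statistic (alpha = 1); alpha = 0 gives the
classic unweighted KS statistic, which is invariant under monotone score
transformations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ioformats import GeneSetCollection


@dataclass
class RankedList:
    """Genes in descending phenotype-score order (ties by gene id)."""

    genes: np.ndarray
    scores: np.ndarray
    phenotype: str
    n_missing: int = 0

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    phenotype: str
    es: float
    p_value: float
    n_permutations: int
    direction: str  # "top" or "bottom"
    n_hits: int


def rank_genes(scores: pd.Series | Mapping[str, float], phenotype: str) -> RankedList:
    """Descending stable ranking; genes with missing scores are dropped."""
    s = pd.Series(scores, dtype=float)
    n_missing = int(s.isna().sum())
    s = s.dropna()
    if s.index.has_duplicates:
        raise ValueError("duplicate gene ids in score table")
    s = s.sort_index(kind="mergesort")
    s = s.sort_values(ascending=False, kind="mergesort")
    return RankedList(genes=s.index.to_numpy(), scores=s.to_numpy(),
                      phenotype=phenotype, n_missing=n_missing)


def _hit_weights(abs_scores: np.ndarray, positions: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    """Normalized cumulative hit weights along sorted positions (... x k)."""
    if weight_exponent == 0:
        w = np.ones(positions.shape, dtype=float)
    else:
        w = abs_scores[positions] ** weight_exponent
    cw = np.cumsum(w, axis=-1)
    totals = cw[..., -1:]
    totals = np.where(totals > 0, totals, 1.0)  # all-zero scores: uniform steps
    if weight_exponent != 0:
        zero_total = cw[..., -1] == 0
        if np.any(zero_total):
            flat = np.cumsum(np.ones(positions.shape, dtype=float), axis=-1)
            cw = np.where(zero_total[..., None], flat, cw)
            totals = cw[..., -1:]
    return cw / totals


def _es_from_positions(n: int, positions: np.ndarray, abs_scores: np.ndarray,
                       weight_exponent: float) -> np.ndarray:
    """Signed ES for hit-position sets (... x k), vectorized.

    The running sum is linear between hits, so its extrema lie immediately
    after a hit (candidate maxima) or immediately before one (candidate
    minima); both are evaluated in closed form from cumulative hit weights
    and miss counts.
    """
    positions = np.sort(positions, axis=-1)
    k = positions.shape[-1]
    n_miss = n - k
    if n_miss <= 0:
        raise ValueError("gene set covers the entire ranked list")
    cw = _hit_weights(abs_scores, positions, weight_exponent)
    j = np.arange(1, k + 1, dtype=float)
    miss_dec = 1.0 / n_miss
    after = cw - (positions + 1 - j) * miss_dec
    before = np.concatenate(
        [np.zeros((*positions.shape[:-1], 1)), cw[..., :-1]], axis=-1
    ) - (positions - (j - 1)) * miss_dec
    hi = after.max(axis=-1)
    lo = np.minimum(before.min(axis=-1), 0.0)
    # ties in magnitude (within rounding) favour the positive extremum
    return np.where(hi >= -lo - 1e-12, hi, lo)


def enrichment_score(ranked: RankedList, gene_set: Iterable[str],
                     weight_exponent: float = 1.0) -> float:
    """Signed enrichment score of a gene set against a ranked list."""
    members = set(gene_set)
    hits = np.flatnonzero(np.isin(ranked.genes, list(members)))
    if len(hits) == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    es = _es_from_positions(len(ranked), hits, np.abs(ranked.scores),
                            weight_exponent)
    return float(es)


def empirical_pvalue(ranked: RankedList, gene_set: Iterable[str],
                     n_perm: int = 10000, seed: int = 0,
                     weight_exponent: float = 1.0,
                     set_name: str = "") -> EnrichmentResult:
    """Two-sided empirical p-value over random same-size gene sets,
    p = (1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    es_obs = enrichment_score(ranked, gene_set, weight_exponent)
    members = set(gene_set)
    k = int(np.isin(ranked.genes, list(members)).sum())
    n = len(ranked)
    rng = np.random.default_rng(seed)
    abs_scores = np.abs(ranked.scores)
    positions = np.empty((n_perm, k), dtype=np.intp)
    for i in range(n_perm):
        positions[i] = rng.choice(n, size=k, replace=False)
    es_perm = _es_from_positions(n, positions, abs_scores, weight_exponent)
    count = int((np.abs(es_perm) >= abs(es_obs) - 1e-15).sum())
    return EnrichmentResult(
        set_name=set_name,
        phenotype=ranked.phenotype,
        es=es_obs,
        p_value=(1 + count) / (1 + n_perm),
        n_permutations=n_perm,
        direction="top" if es_obs >= 0 else "bottom",
        n_hits=k,
    )


def enrichment_panel(score_tables: Mapping[str, pd.Series],
                     collection: GeneSetCollection, n_perm: int = 10000,
                     seed: int = 0,
                     weight_exponent: float = 1.0) -> pd.DataFrame:
    """One enrichment test per (phenotype, gene set) pair.

    No multiple-testing correction is applied: the panel is small by design
    and results are reported as raw empirical p-values.
    """
    rows = []
    for pi, (phenotype, scores) in enumerate(score_tables.items()):
        ranked = rank_genes(scores, phenotype)
        for si, (name, members) in enumerate(collection):
            res = empirical_pvalue(
                ranked, members, n_perm=n_perm,
                seed=seed + 10007 * pi + 101 * si,
                weight_exponent=weight_exponent, set_name=name,
            )
            rows.append((res.phenotype, res.set_name, res.n_hits, res.es,
                         res.direction, res.p_value, res.n_permutations))
    return pd.DataFrame(rows, columns=["phenotype", "gene_set", "n_hits", "es",
                                       "direction", "p_value", "n_permutations"])
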