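"""Coordination between acetylation change and expression change.

Three complementary views, all anchored on day 0:

* day-pair correlation matrices between summarized (mean or median over the
  14 bins) acetylation changes and expression changes, with analytic and
  structure-preserving permutation significance;
* one-dimensional canonical correlation (the maximal correlation between any
  linear combination of the 14 profile bins and the expression change, i.e.
  the multiple correlation);
* a Gaussian graphical model of the stacked spatio-temporal profile
  variables (14 bins x post-baseline days), estimated by shrinking the
  sample correlation matrix toward the identity (Schafer-Strimmer analytic
  intensity) and reading partial correlations off the standardized inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ChangeMatrices:
    """Aligned per-gene change matrices versus day 0.

    ``acet_mean``/``acet_median`` and ``expr`` are genes x post-baseline-day
    DataFrames; ``delta_profiles[d]`` is the genes x 14 per-bin change on
    day d. ``n_dropped`` counts genes excluded for lacking day-0 data.
    """

    acet_mean: pd.DataFrame
    acet_median: pd.DataFrame
    expr: pd.DataFrame
    delta_profiles: dict[int, pd.DataFrame]
    days: tuple[int, ...]
    n_dropped: int = 0

    def summary(self, which: str) -> pd.DataFrame:
        if which == "mean":
            return self.acet_mean
        if which == "median":
            return self.acet_median
        raise ValueError(f"unknown summary {which!r} (use 'mean' or 'median')")


@dataclass
class CorrelationReport:
    method: str
    summary: str
    matrix: pd.DataFrame            # (acet day, expr day)
    analytic_p: pd.DataFrame
    permutation_p: pd.DataFrame | None = None
    n_permutations: int = 0


@dataclass
class PcorResult:
    """Shrinkage partial-correlation estimate over labelled variables."""

    labels: list[str]
    pcor: np.ndarray
    shrinkage: float
    n: int
    group: str = "all"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcor, index=self.labels, columns=self.labels)


def build_changes(binned: pd.DataFrame, expr_table: pd.DataFrame) -> ChangeMatrices:
    """Assemble change matrices from ``bin_all`` output and an expression table.

    Expression replicates are averaged per (gene, day); changes are
    differences against day 0. Genes missing day 0 in either layer are
    excluded (counted in ``n_dropped``).
    """
    expr = (
        expr_table.groupby(["gene_id", "day"])["expression"].mean().unstack("day")
    )
    days_all = sorted(expr.columns)
    if 0 not in days_all:
        raise ValueError("expression table has no day 0")
    prof_days = sorted(binned.index.get_level_values("day").unique())
    genes_binned = binned.index.get_level_values("gene_id").unique()
    common = genes_binned.intersection(expr.index[expr[0].notna()])
    n_dropped = len(genes_binned.union(expr.index)) - len(common)

    post_days = tuple(d for d in prof_days if d != 0 and d in days_all)
    wide = {d: binned.xs(d, level="day").reindex(common) for d in prof_days}
    base = wide[0]
    acet_mean, acet_median, deltas = {}, {}, {}
    for d in post_days:
        delta = wide[d] - base.to_numpy()
        deltas[d] = delta
        acet_mean[d] = delta.mean(axis=1)
        acet_median[d] = delta.median(axis=1)
    e = {d: expr.loc[common, d] - expr.loc[common, 0] for d in post_days}
    return ChangeMatrices(
        acet_mean=pd.DataFrame(acet_mean),
        acet_median=pd.DataFrame(acet_median),
        expr=pd.DataFrame(e),
        delta_profiles=deltas,
        days=post_days,
        n_dropped=int(n_dropped),
    )


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def correlation_matrix(changes: ChangeMatrices, summary: str = "mean",
                       method: str = "pearson") -> CorrelationReport:
    """Correlation of acetylation change on day s with expression change on
    day t, for all day pairings, with analytic p-values.

    Zero-variance columns yield NaN entries (flagged undefined).
    """
    A = changes.summary(summary)
    E = changes.expr
    if len(A) < 3:
        raise ValueError("need at least 3 genes")
    days = changes.days
    mat = pd.DataFrame(index=days, columns=days, dtype=float)
    pv = pd.DataFrame(index=days, columns=days, dtype=float)
    for s in days:
        for t in days:
            r, p = _corr(A[s].to_numpy(), E[t].to_numpy(), method)
            mat.loc[s, t] = r
            pv.loc[s, t] = p
    mat.index.name = "acet_day"
    mat.columns.name = "expr_day"
    return CorrelationReport(method=method, summary=summary, matrix=mat,
                             analytic_p=pv)


def permutation_significance(changes: ChangeMatrices, summary: str = "mean",
                             method: str = "pearson", n_perm: int = 1000,
                             seed: int = 0) -> CorrelationReport:
    """Permutation p-values that preserve the correlation structure of genes.

    Each permutation applies one random gene relabelling to the *whole*
    expression change matrix (all days jointly), leaving the inter-day and
    inter-gene structure within each layer intact. Empirical two-sided
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    report = correlation_matrix(changes, summary=summary, method=method)
    A = changes.summary(summary).to_numpy()
    E = changes.expr.to_numpy()
    days = changes.days
    if method == "spearman":
        A = stats.rankdata(A, axis=0)
        E = stats.rankdata(E, axis=0)
    obs = np.abs(report.matrix.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(obs)
    n = A.shape[0]
    Ac = (A - A.mean(0)) / A.std(0)
    Ec = (E - E.mean(0)) / E.std(0)  # relabelling leaves column moments intact
    for _ in range(n_perm):
        r = np.abs(Ac.T @ Ec[rng.permutation(n)] / n)
        counts += r >= obs - 1e-15
    perm_p = pd.DataFrame((1 + counts) / (1 + n_perm), index=days, columns=days)
    report.permutation_p = perm_p
    report.n_permutations = n_perm
    return report


def cca_1d(change_profiles: np.ndarray | pd.DataFrame,
           expr_change: np.ndarray | pd.Series,
           ridge_eps: float = 1e-8) -> tuple[np.ndarray, float]:
    """Canonical correlation between a 14-bin profile block and a 1-D
    expression change.

    With a one-dimensional second block, CCA reduces to the multiple
    correlation: the weight vector is the least-squares regression of
    expression change on the bins, and rho = corr(X a, y). Rank-deficient
    profile matrices are ridge-regularized with ``ridge_eps`` x mean
    diagonal. The weight vector is scaled so the canonical variate X a has
    unit variance.
    """
    X = np.asarray(change_profiles, dtype=float)
    y = np.asarray(expr_change, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more genes ({n}) than bins ({p})")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    if np.linalg.matrix_rank(G) < p:
        G = G + ridge_eps * np.trace(G) / p * np.eye(p)
    a = np.linalg.solve(G, Xc.T @ yc)
    variate = Xc @ a
    sd = variate.std()
    if sd == 0 or yc.std() == 0:
        return np.zeros(p), 0.0
    rho = float(np.corrcoef(variate, yc)[0, 1])
    return a / (sd * np.sqrt(n / (n - 1))), abs(rho)


def stack_profiles(changes: ChangeMatrices) -> pd.DataFrame:
    """Genes x (14 bins x post-baseline days) matrix of change profiles with
    labels 'd{day}_b{bin}' — input for the graphical model."""
    blocks = []
    for d in changes.days:
        block = changes.delta_profiles[d].copy()
        block.columns = [f"d{d}_b{k + 1:02d}" for k in range(block.shape[1])]
        blocks.append(block)
    return pd.concat(blocks, axis=1)


def shrinkage_pcor(data: pd.DataFrame | np.ndarray,
                   shrinkage: float | None = None,
                   group: str = "all") -> PcorResult:
    """Partial correlations from a shrinkage-regularized correlation matrix.

    The sample correlation matrix R is shrunk toward the identity,
    R* = (1 - lambda) R + lambda I, with the analytic intensity
    lambda* = sum var(r_ij) / sum r_ij^2 over off-diagonal entries
    (clipped to [0, 1]); partial correlations come from the inverse Omega of
    R*: pcor_ij = -Omega_ij / sqrt(Omega_ii Omega_jj).

    ``shrinkage`` overrides the analytic intensity (0 = plain inversion,
    only valid when there are more observations than variables).
    """
    if isinstance(data, pd.DataFrame):
        labels = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        labels = [f"v{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable(s) present")
    Z = (X - X.mean(axis=0)) / sd
    R = Z.T @ Z / (n - 1)
    if shrinkage is None:
        # Schafer-Strimmer analytic intensity toward the identity target
        W = Z[:, :, None] * Z[:, None, :]           # n x p x p products
        var_r = (n / ((n - 1) ** 3)) * ((W - W.mean(axis=0)) ** 2).sum(axis=0)
        off = ~np.eye(p, dtype=bool)
        denom = (R[off] ** 2).sum()
        lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
        if not 0 <= lam <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
        if lam == 0 and n <= p:
            raise ValueError("shrinkage 0 requires more observations than variables")
    Rs = (1 - lam) * R + lam * np.eye(p)
    omega = np.linalg.inv(Rs)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = (pcor + pcor.T) / 2
    return PcorResult(labels=labels, pcor=pcor, shrinkage=lam, n=n, group=group)


def pcor_edges(result: PcorResult, significance_cutoff: float = 0.05) -> pd.DataFrame:
    """Significant partial-correlation edges.

    Fisher-z transform with effective degrees of freedom n - p - 1 (each
    coefficient conditions on the remaining p - 2 variables), two-sided
    normal p-values, BH correction across the upper triangle; an edge is
    kept iff q <= cutoff. Returns a (var_a, var_b, pcor, p, q) DataFrame.
    """
    p_vars = len(result.labels)
    df = result.n - p_vars - 1
    if df <= 0:
        raise ValueError("not enough observations for edge significance")
    iu = np.triu_indices(p_vars, k=1)
    r = np.clip(result.pcor[iu], -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(df)
    pvals = 2 * stats.norm.sf(np.abs(z))
    qvals = stats.false_discovery_control(pvals, method="bh")
    edges = pd.DataFrame({
        "var_a": [result.labels[i] for i in iu[0]],
        "var_b": [result.labels[j] for j in iu[1]],
        "pcor": result.pcor[iu],
        "p": pvals,
        "q": qvals,
    })
    return edges[edges["q"] <= significance_cutoff].reset_index(drop=True)


def edge_graph(edges: pd.DataFrame) -> nx.Graph:
    """NetworkX graph of significant edges (pcor as edge weight)."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.var_a, row.var_b, pcor=float(row.pcor), q=float(row.q))
    return g


def group_difference(pcor_a: PcorResult, pcor_b: PcorResult) -> pd.DataFrame:
    """Elementwise difference of two partial-correlation matrices over the
    same variables (e.g. differential minus non-differential genes)."""
    if pcor_a.labels != pcor_b.labels:
        raise ValueError("variable labels differ between the two results")
    return pd.DataFrame(pcor_a.pcor - pcor_b.pcor,
                        index=pcor_a.labels, columns=pcor_a.labels)
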