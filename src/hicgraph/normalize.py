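"""Poisson GLM normalization of edge counts and per-edge scoring.

Contact counts between two genes are modeled with a log-linear Poisson
regression on the product covariates of the two genes' restriction
fragments — total fragment length, GC content and mappability:

    log mu_ij = b0 + b_len * log(len_i * len_j)
                  + b_gc  * log(gc_i * gc_j)
                  + b_map * log(map_i * map_j)

A gene's ``len`` is the summed length of its overlapping fragments; its
``gc`` and ``map`` are length-weighted means, clamped to [1e-3, 1]
before the log.  The fitted model gives each edge an expected count;
the edge score is the upper-tail probability P(X >= observed | mu_ij)
with Benjamini-Hochberg adjustment across all edges of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import FragmentGeneMap, FragmentMap
from .graph import NeighborhoodGraph

__all__ = [
    "GLMFit",
    "gene_covariates",
    "edge_design",
    "fit_glm",
    "score_edges",
    "bh_adjust",
]

CLAMP = 1e-3
TERMS = ["intercept", "x_len", "x_gc", "x_map"]


@dataclass
class GLMFit:
    """Fitted Poisson GLM: coefficients, standard errors, diagnostics."""

    params: pd.Series  # indexed by TERMS
    bse: pd.Series
    deviance: float
    nobs: int
    converged: bool

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = design[["x_len", "x_gc", "x_map"]].to_numpy()
        eta = (
            self.params["intercept"]
            + X @ self.params[["x_len", "x_gc", "x_map"]].to_numpy()
        )
        return np.exp(eta)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": TERMS, "estimate": self.params.values, "se": self.bse.values}
        )


def gene_covariates(
    symbols: "list[str]",
    frag_gene_map: FragmentGeneMap,
    fragments: FragmentMap,
) -> pd.DataFrame:
    """Aggregate fragment covariates to the gene level.

    len: sum of overlapping fragment lengths; gc / mappability:
    length-weighted means.  Genes without fragments get NaN rows.
    """
    fdf = fragments.df
    lengths = fdf["length"].to_numpy(dtype=float)
    gcs = fdf["gc"].to_numpy(dtype=float)
    maps = fdf["mappability"].to_numpy(dtype=float)
    rows = []
    for sym in symbols:
        fids = np.asarray(frag_gene_map.fragments_of(sym), dtype=np.int64)
        if fids.size == 0:
            rows.append((sym, np.nan, np.nan, np.nan))
            continue
        w = lengths[fids]
        rows.append(
            (sym, w.sum(), np.average(gcs[fids], weights=w),
             np.average(maps[fids], weights=w))
        )
    return pd.DataFrame(rows, columns=["symbol", "len", "gc", "map"]).set_index("symbol")


def edge_design(
    graph: NeighborhoodGraph, gene_cov: pd.DataFrame
) -> pd.DataFrame:
    """Per-edge product covariates (log scale) plus the observed count."""
    rows = []
    for a, b in graph.edges():
        try:
            ca, cb = gene_cov.loc[a], gene_cov.loc[b]
        except KeyError as e:
            raise ValueError(f"edge {a}-{b}: missing covariates for {e.args[0]!r}")
        if ca.isna().any() or cb.isna().any():
            raise ValueError(f"edge {a}-{b}: gene without fragment covariates")
        gc_a, gc_b = np.clip([ca["gc"], cb["gc"]], CLAMP, 1.0)
        m_a, m_b = np.clip([ca["map"], cb["map"]], CLAMP, 1.0)
        rows.append(
            (
                a,
                b,
                graph.g.edges[a, b]["weight"],
                np.log(ca["len"] * cb["len"]),
                np.log(gc_a * gc_b),
                np.log(m_a * m_b),
            )
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "count", "x_len", "x_gc", "x_map"])


def fit_glm(design: pd.DataFrame, tol: float = 1e-8, maxiter: int = 100) -> GLMFit:
    """Fit the Poisson log-linear model by IRLS.

    ``design`` needs columns ``count x_len x_gc x_map``.  Raises on
    fewer than 10 observations, exactly collinear covariate pairs, or
    non-convergence.
    """
    if len(design) < 10:
        raise ValueError(f"need >= 10 observations to fit, got {len(design)}")
    y = design["count"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    X = design[["x_len", "x_gc", "x_map"]].to_numpy(dtype=float)
    cols = ["x_len", "x_gc", "x_map"]
    for i in range(3):
        for j in range(i + 1, 3):
            xi, xj = X[:, i], X[:, j]
            if np.std(xi) > 0 and np.std(xj) > 0:
                r = np.corrcoef(xi, xj)[0, 1]
                if abs(r) > 1 - 1e-10:
                    raise ValueError(f"collinear covariates: {cols[i]} and {cols[j]}")
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, Xc, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise RuntimeError(
            f"Poisson IRLS failed to converge after {maxiter} iterations "
            f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', [])})"
        )
    params = pd.Series(res.params, index=TERMS)
    bse = pd.Series(res.bse, index=TERMS)
    return GLMFit(params, bse, float(res.deviance), int(res.nobs), True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def score_edges(
    graph: NeighborhoodGraph,
    fit: GLMFit,
    gene_cov: pd.DataFrame,
    alpha: float = 0.05,
) -> NeighborhoodGraph:
    """Annotate every edge with expected count, upper-tail p and BH q.

    ``p`` is P(X >= observed | Poisson(mu_hat)), i.e. the probability of
    a contact count at least as large as seen under the covariate-only
    model; ``q`` adjusts over all edges of this graph.  Topology is
    untouched.  Edges with ``q < alpha`` are flagged significant.
    """
    if not fit.converged:
        raise ValueError("cannot score edges with an unconverged fit")
    design = edge_design(graph, gene_cov)
    if design.empty:
        return graph
    mu = fit.predict(design)
    obs = design["count"].to_numpy()
    p = stats.poisson.sf(obs - 1, mu)  # P(X >= obs)
    q = bh_adjust(p)
    for row, mu_i, p_i, q_i in zip(design.itertuples(index=False), mu, p, q):
        d = graph.g.edges[row.gene_a, row.gene_b]
        d["expected"] = float(mu_i)
        d["p"] = float(p_i)
        d["q"] = float(q_i)
        d["significant"] = bool(q_i < alpha)
    return graph
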