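"""Exponential-family random graph modeling of edge formation.

The model is P(Y = y) proportional to exp(sum_k theta_k g_k(y)) with
term statistics g_k drawn from: ``edges`` (edge count), ``nodecov(a)``
(sum over edges of a_i + a_j), ``absdiff(a)`` (sum of |a_i - a_j|),
``triangle`` (triangle count) and ``twopath`` (number of 2-paths,
sum_v C(deg_v, 2)).

Estimation is maximum pseudo-likelihood (MPLE): a logistic regression
of dyad indicators on change statistics.  For dyad-independent term
sets (edges / nodecov / absdiff) the pseudo-likelihood *is* the
likelihood, so MPLE returns the exact MLE; for ``triangle`` and
``twopath`` it is the standard approximation.  ``exact_mle_small``
maximizes the true likelihood by enumerating every graph on up to five
nodes and serves as an independent verification route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ErgmTerm",
    "ErgmFit",
    "DegeneracyError",
    "parse_term",
    "change_statistics",
    "fit_mple",
    "exact_mle_small",
    "simulate_ergm",
]

DYAD_INDEPENDENT = {"edges", "nodecov", "absdiff"}


class DegeneracyError(RuntimeError):
    """Model degeneracy: complete/empty graph or perfect separation."""


@dataclass(frozen=True)
class ErgmTerm:
    """One model term; ``attr`` names the node attribute where needed."""

    name: str  # edges | nodecov | absdiff | triangle | twopath
    attr: str | None = None

    def __post_init__(self) -> None:
        if self.name not in ("edges", "nodecov", "absdiff", "triangle", "twopath"):
            raise ValueError(f"unknown ERGM term {self.name!r}")
        if self.name in ("nodecov", "absdiff") and not self.attr:
            raise ValueError(f"term {self.name} requires a node attribute")
        if self.name in ("edges", "triangle", "twopath") and self.attr:
            raise ValueError(f"term {self.name} takes no attribute")

    @property
    def label(self) -> str:
        return f'{self.name}("{self.attr}")' if self.attr else self.name

    @property
    def dyad_independent(self) -> bool:
        return self.name in DYAD_INDEPENDENT


def parse_term(spec: "str | ErgmTerm") -> ErgmTerm:
    """Parse 'edges', 'nodecov(ctcf)', 'absdiff("expr")' style specs."""
    if isinstance(spec, ErgmTerm):
        return spec
    spec = spec.strip()
    if "(" in spec:
        name, rest = spec.split("(", 1)
        attr = rest.rstrip(")").strip("'\" ")
        return ErgmTerm(name.strip(), attr)
    return ErgmTerm(spec)


@dataclass
class ErgmFit:
    """Term estimates and standard errors (the model's summary surface)."""

    terms: list[ErgmTerm]
    estimates: np.ndarray
    se: np.ndarray
    loglik: float
    method: str  # "mple" | "exact"
    n_dyads: int
    converged: bool = True

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [t.label for t in self.terms],
                "estimate": self.estimates,
                "se": self.se,
            }
        )

    def model_label(self) -> str:
        return " + ".join(t.label.capitalize() if t.name == "edges" else t.label
                          for t in self.terms)


def _attr_values(g: nx.Graph, attr: str) -> dict:
    vals = nx.get_node_attributes(g, attr)
    missing = [n for n in g.nodes if n not in vals]
    if missing:
        raise ValueError(f"node attribute {attr!r} missing on nodes: {missing}")
    return vals


def change_statistics(
    g: nx.Graph, dyad: tuple, terms: Sequence["str | ErgmTerm"]
) -> np.ndarray:
    """Change statistic vector for toggling ``dyad`` on: g(y+ij) - g(y-ij).

    Statistics that depend on the rest of the graph (triangle, twopath)
    are evaluated with the dyad edge removed, so the result does not
    depend on whether the edge is currently present.
    """
    i, j = dyad
    if i == j:
        raise ValueError("dyad endpoints must differ")
    terms = [parse_term(t) for t in terms]
    out = np.empty(len(terms))
    for k, t in enumerate(terms):
        if t.name == "edges":
            out[k] = 1.0
        elif t.name == "nodecov":
            vals = _attr_values(g, t.attr)
            out[k] = vals[i] + vals[j]
        elif t.name == "absdiff":
            vals = _attr_values(g, t.attr)
            out[k] = abs(vals[i] - vals[j])
        elif t.name == "triangle":
            out[k] = len(set(g.neighbors(i)) & set(g.neighbors(j)) - {i, j})
        elif t.name == "twopath":
            di = g.degree(i) - (1 if g.has_edge(i, j) else 0)
            dj = g.degree(j) - (1 if g.has_edge(i, j) else 0)
            out[k] = di + dj
    return out


def _dyads(g: nx.Graph) -> list[tuple]:
    return list(itertools.combinations(sorted(g.nodes), 2))


def fit_mple(g: nx.Graph, terms: Sequence["str | ErgmTerm"]) -> ErgmFit:
    """Maximum pseudo-likelihood fit: logistic regression on change stats.

    Exact MLE when every term is dyad-independent.  Raises
    :class:`DegeneracyError` for complete or empty graphs and for
    perfectly separated fits (infinite estimates).
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    terms = [parse_term(t) for t in terms]
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    dyads = _dyads(g)
    n_present = g.number_of_edges()
    if n_present == 0 or n_present == len(dyads):
        raise DegeneracyError(
            "graph is empty or complete: every dyad identical, MLE diverges"
        )
    X = np.array([change_statistics(g, d, terms) for d in dyads])
    y = np.array([1.0 if g.has_edge(*d) else 0.0 for d in dyads])
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            # separation manifests as statsmodels warnings; we detect it
            # below from the estimates themselves and raise explicitly
            _warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise DegeneracyError(f"perfect separation in MPLE fit: {e}") from e
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(res.params)) > 30:
        raise DegeneracyError("MPLE estimates diverged (separation or extreme statistic)")
    method = "exact" if all(t.dyad_independent for t in terms) else "mple"
    return ErgmFit(
        terms=terms,
        estimates=np.asarray(res.params),
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        method=method,
        n_dyads=len(dyads),
        converged=True,
    )


def _graph_statistics_enum(
    nodes: list, attrs: dict[str, dict], terms: list[ErgmTerm]
) -> tuple[np.ndarray, list[tuple]]:
    """Statistic vectors for every graph on ``nodes`` (n <= 5).

    Returns (S, dyads) where S[s, k] is statistic k of the graph whose
    edge set is the bitmask ``s`` over ``dyads``.
    """
    dyads = list(itertools.combinations(nodes, 2))
    m = len(dyads)
    n_graphs = 1 << m
    S = np.zeros((n_graphs, len(terms)))
    # dyad-level contributions for dyad-independent terms
    dyad_contrib = np.zeros((m, len(terms)))
    for di, (i, j) in enumerate(dyads):
        for k, t in enumerate(terms):
            if t.name == "edges":
                dyad_contrib[di, k] = 1.0
            elif t.name == "nodecov":
                dyad_contrib[di, k] = attrs[t.attr][i] + attrs[t.attr][j]
            elif t.name == "absdiff":
                dyad_contrib[di, k] = abs(attrs[t.attr][i] - attrs[t.attr][j])
    masks = np.arange(n_graphs)
    bits = ((masks[:, None] >> np.arange(m)[None, :]) & 1).astype(float)
    S += bits @ dyad_contrib
    dep = [k for k, t in enumerate(terms) if not t.dyad_independent]
    if dep:
        dyad_index = {frozenset(d): di for di, d in enumerate(dyads)}
        triples = list(itertools.combinations(nodes, 3))
        for s in range(n_graphs):
            present = bits[s].astype(bool)
            tri = two = 0
            if any(terms[k].name == "triangle" for k in dep):
                tri = sum(
                    1
                    for (a, b, c) in triples
                    if present[dyad_index[frozenset((a, b))]]
                    and present[dyad_index[frozenset((b, c))]]
                    and present[dyad_index[frozenset((a, c))]]
                )
            if any(terms[k].name == "twopath" for k in dep):
                deg = {n: 0 for n in nodes}
                for di, d in enumerate(dyads):
                    if present[di]:
                        a, b = tuple(d)
                        deg[a] += 1
                        deg[b] += 1
                two = sum(dv * (dv - 1) // 2 for dv in deg.values())
            for k in dep:
                S[s, k] = tri if terms[k].name == "triangle" else two
    return S, dyads


def exact_mle_small(g: nx.Graph, terms: Sequence["str | ErgmTerm"]) -> ErgmFit:
    """Exact MLE by full enumeration of graphs on up to 5 nodes.

    Newton iteration on the exact log-likelihood
    ``theta . g(y_obs) - log Z(theta)`` to 1e-8; the Fisher information
    (the covariance of the statistics under the model) supplies the
    standard errors.  Estimates diverging past ||theta|| = 30 signal a
    statistic at its extreme and raise :class:`DegeneracyError`.
    """
    terms = [parse_term(t) for t in terms]
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n > 5:
        raise ValueError("exact enumeration limited to n <= 5 nodes")
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if g.number_of_edges() in (0, n * (n - 1) // 2):
        raise DegeneracyError("graph is empty or complete: MLE diverges")
    attrs = {
        t.attr: _attr_values(g, t.attr) for t in terms if t.attr is not None
    }
    S, dyads = _graph_statistics_enum(nodes, attrs, terms)
    obs_mask = 0
    for di, d in enumerate(dyads):
        if g.has_edge(*d):
            obs_mask |= 1 << di
    g_obs = S[obs_mask]

    theta = np.zeros(len(terms))
    for _ in range(200):
        eta = S @ theta
        eta -= eta.max()
        w = np.exp(eta)
        w /= w.sum()
        mean = w @ S
        centered = S - mean
        cov = centered.T @ (centered * w[:, None])
        grad = g_obs - mean
        try:
            step = np.linalg.solve(cov + 1e-12 * np.eye(len(terms)), grad)
        except np.linalg.LinAlgError as e:
            raise DegeneracyError(f"singular Fisher information: {e}") from e
        # damped Newton for stability far from the optimum
        if np.linalg.norm(step) > 5:
            step *= 5 / np.linalg.norm(step)
        theta = theta + step
        if np.linalg.norm(theta) > 30:
            raise DegeneracyError("exact MLE diverged: statistic at its extreme")
        if np.linalg.norm(grad) < 1e-8:
            break
    else:
        raise DegeneracyError("exact MLE Newton iteration failed to converge")

    eta = S @ theta
    logz = float(np.logaddexp.reduce(eta))
    loglik = float(theta @ g_obs - logz)
    w = np.exp(eta - eta.max())
    w /= w.sum()
    mean = w @ S
    centered = S - mean
    cov = centered.T @ (centered * w[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(cov + 1e-12 * np.eye(len(terms)))))
    return ErgmFit(
        terms=terms,
        estimates=theta,
        se=se,
        loglik=loglik,
        method="exact",
        n_dyads=len(dyads),
        converged=True,
    )


def simulate_ergm(
    nodes: Sequence,
    attrs: dict[str, dict],
    terms: Sequence["str | ErgmTerm"],
    theta: Sequence[float],
    seed: "int | np.random.Generator" = 0,
    burn_in: int = 20,
    thin: int = 1,
) -> nx.Graph:
    """Draw one graph from the model.

    Dyad-independent models sample every dyad independently at its
    conditional probability; models with triangle/twopath terms run a
    Gibbs sweep over dyads (``burn_in`` full sweeps, then ``thin`` more
    before returning).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    terms = [parse_term(t) for t in terms]
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for attr, vals in attrs.items():
        nx.set_node_attributes(g, vals, attr)
    dyads = _dyads(g)
    if all(t.dyad_independent for t in terms):
        for d in dyads:
            x = change_statistics(g, d, terms)
            p = 1.0 / (1.0 + np.exp(-(x @ theta)))
            if rng.random() < p:
                g.add_edge(*d)
        return g
    # Gibbs sampling for dependence terms
    for sweep in range(burn_in + thin):
        for d in dyads:
            had = g.has_edge(*d)
            if had:
                g.remove_edge(*d)
            x = change_statistics(g, d, terms)
            p = 1.0 / (1.0 + np.exp(-(x @ theta)))
            if rng.random() < p:
                g.add_edge(*d)
    return g
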