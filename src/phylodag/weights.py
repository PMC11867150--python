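"""Dynamic programming over a history DAG for edge-decomposable weights.

A history weight ``g_f`` is the sum of an edge function ``f`` over the edges
of a history (the UA edge included).  Whenever ``f`` takes values in a
totally ordered set with associative, commutative addition, a single
bottom-up pass over the DAG suffices to find the optimal ``g_f`` over all
expressed histories, to count histories, to trim the DAG to the optima, and
to compute log-marginals over all histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .sdag import UA, HistoryNode, HistorySDAG


@dataclass(frozen=True)
class WeightSet:
    """A totally ordered commutative monoid ``(W, +, 0, <)``.

    ``compare(a, b)`` returns negative/zero/positive like ``cmp``.
    """

    zero: object
    add: Callable
    compare: Callable = field(
        default=lambda a, b: (a > b) - (a < b)
    )


#: Real or integer weights under ordinary addition.
REAL_WEIGHTS = WeightSet(zero=0, add=lambda a, b: a + b)


@dataclass(frozen=True)
class RankingCriterion:
    """An edge weight function plus an optimization direction."""

    edge_fn: Callable  # (parent | UA, child) -> W
    direction: str = "min"  # "min" or "max"
    weights: WeightSet = REAL_WEIGHTS
    name: str = ""

    def __post_init__(self):
        if self.direction not in ("min", "max"):
            raise ValueError("direction must be 'min' or 'max'")

    def better(self, a, b) -> bool:
        c = self.weights.compare(a, b)
        return c < 0 if self.direction == "min" else c > 0


def _downward_optima(dag: HistorySDAG, criterion: RankingCriterion) -> dict:
    """Optimal subtree weight below each vertex (excluding its incoming edge)."""
    ws = criterion.weights
    best: dict[HistoryNode, object] = {}
    for v in reversed(dag.topological_order()):
        if v.is_leaf():
            best[v] = ws.zero
            continue
        total = ws.zero
        for clade, kids in dag.children[v].items():
            opt = None
            for child in kids:
                w = ws.add(criterion.edge_fn(v, child), best[child])
                if opt is None or criterion.better(w, opt):
                    opt = w
            if opt is None:
                raise ValueError("dead-end clade encountered; prune the DAG first")
            total = ws.add(total, opt)
        best[v] = total
    return best


def optimal_weight(dag: HistorySDAG, criterion: RankingCriterion):
    """Optimal (min or max) history weight ``g_f`` over all expressed histories."""
    if not dag.ua_children:
        raise ValueError("empty DAG")
    ws = criterion.weights
    best = _downward_optima(dag, criterion)
    opt = None
    for child in dag.ua_children:
        w = ws.add(criterion.edge_fn(UA, child), best[child])
        if opt is None or criterion.better(w, opt):
            opt = w
    return opt


def _weights_close(a, b, rel_tol: float) -> bool:
    if isinstance(a, tuple):
        return len(a) == len(b) and all(
            _weights_close(x, y, rel_tol) for x, y in zip(a, b)
        )
    if isinstance(a, float) or isinstance(b, float):
        return math.isclose(a, b, rel_tol=rel_tol, abs_tol=rel_tol)
    return a == b


def trim(
    dag: HistorySDAG, criterion: RankingCriterion, rel_tol: float = 1e-9
) -> HistorySDAG:
    """Trim to express exactly the histories achieving the optimal weight.

    Keeps, at each vertex and clade, the edges achieving the per-clade
    optimum (ties within ``rel_tol`` for float weights are kept), then prunes
    unreachable vertices.
    """
    if not dag.ua_children:
        raise ValueError("empty DAG")
    ws = criterion.weights
    best = _downward_optima(dag, criterion)
    out = HistorySDAG()

    def keep_edges(parent, kids):
        scored = [(ws.add(criterion.edge_fn(parent, c), best[c]), c) for c in kids]
        opt = None
        for w, _ in scored:
            if opt is None or criterion.better(w, opt):
                opt = w
        return {c for w, c in scored if _weights_close(w, opt, rel_tol)}

    for v in dag.children:
        out._ensure_node(v)
        for clade, kids in dag.children[v].items():
            out.children[v][clade] = keep_edges(v, kids)
    out.ua_children = keep_edges(UA, dag.ua_children)
    return out.prune()


def count_histories(dag: HistorySDAG) -> int:
    """Exact number of distinct histories expressed by the DAG."""
    counts: dict[HistoryNode, int] = {}
    for v in reversed(dag.topological_order()):
        if v.is_leaf():
            counts[v] = 1
        else:
            n = 1
            for kids in dag.children[v].values():
                n *= sum(counts[c] for c in kids)
            counts[v] = n
    return sum(counts[c] for c in dag.ua_children)


def marginalize(dag: HistorySDAG, log_edge_fn: Callable) -> float:
    """log Σ_histories exp(Σ_edges log_edge_fn(edge)), by sum-product DP."""
    logs: dict[HistoryNode, float] = {}
    for v in reversed(dag.topological_order()):
        if v.is_leaf():
            logs[v] = 0.0
            continue
        total = 0.0
        for kids in dag.children[v].values():
            terms = [log_edge_fn(v, c) + logs[c] for c in kids]
            total += _logsumexp(terms)
        logs[v] = total
    terms = [log_edge_fn(UA, c) + logs[c] for c in dag.ua_children]
    return _logsumexp(terms)


def _logsumexp(terms: list[float]) -> float:
    arr = np.asarray(terms, dtype=float)
    if np.all(np.isneginf(arr)):
        return float("-inf")
    m = np.max(arr)
    return float(m + np.log(np.sum(np.exp(arr - m))))


def lexicographic_trim(
    dag: HistorySDAG,
    criteria: Sequence[RankingCriterion],
    rel_tol: float = 1e-9,
) -> HistorySDAG:
    """Trim iteratively by each criterion in descending order of importance."""
    if not criteria:
        raise ValueError("need at least one criterion")
    for criterion in criteria:
        dag = trim(dag, criterion, rel_tol=rel_tol)
    return dag


def linear_combination(
    edge_fns: Sequence[Callable], coefficients: Sequence[float]
) -> Callable:
    """Edge function ``f'(e) = Σ a_i f_i(e)`` for real-valued ``f_i``.

    The induced history weight satisfies ``g_{f'} = Σ a_i g_{f_i}``.
    """
    if len(edge_fns) != len(coefficients):
        raise ValueError("edge_fns and coefficients must have equal length")
    fns = list(edge_fns)
    coeffs = [float(a) for a in coefficients]

    def combined(parent, child):
        return sum(a * f(parent, child) for f, a in zip(fns, coeffs))

    return combined
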