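"""Abundance-aware branching-process likelihood on genotype trees.

The offspring model is a binary Galton–Watson process: each cell divides
with probability ``p`` into two children, each of which independently
mutates to a new genotype with probability ``q``; with probability ``1 - p``
the cell terminates and is observed.  For a genotype founder, let
``f(c, m | p, q)`` be the probability that the clone leaves ``c`` observed
cells of the founding genotype and ``m`` distinct mutant offspring
lineages.  It satisfies the recursion

    f(c, m) = (1 - p) [c = 1, m = 0]
            + p * ( q^2 [c = 0, m = 2]
                  + 2 q (1 - q) f(c, m - 1)
                  + (1 - q)^2 * sum_{c1 + c2 = c, m1 + m2 = m} f(c1, m1) f(c2, m2) )

with ``f(0, 0) = 0`` (a same-genotype lineage always terminates in an
observed cell).  The log-likelihood of a collapsed genotype tree is the sum
over genotype nodes of ``log f(c, m)`` where ``c`` is the node's observed
abundance and ``m`` its number of distinct mutant child lineages — an
edge-decomposable weight when each edge carries its child node's term and
the UA edge carries the root's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .sdag import UA, History, HistoryNode, HistorySDAG
from .weights import RankingCriterion, marginalize


@dataclass(frozen=True)
class BranchingParams:
    """Branching probability ``p`` and per-child mutation probability ``q``."""

    p: float
    q: float

    def __post_init__(self):
        if not (0.0 < self.p < 1.0 and 0.0 < self.q < 1.0):
            raise ValueError("p and q must lie in the open interval (0, 1)")


@lru_cache(maxsize=None)
def _genotype_prob(c: int, m: int, p: float, q: float) -> float:
    if c < 0 or m < 0 or c + m == 0:
        return 0.0
    result = 0.0
    if c == 1 and m == 0:
        result += 1.0 - p
    if c == 0 and m == 2:
        result += p * q * q
    if m >= 1:
        result += p * 2.0 * q * (1.0 - q) * _genotype_prob(c, m - 1, p, q)
    conv = 0.0
    for c1 in range(c + 1):
        for m1 in range(m + 1):
            if c1 + m1 == 0 or (c1 == c and m1 == m):
                continue  # f(0,0) = 0 on either side
            conv += _genotype_prob(c1, m1, p, q) * _genotype_prob(c - c1, m - m1, p, q)
    result += p * (1.0 - q) ** 2 * conv
    return result


def genotype_prob(c: int, m: int, params: BranchingParams) -> float:
    """P(clone leaves c observed same-genotype cells, m mutant lineages).

    Requires ``c + m >= 1``; computed by memoized recursion.
    """
    if c < 0 or m < 0 or c + m < 1:
        raise ValueError("need c, m >= 0 with c + m >= 1")
    return _genotype_prob(c, m, params.p, params.q)


def simulate_clone(params: BranchingParams, rng: np.random.Generator,
                   max_cells: int = 1_000_000) -> tuple[int, int]:
    """Simulate one genotype clone, returning (c, m).

    Direct Monte-Carlo realization of the process behind
    :func:`genotype_prob`, for validation and simulation studies.
    """
    c = m = 0
    active = 1  # same-genotype cells still dividing
    total = 1
    while active:
        active -= 1
        if rng.random() >= params.p:
            c += 1
            continue
        total += 2
        if total > max_cells:
            raise RuntimeError("clone exceeded max_cells; process near-critical?")
        for _ in range(2):
            if rng.random() < params.q:
                m += 1
            else:
                active += 1
    return c, m


def node_genotype_counts(
    node: HistoryNode, abundances: Mapping[str, int]
) -> tuple[int, int]:
    """(c, m) for a vertex of a collapsed history.

    ``c`` is the vertex label's observed abundance and ``m`` its number of
    child clades, excluding a same-label leaf child (the bundle of observed
    cells of the vertex's own genotype, already counted by ``c``).  A leaf
    whose parent shares its label contributes no term of its own; the edge
    function handles that case.
    """
    c = int(abundances.get(node.label, 0))
    own_clade = frozenset({node.label})
    m = len(node.clades)
    if own_clade in node.clades:
        m -= 1
    return c, m


def bp_edge_weight(
    params: BranchingParams, abundances: Mapping[str, int]
) -> Callable:
    """Edge function carrying the child vertex's ``log f(c, m)`` term.

    The UA edge carries the root's term; an edge to a leaf sharing its
    parent's label carries 0 (that leaf is the parent genotype's observed
    bundle).  Summing over a history's edges gives the branching process
    log-likelihood of the collapsed genotype tree.
    """

    def edge_fn(parent, child) -> float:
        if (
            parent is not UA
            and child.is_leaf()
            and child.label == parent.label
        ):
            return 0.0
        c, m = node_genotype_counts(child, abundances)
        if c + m == 0:
            raise ValueError(
                f"genotype {child.label[:16]}... has no abundance and no "
                "mutant children; is the DAG collapsed?"
            )
        prob = genotype_prob(c, m, params)
        return math.log(prob) if prob > 0 else float("-inf")

    return edge_fn


def bp_criterion(
    params: BranchingParams, abundances: Mapping[str, int]
) -> RankingCriterion:
    return RankingCriterion(
        edge_fn=bp_edge_weight(params, abundances),
        direction="max",
        name="bp_likelihood",
    )


def history_bp_loglik(
    history: History, params: BranchingParams, abundances: Mapping[str, int]
) -> float:
    return history.weight(bp_edge_weight(params, abundances), zero=0.0)


# ---------------------------------------------------------------------------
# Parameter fitting


def _collect_count_pairs(dag: HistorySDAG, abundances: Mapping[str, int]):
    """Map each DAG edge to its (c, m) pair (None for leaf-bundle edges)."""
    pairs = {}
    for parent, child in dag.edges(include_ua=True):
        if (
            parent is not UA
            and child.is_leaf()
            and child.label == parent.label
        ):
            pairs[(parent, child)] = None
        else:
            pairs[(parent, child)] = node_genotype_counts(child, abundances)
    return pairs


def _genotype_prob_arrays(cms, P: np.ndarray, Q: np.ndarray) -> dict:
    """Vectorized f(c, m) over parameter arrays, for all pairs in ``cms``."""
    memo: dict[tuple[int, int], np.ndarray] = {}

    def f(c: int, m: int) -> np.ndarray:
        if c < 0 or m < 0 or c + m == 0:
            return np.zeros_like(P)
        key = (c, m)
        if key in memo:
            return memo[key]
        result = np.zeros_like(P)
        if c == 1 and m == 0:
            result = result + (1.0 - P)
        if c == 0 and m == 2:
            result = result + P * Q * Q
        if m >= 1:
            result = result + P * 2.0 * Q * (1.0 - Q) * f(c, m - 1)
        conv = np.zeros_like(P)
        for c1 in range(c + 1):
            for m1 in range(m + 1):
                if c1 + m1 == 0 or (c1 == c and m1 == m):
                    continue
                conv = conv + f(c1, m1) * f(c - c1, m - m1)
        result = result + P * (1.0 - Q) ** 2 * conv
        memo[key] = result
        return result

    return {cm: f(*cm) for cm in cms}


def _marginal_loglik_grid(dag, pairs, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood at every parameter grid point at once."""
    needed = {cm for cm in pairs.values() if cm is not None}
    probs = _genotype_prob_arrays(needed, P, Q)
    with np.errstate(divide="ignore"):
        logprobs = {cm: np.log(arr) for cm, arr in probs.items()}
    zero = np.zeros_like(P)

    def edge_logs(parent, child):
        cm = pairs[(parent, child)]
        return zero if cm is None else logprobs[cm]

    logs: dict = {}
    for v in reversed(dag.topological_order()):
        if v.is_leaf():
            logs[v] = zero
            continue
        total = zero
        for kids in dag.children[v].values():
            stacked = np.stack([edge_logs(v, c) + logs[c] for c in kids])
            total = total + _logsumexp_rows(stacked)
        logs[v] = total
    from .sdag import UA as _UA

    stacked = np.stack([edge_logs(_UA, c) + logs[c] for c in dag.ua_children])
    return _logsumexp_rows(stacked)


def _logsumexp_rows(stacked: np.ndarray) -> np.ndarray:
    m = np.max(stacked, axis=0)
    safe = np.where(np.isneginf(m), 0.0, m)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.sum(np.exp(stacked - safe), axis=0))
    return np.where(np.isneginf(m), -np.inf, out)


def _marginal_loglik(dag, pairs, p: float, q: float) -> float:
    cache = {}

    def edge_fn(parent, child):
        cm = pairs[(parent, child)]
        if cm is None:
            return 0.0
        if cm not in cache:
            prob = _genotype_prob(cm[0], cm[1], p, q)
            cache[cm] = math.log(prob) if prob > 0 else float("-inf")
        return cache[cm]

    return marginalize(dag, edge_fn)


def fit_params(
    dag: HistorySDAG,
    abundances: Mapping[str, int],
    grid_size: int = 50,
    max_p: float = 0.5,
    refine: bool = True,
) -> BranchingParams:
    """Maximize the marginal branching-process likelihood over all histories.

    A coarse grid search on ``(0, max_p) x (0, 1)`` is followed by local
    refinement (Nelder–Mead).  ``max_p`` defaults to 0.5 so the fitted
    process is sub-critical.  Deterministic: no randomness is involved.
    """
    pairs = _collect_count_pairs(dag, abundances)
    ps = np.linspace(0.0, max_p, grid_size + 2)[1:-1]
    qs = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    P, Q = (a.ravel() for a in np.meshgrid(ps, qs, indexing="ij"))
    lls = _marginal_loglik_grid(dag, pairs, P, Q)
    i_best = int(np.argmax(lls))
    if np.isneginf(lls[i_best]):
        raise ValueError("likelihood is degenerate everywhere on the grid")
    best = (float(lls[i_best]), None)
    p0, q0 = float(P[i_best]), float(Q[i_best])
    if refine:
        eps = 1e-6

        def objective(x):
            p, q = x
            if not (eps < p < max_p - eps and eps < q < 1 - eps):
                return math.inf
            return -_marginal_loglik(dag, pairs, p, q)

        res = minimize(
            objective, [p0, q0], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9},
        )
        if res.fun < -best[0]:
            p0, q0 = float(res.x[0]), float(res.x[1])
    return BranchingParams(p0, q0)


def loglik_counts(pairs: Sequence[tuple[int, int]], p: float, q: float) -> float:
    """Total log f(c, m) over independent genotype observations."""
    total = 0.0
    for c, m in pairs:
        prob = _genotype_prob(c, m, p, q)
        if prob <= 0:
            return float("-inf")
        total += math.log(prob)
    return total


def fit_counts(
    pairs: Sequence[tuple[int, int]],
    grid_size: int = 50,
    max_p: float = 0.5,
) -> tuple[BranchingParams, np.ndarray]:
    """MLE of (p, q) from independent (c, m) observations, with standard errors.

    Returns the fitted parameters and the asymptotic standard errors from
    the inverse observed Fisher information (numerical Hessian).
    """
    ps = np.linspace(0.0, max_p, grid_size + 2)[1:-1]
    qs = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    best = (-math.inf, (0.25, 0.5))
    for p in ps:
        for q in qs:
            ll = loglik_counts(pairs, float(p), float(q))
            if ll > best[0]:
                best = (ll, (float(p), float(q)))
    eps = 1e-6

    def objective(x):
        p, q = x
        if not (eps < p < 1 - eps and eps < q < 1 - eps):
            return math.inf
        return -loglik_counts(pairs, p, q)

    res = minimize(
        objective, list(best[1]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10},
    )
    p_hat, q_hat = float(res.x[0]), float(res.x[1])
    h = 1e-4
    hess = np.empty((2, 2))
    x0 = np.array([p_hat, q_hat])
    for i in range(2):
        for j in range(2):
            e_i = np.eye(2)[i] * h
            e_j = np.eye(2)[j] * h
            hess[i, j] = (
                objective(x0 + e_i + e_j)
                - objective(x0 + e_i - e_j)
                - objective(x0 - e_i + e_j)
                + objective(x0 - e_i - e_j)
            ) / (4 * h * h)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return BranchingParams(p_hat, q_hat), se
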