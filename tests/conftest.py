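"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from phylodag import HistorySDAG, UA, history_from_tree, synthetic_model


@pytest.fixture(scope="session")
def model():
    return synthetic_model(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequences(rng, n, length):
    """n distinct random sequences of the given length."""
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(list("ACGT"), size=length)))
    return sorted(out)


def mutated_family(rng, n, length, n_mutations=3):
    """n distinct sequences derived from a common ancestor by point mutations.

    Low-divergence families mimic the inputs maximum-parsimony pipelines see
    and keep ancestral-state ambiguity (hence DAG size) moderate.
    """
    root = "".join(rng.choice(list("ACGT"), size=length))
    out = {root}
    while len(out) < n:
        seq = list(root)
        for _ in range(int(rng.integers(1, n_mutations + 1))):
            j = int(rng.integers(length))
            seq[j] = "ACGT"[rng.integers(4)]
        out.add("".join(seq))
    return sorted(out)


def random_history(rng, leaf_seqs, internal_pool=None):
    """A random rooted tree over the given leaf sequences.

    Internal labels are drawn from ``internal_pool`` (default: random
    sequences of the same length), so parsimony scores are arbitrary.
    """
    length = len(leaf_seqs[0])

    def rand_label():
        if internal_pool is not None:
            return internal_pool[rng.integers(len(internal_pool))]
        return "".join(rng.choice(list("ACGT"), size=length))

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        idx = rng.permutation(len(leaves))
        left = [leaves[i] for i in sorted(idx[:k])]
        right = [leaves[i] for i in sorted(idx[k:])]
        return (rand_label(), [build(left), build(right)])

    tree = build(list(leaf_seqs))
    if isinstance(tree, str):
        return history_from_tree(tree)
    return history_from_tree(tree)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the library's DP paths).


def brute_force_histories(dag: HistorySDAG):
    """Set of histories as frozensets of (parent, child) edges, UA included.

    Independent recursive expansion used as the enumeration oracle.
    """

    def expand(node):
        if node.is_leaf():
            return [frozenset()]
        per_clade = []
        for clade in node.clades:
            options = []
            for child in dag.children[node][clade]:
                for sub in expand(child):
                    options.append(sub | {(node, child)})
            per_clade.append(options)
        results = []
        for combo in itertools.product(*per_clade):
            merged = frozenset().union(*combo) if combo else frozenset()
            results.append(merged)
        return results

    out = set()
    for root in dag.ua_children:
        for sub in expand(root):
            out.add(sub | {(UA, root)})
    return out


def history_edge_set(history):
    return frozenset(history.edges(include_ua=True))


def brute_force_weight(dag, edge_fn, best=min):
    """Optimal summed edge weight over the enumeration oracle's histories."""
    totals = [
        sum(edge_fn(p, c) for p, c in edges)
        for edges in brute_force_histories(dag)
    ]
    return best(totals)
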