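"""Parsimony weights and small-parsimony ancestral reconstruction.

Provides the Hamming edge weight used for parsimony trimming, a per-site
dynamic program that annotates a rooted topology with the full set of
maximally parsimonious ancestral states (encoded as IUPAC ambiguity codes),
and an exhaustive maximum-parsimony tree generator for tiny leaf sets used
to produce test inputs without an external parsimony search program.
"""

from __future__ import annotations

from typing import Optional, Sequence

from ._seq import BASES, BASES_TO_IUPAC, hamming, validate_sequence
from .sdag import UA, History, HistorySDAG, history_from_tree
from .weights import RankingCriterion, WeightSet

INF = float("inf")


def hamming_edge_weight(parent, child) -> int:
    """Number of differing sites on an edge; UA edges weigh 0."""
    if parent is UA:
        return 0
    return hamming(parent.label, child.label)


#: Integer parsimony weights under addition.
PARSIMONY_WEIGHTS = WeightSet(zero=0, add=lambda a, b: a + b)


def parsimony_criterion() -> RankingCriterion:
    return RankingCriterion(
        edge_fn=hamming_edge_weight,
        direction="min",
        weights=PARSIMONY_WEIGHTS,
        name="parsimony",
    )


def parsimony_score(history: History) -> int:
    """Total number of mutations over the history's edges."""
    return history.weight(hamming_edge_weight)


# ---------------------------------------------------------------------------
# Topologies are nested tuples: a leaf is a sequence string, an internal node
# is a tuple of subtrees.


def _topology_leaves(topology) -> list[str]:
    if isinstance(topology, str):
        return [topology]
    out = []
    for sub in topology:
        out.extend(_topology_leaves(sub))
    return out


def _site_costs(topology, site: int) -> tuple:
    """Bottom-up minimal subtree cost per state, memo keyed by subtree id."""
    # returns nested (costs, children_costs) mirroring the topology
    if isinstance(topology, str):
        base = topology[site]
        costs = tuple(0 if b == base else INF for b in BASES)
        return costs, None
    child_results = [_site_costs(sub, site) for sub in topology]
    costs = []
    for si in range(4):
        total = 0.0
        for ccosts, _ in child_results:
            total += min(ccosts[sj] + (si != sj) for sj in range(4))
        costs.append(total)
    return tuple(costs), child_results


def _site_mpr_states(topology, site: int) -> list[frozenset]:
    """Per-node sets of states appearing in at least one MP labeling.

    Returns states for internal nodes in preorder.  Uses the up/down
    decomposition: a state is optimal at a node iff the minimal cost of its
    subtree given that state, plus the minimal cost of the rest of the tree
    given that state, equals the global minimum.
    """
    up, child_up = _site_costs(topology, site)
    total_min = min(up)
    out: list[frozenset] = []

    def walk(node, up_costs, children, down_costs):
        if isinstance(node, str):
            return
        states = frozenset(
            BASES[si]
            for si in range(4)
            if up_costs[si] + down_costs[si] == total_min
        )
        out.append(states)
        for sub, (ccosts, cchildren) in zip(node, children):
            cdown = []
            for sj in range(4):
                best = INF
                for si in range(4):
                    contrib = min(ccosts[sk] + (si != sk) for sk in range(4))
                    rest = up_costs[si] - contrib + down_costs[si]
                    best = min(best, rest + (si != sj))
                cdown.append(best)
            walk(sub, ccosts, cchildren, tuple(cdown))

    walk(topology, up, child_up, (0.0,) * 4)
    return out


def fitch_score(topology) -> int:
    """Minimal number of mutations over all ancestral labelings."""
    leaves = _topology_leaves(topology)
    length = len(leaves[0])
    score = 0
    for site in range(length):
        costs, _ = _site_costs(topology, site)
        score += int(min(costs))
    return score


def fitch_ancestors(topology) -> History:
    """Annotate a rooted topology with MP ancestral state sets.

    Internal labels encode, per site, the set of bases occurring in at least
    one maximally parsimonious labeling, as IUPAC codes.  Expanding the
    resulting history's ambiguities and trimming to minimal parsimony yields
    exactly the MP labelings of this topology.
    """
    leaves = _topology_leaves(topology)
    for leaf in leaves:
        validate_sequence(leaf, allow_ambiguity=False)
    length = len(leaves[0])
    if any(len(leaf) != length for leaf in leaves):
        raise ValueError("unequal sequence lengths")
    per_site = [_site_mpr_states(topology, site) for site in range(length)]
    n_internal = len(per_site[0])
    labels = [
        "".join(BASES_TO_IUPAC[per_site[site][i]] for site in range(length))
        for i in range(n_internal)
    ]

    counter = iter(range(n_internal))

    def convert(node):
        if isinstance(node, str):
            return node
        label = labels[next(counter)]
        return (label, [convert(sub) for sub in node])

    return history_from_tree(convert(topology))


def _rooted_topologies(leaves: Sequence[str]):
    """All rooted binary tree shapes on the given leaves, by leaf insertion."""
    if len(leaves) == 1:
        yield leaves[0]
        return

    def insert(tree, leaf):
        # insert leaf on every edge of tree, plus above the root
        yield (tree, leaf)
        if not isinstance(tree, str):
            left, right = tree
            for new_left in insert(left, leaf):
                yield (new_left, right)
            for new_right in insert(right, leaf):
                yield (left, new_right)

    trees = [(leaves[0], leaves[1])]
    for leaf in leaves[2:]:
        trees = [t for tree in trees for t in insert(tree, leaf)]
    yield from trees


def exhaustive_mp_trees(
    sequences: Sequence[str],
    max_leaves: int = 8,
    root: Optional[str] = None,
) -> list[History]:
    """All maximum-parsimony histories over every rooted binary topology.

    ``sequences`` are deduplicated (identical sequences are one taxon).  If
    ``root`` is given it is attached as an outgroup below the root so the
    returned histories are rooted at that sequence (the founder convention
    for B-cell data); otherwise topologies are rooted arbitrarily.
    Ancestral labels carry IUPAC-coded MP state sets; feed the result
    through DAG ambiguity expansion plus parsimony trimming to obtain all
    unambiguous MP histories.
    """
    unique = sorted(set(sequences))
    if root is not None and root not in unique:
        unique = sorted(set(unique) | {root})
    if len(unique) > max_leaves:
        raise ValueError(
            f"{len(unique)} unique sequences exceed max_leaves={max_leaves}"
        )
    if len(unique) == 1:
        return [history_from_tree(unique[0])]

    if root is not None:
        others = [s for s in unique if s != root]
        if len(others) == 1:
            topologies = [(root, others[0])]
        else:
            topologies = [(root, t) for t in _rooted_topologies(others)]
    else:
        topologies = list(_rooted_topologies(unique))

    scored = [(fitch_score(t), t) for t in topologies]
    best = min(s for s, _ in scored)
    return [fitch_ancestors(t) for s, t in scored if s == best]
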