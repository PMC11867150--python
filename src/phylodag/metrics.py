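"""Tree-comparison metrics: MRCA sequence distance and Robinson–Foulds.

The MRCA distance compares ancestral sequence reconstruction rather than
topology alone: for each unordered pair of taxa, the Hamming distance
between the true and inferred MRCA node sequences is divided by the mean
Hamming distance between each taxon and the true MRCA, and these normalized
terms are summed over all pairs.  Because the MRCA of a pair is unique in
any rooted tree, the metric is well defined for multifurcating trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from ._seq import hamming
from .sdag import History, HistoryNode


@dataclass(frozen=True)
class MRCAResult:
    """Raw pair sum, per-pair mean and bookkeeping for the MRCA distance."""

    total: float
    n_pairs: int
    n_skipped: int  # pairs with zero denominator (both taxa equal true MRCA)

    @property
    def mean(self) -> float:
        return self.total / self.n_pairs if self.n_pairs else 0.0

    def __float__(self) -> float:
        return self.total


def _root_paths(history: History) -> dict[str, list[HistoryNode]]:
    """Leaf label -> list of nodes from the root down to the leaf."""
    paths: dict[str, list[HistoryNode]] = {}

    def walk(node: HistoryNode, prefix: list):
        path = prefix + [node]
        if node.is_leaf():
            paths[node.label] = path
            return
        for child in history.down[node].values():
            walk(child, path)

    walk(history.root, [])
    return paths


def mrca_sequences(history: History) -> dict[frozenset, str]:
    """MRCA node sequence for every unordered pair of leaf labels."""
    paths = _root_paths(history)
    labels = sorted(paths)
    out = {}
    for a, b in combinations(labels, 2):
        pa, pb = paths[a], paths[b]
        mrca = pa[0]
        for x, y in zip(pa, pb):
            if x == y:
                mrca = x
            else:
                break
        out[frozenset((a, b))] = mrca.label
    return out


def mrca_distance(true_history: History, inferred_history: History) -> MRCAResult:
    """Summed normalized MRCA sequence distance between two histories.

    Pairs whose denominator is zero (both taxa identical to the true MRCA
    sequence) are skipped and counted in ``n_skipped``.
    """
    true_leaves = true_history.leaf_labels()
    if true_leaves != inferred_history.leaf_labels():
        raise ValueError("histories have different leaf label sets")
    true_mrcas = mrca_sequences(true_history)
    inf_mrcas = mrca_sequences(inferred_history)
    total = 0.0
    n_pairs = 0
    n_skipped = 0
    for pair, true_seq in true_mrcas.items():
        a, b = sorted(pair)
        denom = (hamming(a, true_seq) + hamming(b, true_seq)) / 2.0
        if denom == 0.0:
            n_skipped += 1
            continue
        total += hamming(true_seq, inf_mrcas[pair]) / denom
        n_pairs += 1
    return MRCAResult(total=total, n_pairs=n_pairs, n_skipped=n_skipped)


def _nontrivial_splits(history: History) -> set[frozenset]:
    """Unrooted nontrivial bipartitions, each as the smaller-side label set."""
    leaves = history.leaf_labels()
    n = len(leaves)
    splits = set()
    for node in history.nodes():
        if node.is_leaf():
            continue
        cu = node.clade_union()
        if 1 < len(cu) < n - 1:
            other = frozenset(leaves - cu)
            splits.add(min(cu, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def rf_distance(t1: History, t2: History, normalized: bool = True) -> float:
    """Robinson–Foulds distance on unrooted nontrivial splits.

    The normalized form divides by the total number of nontrivial splits in
    the two trees (so two fully resolved trees sharing no splits score 1.0).
    """
    if t1.leaf_labels() != t2.leaf_labels():
        raise ValueError("histories have different leaf label sets")
    s1 = _nontrivial_splits(t1)
    s2 = _nontrivial_splits(t2)
    raw = len(s1 ^ s2)
    if not normalized:
        return float(raw)
    denom = len(s1) + len(s2)
    return raw / denom if denom else 0.0
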