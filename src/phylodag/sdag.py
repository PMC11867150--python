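"""History DAG core data structure.

A *history* is a rooted tree whose leaves carry observed sequences and whose
internal nodes carry inferred ancestral sequences.  A collection of histories
sharing a leaf set can be stored compactly as a directed acyclic graph — the
history DAG — whose vertices are ``(label, child clade set)`` pairs.  Because
vertex identity includes the child clades, the DAG is simply the graph union
of its input histories, and recombining stored substructures expresses new
histories beyond those used to build it.

Vertices
--------
``HistoryNode(label, clades)`` where ``label`` is a nucleotide sequence and
``clades`` is a set of pairwise-disjoint, nonempty frozen sets of leaf
labels, one per child of the node.  Leaves have an empty clade set.  A formal
*universal ancestor* (UA) vertex sits above every history root so that the
choice of root is itself an edge choice.

Edges
-----
A directed edge ``(parent, child)`` is valid exactly when the child's clade
union equals one of the parent's child clades.  A history is a sub-DAG with
exactly one edge descending from each child clade of each vertex and one edge
descending from the UA vertex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from ._seq import (
    disambiguations,
    is_ambiguous,
    n_disambiguations,
    validate_sequence,
)

Clade = frozenset  # frozenset[str]: set of leaf labels


class AmbiguityExpansionError(RuntimeError):
    """Raised when ambiguity expansion would exceed the configured cap."""


class _UANode:
    """Singleton formal root; compares identical to itself only."""

    __slots__ = ()
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "UA"


#: The universal ancestor vertex, shared by all DAGs.
UA = _UANode()


@dataclass(frozen=True)
class HistoryNode:
    """A history DAG vertex: a (sequence label, child clade set) pair."""

    label: str
    clades: frozenset  # frozenset[Clade]

    def is_leaf(self) -> bool:
        return not self.clades

    def clade_union(self) -> Clade:
        """Set of all leaf labels reachable below this vertex.

        For a leaf this is the singleton of its own label; for an internal
        vertex, the union of its child clades.
        """
        if self.is_leaf():
            return frozenset({self.label})
        return frozenset().union(*self.clades)

    def __repr__(self):  # pragma: no cover - cosmetic
        clades = sorted(tuple(sorted(c)) for c in self.clades)
        return f"HistoryNode({self.label!r}, {clades})"


def clade_union(node: HistoryNode) -> Clade:
    """Functional alias for :meth:`HistoryNode.clade_union`."""
    return node.clade_union()


def leaf_node(label: str) -> HistoryNode:
    return HistoryNode(label, frozenset())


class History:
    """A single history: one chosen child per clade of each internal node.

    Stored as the root vertex plus, for every internal vertex, a mapping from
    each child clade to the chosen child vertex.
    """

    def __init__(self, root: HistoryNode, down: dict[HistoryNode, dict[Clade, HistoryNode]]):
        self.root = root
        self.down = down

    # -- structure ---------------------------------------------------------
    def children(self, node: HistoryNode) -> list[HistoryNode]:
        return list(self.down.get(node, {}).values())

    def nodes(self) -> list[HistoryNode]:
        """All vertices in preorder from the root."""
        out = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.down.get(v, {}).values())
        return out

    def edges(self, include_ua: bool = False) -> list[tuple]:
        """Directed (parent, child) pairs; optionally the UA edge first."""
        out = [(UA, self.root)] if include_ua else []
        for parent, choice in self.down.items():
            for child in choice.values():
                out.append((parent, child))
        return out

    def leaves(self) -> list[HistoryNode]:
        return [v for v in self.nodes() if v.is_leaf()]

    def leaf_labels(self) -> frozenset:
        return self.root.clade_union()

    def parent_map(self) -> dict[HistoryNode, HistoryNode]:
        return {c: p for p, choice in self.down.items() for c in choice.values()}

    def __eq__(self, other):
        return (
            isinstance(other, History)
            and self.root == other.root
            and self.down == other.down
        )

    def __hash__(self):
        return hash((self.root, frozenset((k, frozenset(v.items())) for k, v in self.down.items())))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"History(root={self.root!r}, n_nodes={len(self.nodes())})"

    # -- weights -----------------------------------------------------------
    def weight(self, edge_fn: Callable, zero=0, add=None):
        """Sum an edge function over all edges (UA edge included)."""
        add = add or (lambda a, b: a + b)
        total = zero
        for parent, child in self.edges(include_ua=True):
            total = add(total, edge_fn(parent, child))
        return total

    # -- editing -----------------------------------------------------------
    def collapse(self) -> "History":
        """Remove internal edges whose parent and child labels are equal.

        The child's clades are merged into the parent; leaf-adjacent
        zero-mutation edges are kept so every observed label survives.
        Iterates to the unique fixed point.
        """

        def build(node: HistoryNode):
            # returns (collapsed clade->child map) for the subtree at node
            if node.is_leaf():
                return node, {}
            mapping = {}
            collected = {}
            for clade, child in self.down[node].items():
                cnode, cdown = build(child)
                if not cnode.is_leaf() and cnode.label == node.label:
                    # merge grandchildren straight into this node
                    for gclade, gchild in cdown[cnode].items():
                        collected[gclade] = gchild
                    for k, v in cdown.items():
                        if k != cnode:
                            mapping[k] = v
                else:
                    collected[clade] = cnode
                    mapping.update(cdown)
            new_node = HistoryNode(node.label, frozenset(collected))
            mapping[new_node] = collected
            return new_node, mapping

        root, down = build(self.root)
        out = History(root, down)
        # label equality is edge-local, but merging can juxtapose new
        # equal-label pairs; iterate to the fixed point.
        if any(
            not c.is_leaf() and p.label == c.label for p, c in out.edges()
        ):
            return out.collapse()
        return out


def history_from_tree(tree) -> History:
    """Build a :class:`History` from a nested tuple tree.

    ``tree`` is either a leaf label (``str``) or a pair
    ``(label, [subtree, ...])``.
    """

    down: dict[HistoryNode, dict[Clade, HistoryNode]] = {}

    def build(t) -> HistoryNode:
        if isinstance(t, str):
            return leaf_node(t)
        label, subtrees = t
        if not subtrees:
            return leaf_node(label)
        choice = {}
        for sub in subtrees:
            child = build(sub)
            cu = child.clade_union()
            if cu in choice:
                raise ValueError(f"duplicate child clade {sorted(cu)}")
            choice[cu] = child
        node = HistoryNode(label, frozenset(choice))
        down[node] = choice
        return node

    root = build(tree)
    return History(root, down)


class HistorySDAG:
    """A DAG of :class:`HistoryNode` vertices under the UA vertex.

    Edges are stored grouped by the parent's child clade:
    ``children[parent][clade]`` is the set of candidate child vertices for
    that clade.  The UA vertex's single "clade" is the full leaf label set.
    """

    def __init__(self):
        self.children: dict[HistoryNode, dict[Clade, set]] = {}
        self.ua_children: set = set()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_histories(cls, histories: Iterable[History]) -> "HistorySDAG":
        """Graph union of histories: union of vertex sets and edge sets."""
        dag = cls()
        leaf_set = None
        seq_len = None
        for h in histories:
            labels = h.leaf_labels()
            if leaf_set is None:
                leaf_set = labels
                seq_len = len(next(iter(labels)))
                for lab in labels:
                    validate_sequence(lab, allow_ambiguity=False)
            elif labels != leaf_set:
                raise ValueError("histories have mismatched leaf label sets")
            for v in h.nodes():
                if len(v.label) != seq_len:
                    raise ValueError("unequal sequence lengths")
                validate_sequence(v.label, allow_ambiguity=not v.is_leaf())
                dag._ensure_node(v)
            for parent, choice in h.down.items():
                for clade, child in choice.items():
                    dag.children[parent][clade].add(child)
            dag.ua_children.add(h.root)
        if leaf_set is None:
            raise ValueError("no histories given")
        dag._check_acyclic()
        return dag

    def _ensure_node(self, v: HistoryNode) -> None:
        if v not in self.children:
            self.children[v] = {clade: set() for clade in v.clades}

    def add_edge(self, parent, child: HistoryNode) -> None:
        if parent is UA:
            if child.clade_union() != self.leaf_labels():
                raise ValueError("UA child must cover the full leaf set")
            self._ensure_node(child)
            self.ua_children.add(child)
            return
        cu = child.clade_union()
        if cu not in parent.clades:
            raise ValueError("edge violates clade-union constraint")
        self._ensure_node(parent)
        self._ensure_node(child)
        self.children[parent][cu].add(child)

    def copy(self) -> "HistorySDAG":
        dag = HistorySDAG()
        dag.children = {
            v: {c: set(s) for c, s in cl.items()} for v, cl in self.children.items()
        }
        dag.ua_children = set(self.ua_children)
        return dag

    # -- basic queries -----------------------------------------------------
    def nodes(self) -> list[HistoryNode]:
        return list(self.children)

    def leaf_labels(self) -> Clade:
        for v in self.ua_children:
            return v.clade_union()
        raise ValueError("empty DAG")

    def edges(self, include_ua: bool = False) -> Iterator[tuple]:
        if include_ua:
            for c in self.ua_children:
                yield (UA, c)
        for parent, clades in self.children.items():
            for kids in clades.values():
                for child in kids:
                    yield (parent, child)

    def n_edges(self) -> int:
        return sum(1 for _ in self.edges(include_ua=True))

    def clade_children(self, node) -> dict[Clade, set]:
        """clade -> candidate children mapping; UA gets its single pseudo-clade."""
        if node is UA:
            return {self.leaf_labels(): set(self.ua_children)}
        return self.children[node]

    def topological_order(self) -> list[HistoryNode]:
        """Parents before children; raises on cycles."""
        order: list[HistoryNode] = []
        state: dict[HistoryNode, int] = {}  # 1=in progress, 2=done

        for start in sorted(self.ua_children, key=_node_sort_key):
            stack = [(start, iter(self._child_list(start)))]
            if state.get(start) == 2:
                continue
            state[start] = 1
            while stack:
                v, it = stack[-1]
                advanced = False
                for child in it:
                    st = state.get(child)
                    if st == 1:
                        raise ValueError("cycle detected in history DAG")
                    if st is None:
                        state[child] = 1
                        stack.append((child, iter(self._child_list(child))))
                        advanced = True
                        break
                if not advanced:
                    state[v] = 2
                    order.append(v)
                    stack.pop()
        order.reverse()
        return order

    def _child_list(self, v: HistoryNode) -> list[HistoryNode]:
        return [c for kids in self.children[v].values() for c in kids]

    def reachable_nodes(self) -> set:
        seen = set()
        stack = list(self.ua_children)
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self._child_list(v))
        return seen

    # -- validity ----------------------------------------------------------
    def _check_acyclic(self) -> None:
        self.topological_order()

    def validate(self) -> None:
        """Assert the structural invariants; raises ValueError on violation."""
        if not self.ua_children:
            raise ValueError("empty DAG")
        leaf_set = self.leaf_labels()
        for c in self.ua_children:
            if c.clade_union() != leaf_set:
                raise ValueError("UA child with wrong clade union")
        for parent, clades in self.children.items():
            for clade, kids in clades.items():
                for child in kids:
                    if child.clade_union() != clade:
                        raise ValueError("edge violates clade-union constraint")
        for v in self.reachable_nodes():
            for clade, kids in self.children[v].items():
                if not kids:
                    raise ValueError(f"dead-end clade {sorted(clade)} at {v!r}")
        self._check_acyclic()

    # -- pruning -----------------------------------------------------------
    def prune(self) -> "HistorySDAG":
        """Drop dead-end vertices (a clade with no child) and unreachable ones."""
        dag = self.copy()
        changed = True
        while changed:
            changed = False
            dead = {
                v
                for v, clades in dag.children.items()
                if any(not kids for kids in clades.values())
            }
            if dead:
                changed = True
                for v in dead:
                    del dag.children[v]
                dag.ua_children -= dead
                for clades in dag.children.values():
                    for kids in clades.values():
                        kids -= dead
        keep = dag.reachable_nodes()
        dag.children = {v: cl for v, cl in dag.children.items() if v in keep}
        if not dag.ua_children:
            raise ValueError("pruning removed every history")
        return dag

    # -- history enumeration ----------------------------------------------
    def enumerate_histories(self) -> Iterator[History]:
        """Yield each expressed history exactly once.

        A history is formed by choosing one child of the UA vertex, then one
        child for each child clade of each chosen vertex, recursively.
        """
        memo: dict[HistoryNode, list] = {}

        def sub(v: HistoryNode) -> list:
            # list of down-maps for the subtree rooted at v
            if v.is_leaf():
                return [{}]
            if v in memo:
                return memo[v]
            per_clade = []
            for clade in sorted(v.clades, key=_clade_sort_key):
                options = []
                for child in sorted(self.children[v][clade], key=_node_sort_key):
                    for m in sub(child):
                        options.append((child, m))
                per_clade.append((clade, options))
            results = []
            for combo in itertools.product(*(opts for _, opts in per_clade)):
                down = {}
                choice = {}
                for (clade, _), (child, m) in zip(per_clade, combo):
                    choice[clade] = child
                    down.update(m)
                down[v] = choice
                results.append(down)
            memo[v] = results
            return results

        for root in sorted(self.ua_children, key=_node_sort_key):
            for down in sub(root):
                yield History(root, dict(down))

    # -- editing operations ------------------------------------------------
    def expand_ambiguities(self, cap: int = 100_000) -> "HistorySDAG":
        """Replace ambiguous internal vertices by all their disambiguations.

        Each internal vertex whose label carries IUPAC ambiguity codes is
        replaced by one vertex per compatible unambiguous sequence (per-site
        Cartesian product), inheriting all incident edges.  Raises
        :class:`AmbiguityExpansionError` if a single vertex would expand to
        more than ``cap`` vertices.
        """
        repl: dict[HistoryNode, list[HistoryNode]] = {}
        for v in self.children:
            if not v.is_leaf() and is_ambiguous(v.label):
                n = n_disambiguations(v.label)
                if n > cap:
                    raise AmbiguityExpansionError(
                        f"vertex would expand to {n} > cap {cap} vertices"
                    )
                repl[v] = [HistoryNode(s, v.clades) for s in disambiguations(v.label)]
            else:
                repl[v] = [v]

        dag = HistorySDAG()
        for v, images in repl.items():
            for im in images:
                dag._ensure_node(im)
        for parent, clades in self.children.items():
            for clade, kids in clades.items():
                for child in kids:
                    for pim in repl[parent]:
                        for cim in repl[child]:
                            dag.children[pim][clade].add(cim)
        for c in self.ua_children:
            for cim in repl[c]:
                dag.ua_children.add(cim)
        return dag

    def complete(self) -> "HistorySDAG":
        """Add every structurally valid edge.

        An edge ``(vp, vc)`` is added whenever ``CU(vc)`` equals one of
        ``vp``'s child clades, and a UA edge to every vertex whose clade
        union is the full leaf set.  Edges between vertices of equal clade
        union (unary chains) are never *added*, which keeps completion
        acyclic; such edges only occur if present in the input histories.
        """
        dag = self.copy()
        by_cu: dict[Clade, list[HistoryNode]] = {}
        for v in dag.children:
            by_cu.setdefault(v.clade_union(), []).append(v)
        for parent in list(dag.children):
            pcu = parent.clade_union()
            for clade in parent.clades:
                if clade == pcu:
                    continue
                for cand in by_cu.get(clade, ()):
                    dag.children[parent][clade].add(cand)
        full = dag.leaf_labels()
        for cand in by_cu.get(full, ()):
            dag.ua_children.add(cand)
        return dag

    def collapse(self, max_rounds: int = 10_000) -> "HistorySDAG":
        """Remove internal equal-label edges from every expressed history.

        For each edge ``(vp, vc)`` with ``vc`` internal and equal labels, a
        merged vertex absorbing ``vc``'s clades into ``vp`` is added (taking
        over ``vp``'s other children, ``vc``'s children and ``vp``'s
        parents), and the offending edge is removed.  Iterates to a fixed
        point, then prunes.  Leaf-adjacent zero-mutation edges are retained.
        """
        dag = self.copy()
        for _ in range(max_rounds):
            target = None
            for parent, clades in dag.children.items():
                for clade, kids in clades.items():
                    for child in kids:
                        if not child.is_leaf() and child.label == parent.label:
                            target = (parent, clade, child)
                            break
                    if target:
                        break
                if target:
                    break
            if target is None:
                return dag.prune()
            parent, clade, child = target
            merged_clades = frozenset((parent.clades - {clade}) | child.clades)
            merged = HistoryNode(parent.label, merged_clades)
            dag._ensure_node(merged)
            for other_clade in parent.clades - {clade}:
                dag.children[merged][other_clade] |= dag.children[parent][other_clade]
            for child_clade in child.clades:
                dag.children[merged][child_clade] |= dag.children[child][child_clade]
            # merged vertex inherits all of parent's incoming edges
            if parent in dag.ua_children:
                dag.ua_children.add(merged)
            for gp, gclades in list(dag.children.items()):
                for gclade, gkids in gclades.items():
                    if parent in gkids:
                        gkids.add(merged)
            dag.children[parent][clade].discard(child)
        raise RuntimeError("collapse did not converge")

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"HistorySDAG(n_nodes={len(self.children)}, "
            f"n_edges={self.n_edges()})"
        )


def _clade_sort_key(clade: Clade):
    return tuple(sorted(clade))


def _node_sort_key(v: HistoryNode):
    return (v.label, tuple(sorted(_clade_sort_key(c) for c in v.clades)))
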