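"""Core history DAG construction and editing operations."""

import itertools

import numpy as np
import pytest

from phylodag import (
    AmbiguityExpansionError,
    History,
    HistoryNode,
    HistorySDAG,
    UA,
    clade_union,
    history_from_tree,
    leaf_node,
)
from phylodag.parsimony import parsimony_criterion, parsimony_score
from phylodag.weights import count_histories, trim

from conftest import (
    brute_force_histories,
    history_edge_set,
    random_history,
    random_sequences,
)


def fig_example_node():
    clades = frozenset(
        {frozenset({"GAA"}), frozenset({"AAA", "ACT", "GAT"})}
    )
    return HistoryNode("GAA", clades)


class TestCladeUnion:
    def test_internal_node(self):
        assert clade_union(fig_example_node()) == {"GAA", "AAA", "ACT", "GAT"}

    def test_leaf_is_singleton(self):
        assert clade_union(leaf_node("ACT")) == {"ACT"}

    def test_union_of_disjoint_singletons(self):
        node = HistoryNode(
            "AAA",
            frozenset({frozenset({"A"}), frozenset({"C"}), frozenset({"G"})}),
        )
        assert clade_union(node) == {"A", "C", "G"}


def two_fig_histories():
    """Two histories on the same four leaves, sharing substructure."""
    h1 = history_from_tree(
        ("GAA", ["GAA", ("AAA", ["AAA", ("ACT", ["ACT", "GAT"])])])
    )
    h2 = history_from_tree(
        ("GAA", ["GAA", ("AAA", ["AAA", ("GAT", ["ACT", "GAT"])])])
    )
    return h1, h2


class TestFromHistories:
    def test_single_history_roundtrip(self):
        h1, _ = two_fig_histories()
        dag = HistorySDAG.from_histories([h1])
        result = list(dag.enumerate_histories())
        assert result == [h1]

    def test_two_histories_both_recoverable(self):
        h1, h2 = two_fig_histories()
        dag = HistorySDAG.from_histories([h1, h2])
        dag.validate()
        edge_sets = {history_edge_set(h) for h in dag.enumerate_histories()}
        assert history_edge_set(h1) in edge_sets
        assert history_edge_set(h2) in edge_sets
        # shared substructure stored once
        all_nodes = set(h1.nodes()) | set(h2.nodes())
        assert set(dag.nodes()) == all_nodes

    def test_mismatched_leaf_sets_rejected(self):
        h1 = history_from_tree(("AA", ["AC", "AG"]))
        h2 = history_from_tree(("AA", ["AC", "AT"]))
        with pytest.raises(ValueError, match="leaf"):
            HistorySDAG.from_histories([h1, h2])

    def test_unequal_lengths_rejected(self):
        h1 = history_from_tree(("AAA", ["ACA", "AGA"]))
        bad = History(h1.root, h1.down)
        h2 = history_from_tree(("AA", ["AC", "AG"]))
        with pytest.raises(ValueError):
            HistorySDAG.from_histories([h2, bad])

    def test_ambiguous_leaf_rejected(self):
        h = history_from_tree(("AA", ["AN", "AG"]))
        with pytest.raises(ValueError):
            HistorySDAG.from_histories([h])

    def test_union_expresses_recombinations(self, rng):
        # two histories differing in one subtree's resolution can combine
        leaves = random_sequences(rng, 4, 6)
        h1 = random_history(rng, leaves)
        h2 = random_history(rng, leaves)
        dag = HistorySDAG.from_histories([h1, h2])
        enumerated = {history_edge_set(h) for h in dag.enumerate_histories()}
        assert enumerated == brute_force_histories(dag)
        assert {history_edge_set(h1), history_edge_set(h2)} <= enumerated


class TestEnumerateHistories:
    def test_forced_dag_single_history(self):
        h = history_from_tree(("CC", ["CA", "CT"]))
        dag = HistorySDAG.from_histories([h])
        assert len(list(dag.enumerate_histories())) == 1

    def test_one_free_choice_gives_two(self):
        h1 = history_from_tree(("CC", ["CA", ("CT", ["CG", "TT"])]))
        h2 = history_from_tree(("CC", ["CA", ("GG", ["CG", "TT"])]))
        dag = HistorySDAG.from_histories([h1, h2])
        assert len(list(dag.enumerate_histories())) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        leaves = random_sequences(rng, int(rng.integers(3, 7)), 5)
        histories = [random_history(rng, leaves) for _ in range(3)]
        dag = HistorySDAG.from_histories(histories)
        enumerated = [history_edge_set(h) for h in dag.enumerate_histories()]
        assert len(enumerated) == len(set(enumerated)), "duplicate histories"
        assert set(enumerated) == brute_force_histories(dag)
        assert len(enumerated) == count_histories(dag)


class TestExpandAmbiguities:
    def test_iupac_r_expands_to_two(self):
        h = history_from_tree(("ART", ["AAT", "AGG"]))
        dag = HistorySDAG.from_histories([h]).expand_ambiguities()
        labels = {v.label for v in dag.nodes() if not v.is_leaf()}
        assert labels == {"AAT", "AGT"}
        clade_sets = {v.clades for v in dag.nodes() if not v.is_leaf()}
        assert len(clade_sets) == 1

    def test_no_ambiguity_identity(self, rng):
        leaves = random_sequences(rng, 4, 5)
        dag = HistorySDAG.from_histories([random_history(rng, leaves)])
        expanded = dag.expand_ambiguities()
        assert set(expanded.nodes()) == set(dag.nodes())
        assert set(expanded.edges(include_ua=True)) == set(dag.edges(include_ua=True))

    def test_n_site_expansion_then_trim_matches_fitch_oracle(self):
        # one internal N site -> 4 disambiguations; MP trim must retain
        # exactly the relabelings minimizing total Hamming distance.
        h = history_from_tree(("ANA", ["ACA", "AGA"]))
        dag = HistorySDAG.from_histories([h]).expand_ambiguities()
        assert count_histories(dag) == 4
        trimmed = trim(dag, parsimony_criterion())
        kept = {hh.root.label for hh in trimmed.enumerate_histories()}
        # oracle: brute-force scores of all 4 assignments
        scores = {
            f"A{b}A": parsimony_score(history_from_tree((f"A{b}A", ["ACA", "AGA"])))
            for b in "ACGT"
        }
        best = min(scores.values())
        assert kept == {lab for lab, s in scores.items() if s == best}

    def test_expansion_cap(self):
        h = history_from_tree(("N" * 10, ["A" * 10, "C" * 10]))
        dag = HistorySDAG.from_histories([h])
        with pytest.raises(AmbiguityExpansionError):
            dag.expand_ambiguities(cap=1000)


class TestComplete:
    def test_idempotent(self):
        h1, h2 = two_fig_histories()
        dag = HistorySDAG.from_histories([h1, h2]).complete()
        again = dag.complete()
        assert set(dag.edges(include_ua=True)) == set(again.edges(include_ua=True))

    def test_same_clades_different_labels_both_linked(self):
        h1 = history_from_tree(("CC", ["CA", ("CT", ["CG", "TT"])]))
        h2 = history_from_tree(("AA", ["CA", ("GG", ["CG", "TT"])]))
        dag = HistorySDAG.from_histories([h1, h2]).complete()
        # both subtree resolutions now available under both roots
        clade = frozenset({"CG", "TT"})
        for root in dag.ua_children:
            assert {c.label for c in dag.children[root][clade]} == {"CT", "GG"}

    def test_superset_of_input_histories(self, rng):
        leaves = random_sequences(rng, 4, 4)
        histories = [random_history(rng, leaves) for _ in range(2)]
        dag = HistorySDAG.from_histories(histories)
        before = {history_edge_set(h) for h in dag.enumerate_histories()}
        completed = dag.complete()
        after = {history_edge_set(h) for h in completed.enumerate_histories()}
        assert before <= after
        assert after == brute_force_histories(completed)
        for h in completed.enumerate_histories():
            assert h.leaf_labels() == frozenset(leaves)


class TestCollapse:
    def test_internal_equal_label_edge_removed(self):
        h = history_from_tree(("AAA", [("AAA", ["AGA", "ATA"]), "ACA"]))
        dag = HistorySDAG.from_histories([h]).collapse()
        (collapsed,) = dag.enumerate_histories()
        assert len(collapsed.nodes()) == 4  # one internal node, three leaves
        assert collapsed.root.label == "AAA"
        assert len(collapsed.root.clades) == 3

    def test_leaf_adjacent_zero_mutation_edge_kept(self):
        h = history_from_tree(("AAA", ["AAA", "ACA"]))
        dag = HistorySDAG.from_histories([h]).collapse()
        (collapsed,) = dag.enumerate_histories()
        assert history_edge_set(collapsed) == history_edge_set(h)

    def test_collapse_preserves_parsimony_score(self, rng):
        leaves = random_sequences(rng, 5, 6)
        h = random_history(rng, leaves, internal_pool=leaves)
        dag = HistorySDAG.from_histories([h])
        score_before = parsimony_score(h)
        collapsed = dag.collapse()
        for ch in collapsed.enumerate_histories():
            assert parsimony_score(ch) == score_before

    def test_no_uncollapsed_edges_remain(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            leaves = random_sequences(local, 4, 4)
            hs = [
                random_history(local, leaves, internal_pool=leaves)
                for _ in range(2)
            ]
            dag = HistorySDAG.from_histories(hs).collapse()
            for h in dag.enumerate_histories():
                for parent, child in h.edges():
                    assert child.is_leaf() or parent.label != child.label
                assert h.leaf_labels() == frozenset(leaves)

    def test_collapse_never_increases_history_count(self, rng):
        leaves = random_sequences(rng, 4, 4)
        hs = [random_history(rng, leaves, internal_pool=leaves) for _ in range(3)]
        dag = HistorySDAG.from_histories(hs)
        assert count_histories(dag.collapse()) <= count_histories(dag)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(3))
    def test_clade_consistency_after_operations(self, seed):
        rng = np.random.default_rng(seed)
        leaves = random_sequences(rng, 4, 4)
        hs = [random_history(rng, leaves, internal_pool=leaves) for _ in range(2)]
        dag = HistorySDAG.from_histories(hs)
        for op in (
            lambda d: d.expand_ambiguities(),
            lambda d: d.complete(),
            lambda d: d.collapse(),
            lambda d: trim(d, parsimony_criterion()),
        ):
            out = op(dag)
            out.validate()

    def test_completion_monotone_in_history_count(self, rng):
        leaves = random_sequences(rng, 4, 4)
        hs = [random_history(rng, leaves) for _ in range(2)]
        dag = HistorySDAG.from_histories(hs)
        assert count_histories(dag.complete()) >= count_histories(dag)
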