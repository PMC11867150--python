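"""Dynamic programming engine vs. brute-force enumeration."""

import math

import numpy as np
import pytest

from phylodag import (
    HistorySDAG,
    RankingCriterion,
    UA,
    count_histories,
    history_from_tree,
    lexicographic_trim,
    linear_combination,
    marginalize,
    optimal_weight,
    trim,
)
from phylodag.context import context_criterion
from phylodag.parsimony import hamming_edge_weight, parsimony_criterion

from conftest import (
    brute_force_histories,
    brute_force_weight,
    history_edge_set,
    random_history,
    random_sequences,
)


def random_dag(seed, n_leaves=4, length=4, n_histories=3, complete=True):
    rng = np.random.default_rng(seed)
    leaves = random_sequences(rng, n_leaves, length)
    hs = [
        random_history(rng, leaves, internal_pool=leaves if seed % 2 else None)
        for _ in range(n_histories)
    ]
    dag = HistorySDAG.from_histories(hs)
    return dag.complete() if complete else dag


def random_edge_fn(seed):
    rng = np.random.default_rng(seed)
    cache = {}

    def fn(parent, child):
        key = (None if parent is UA else parent, child)
        if key not in cache:
            cache[key] = float(rng.normal())
        return cache[key]

    return fn


class TestOptimalWeight:
    def test_single_history_weight(self):
        h = history_from_tree(("AAA", ["ACA", ("AGA", ["AGT", "GGA"])]))
        dag = HistorySDAG.from_histories([h])
        crit = parsimony_criterion()
        assert optimal_weight(dag, crit) == h.weight(hamming_edge_weight)

    @pytest.mark.parametrize("seed", range(6))
    def test_parsimony_matches_enumeration(self, seed):
        dag = random_dag(seed)
        got = optimal_weight(dag, parsimony_criterion())
        assert got == brute_force_weight(dag, hamming_edge_weight, best=min)

    def test_zero_function_gives_zero(self):
        dag = random_dag(0)
        crit = RankingCriterion(edge_fn=lambda p, c: 0, direction="min")
        assert optimal_weight(dag, crit) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_max_direction_random_weights(self, seed):
        dag = random_dag(seed)
        fn = random_edge_fn(seed)
        crit = RankingCriterion(edge_fn=fn, direction="max")
        got = optimal_weight(dag, crit)
        want = brute_force_weight(dag, fn, best=max)
        assert got == pytest.approx(want, abs=1e-12)

    def test_empty_dag_raises(self):
        with pytest.raises(ValueError):
            optimal_weight(HistorySDAG(), parsimony_criterion())


class TestTrim:
    @pytest.mark.parametrize("seed", range(6))
    def test_trim_keeps_exactly_the_optima(self, seed):
        dag = random_dag(seed)
        crit = parsimony_criterion()
        best = brute_force_weight(dag, hamming_edge_weight, best=min)
        optima = {
            edges
            for edges in brute_force_histories(dag)
            if sum(hamming_edge_weight(p, c) for p, c in edges) == best
        }
        trimmed = trim(dag, crit)
        trimmed.validate()
        got = {history_edge_set(h) for h in trimmed.enumerate_histories()}
        assert got == optima

    def test_idempotent(self):
        dag = random_dag(1)
        crit = parsimony_criterion()
        once = trim(dag, crit)
        twice = trim(once, crit)
        assert set(once.edges(include_ua=True)) == set(twice.edges(include_ua=True))

    def test_constant_function_trims_nothing(self):
        dag = random_dag(2)
        crit = RankingCriterion(edge_fn=lambda p, c: 1.0, direction="min")
        trimmed = trim(dag, crit)
        assert count_histories(trimmed) == count_histories(dag)

    def test_trim_preserves_optimal_weight_and_count_bound(self):
        dag = random_dag(3)
        crit = parsimony_criterion()
        before = optimal_weight(dag, crit)
        trimmed = trim(dag, crit)
        assert optimal_weight(trimmed, crit) == before
        assert count_histories(trimmed) <= count_histories(dag)


class TestCountHistories:
    def test_single_history(self):
        h = history_from_tree(("AA", ["AC", "AG"]))
        assert count_histories(HistorySDAG.from_histories([h])) == 1

    def test_one_free_choice(self):
        h1 = history_from_tree(("CC", ["CA", ("CT", ["CG", "TT"])]))
        h2 = history_from_tree(("CC", ["CA", ("GG", ["CG", "TT"])]))
        assert count_histories(HistorySDAG.from_histories([h1, h2])) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_length(self, seed):
        dag = random_dag(seed)
        assert count_histories(dag) == len(list(dag.enumerate_histories()))


class TestMarginalize:
    def test_single_history_sum(self):
        h = history_from_tree(("AAA", ["ACA", "AGT"]))
        dag = HistorySDAG.from_histories([h])
        fn = random_edge_fn(0)
        want = sum(fn(p, c) for p, c in h.edges(include_ua=True))
        assert marginalize(dag, fn) == pytest.approx(want, abs=1e-12)

    def test_zero_function_counts_histories(self):
        dag = random_dag(4)
        got = marginalize(dag, lambda p, c: 0.0)
        assert got == pytest.approx(math.log(count_histories(dag)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_explicit_sum(self, seed):
        dag = random_dag(seed)
        fn = random_edge_fn(seed + 100)
        explicit = math.log(
            sum(
                math.exp(sum(fn(p, c) for p, c in edges))
                for edges in brute_force_histories(dag)
            )
        )
        assert marginalize(dag, fn) == pytest.approx(explicit, abs=1e-9)

    def test_representation_invariance(self):
        dag = random_dag(5)
        fn = random_edge_fn(5)
        rebuilt = HistorySDAG.from_histories(list(dag.enumerate_histories()))
        assert marginalize(dag, fn) == pytest.approx(
            marginalize(rebuilt, fn), abs=1e-9
        )


class TestLexicographicTrim:
    def test_single_criterion_same_as_trim(self):
        dag = random_dag(6)
        crit = parsimony_criterion()
        a = trim(dag, crit)
        b = lexicographic_trim(dag, [crit])
        assert set(a.edges(include_ua=True)) == set(b.edges(include_ua=True))

    def test_constant_first_criterion_is_ignored(self):
        dag = random_dag(7)
        const = RankingCriterion(edge_fn=lambda p, c: 2.0, direction="min")
        crit = parsimony_criterion()
        a = lexicographic_trim(dag, [const, crit])
        b = trim(dag, crit)
        assert set(a.edges(include_ua=True)) == set(b.edges(include_ua=True))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_lexicographic_sort(self, seed, model):
        dag = random_dag(seed)
        pars = parsimony_criterion()
        ctx = context_criterion(model)
        trimmed = lexicographic_trim(dag, [pars, ctx])

        def history_key(edges):
            p = sum(hamming_edge_weight(a, b) for a, b in edges)
            c = sum(ctx.edge_fn(a, b) for a, b in edges)
            return (p, -c)  # minimize parsimony, then maximize context

        all_histories = brute_force_histories(dag)
        best_key = min(history_key(e) for e in all_histories)
        want = {
            e
            for e in all_histories
            if history_key(e)[0] == best_key[0]
            and math.isclose(history_key(e)[1], best_key[1], rel_tol=1e-9, abs_tol=1e-9)
        }
        got = {history_edge_set(h) for h in trimmed.enumerate_histories()}
        assert got == want


class TestLinearCombination:
    def test_single_coefficient_identity(self):
        fn = random_edge_fn(8)
        combo = linear_combination([fn, random_edge_fn(9)], [1.0, 0.0])
        dag = random_dag(8)
        for p, c in dag.edges(include_ua=True):
            assert combo(p, c) == pytest.approx(fn(p, c), abs=1e-15)

    def test_sum_identity_on_histories(self):
        dag = random_dag(9)
        f1, f2 = random_edge_fn(10), random_edge_fn(11)
        combo = linear_combination([f1, f2], [1.0, 1.0])
        for h in dag.enumerate_histories():
            want = h.weight(f1, zero=0.0) + h.weight(f2, zero=0.0)
            assert h.weight(combo, zero=0.0) == pytest.approx(want, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            linear_combination([random_edge_fn(0)], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_optimum_via_enumeration(self, seed):
        dag = random_dag(seed)
        rng = np.random.default_rng(seed)
        f1, f2 = random_edge_fn(seed + 20), random_edge_fn(seed + 30)
        a1, a2 = rng.normal(size=2)
        combo = linear_combination([f1, f2], [a1, a2])
        crit = RankingCriterion(edge_fn=combo, direction="min")
        want = brute_force_weight(dag, combo, best=min)
        assert optimal_weight(dag, crit) == pytest.approx(want, abs=1e-10)
        # combined optimum can only match the combination of per-criterion
        # optima when one history co-optimizes both
        opt1 = brute_force_weight(dag, f1, best=min if a1 > 0 else max)
        opt2 = brute_force_weight(dag, f2, best=min if a2 > 0 else max)
        assert want >= a1 * opt1 + a2 * opt2 - 1e-10
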