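"""Connectome aggregation, reference comparison, permutation test, depth."""

import random

import numpy as np
import pytest
from oracles import oracle_aggregate, oracle_compare, oracle_symmetrize

from litconn.connectome import (
    CONNECTED,
    DEFAULT_WEIGHTS,
    NOT_CONNECTED,
    NOT_EVALUATED,
    ConnectivityMatrix,
    ReferenceMatrix,
    aggregate,
    compare,
    mean_depth,
    permutation_test,
    symmetrize,
)
from litconn.corpus import TextSpan
from litconn.extractors import ConnectivityStatement, make_pair
from litconn.lexical_ner import Mention
from litconn.lexicon import Lexicon, RegionEntry


def _stmt(a, b, fired, k=0):
    m1 = Mention(span=TextSpan("d", k * 40, k * 40 + 4), surface="aaaa",
                 region_id=a, source="lexical")
    m2 = Mention(span=TextSpan("d", k * 40 + 10, k * 40 + 14), surface="bbbb",
                 region_id=b, source="lexical")
    return ConnectivityStatement(pair=make_pair("d", 0, m1, m2), fired_by=frozenset(fired))


class TestAggregate:
    def test_single_rules_statement_weighs_072(self):
        m = aggregate([_stmt("R1", "R2", {"RULES"})])
        assert m.weight("R1", "R2") == pytest.approx(0.72)
        assert m.weight("R2", "R1") == pytest.approx(0.72)

    def test_max_weight_over_fired_extractors(self):
        m = aggregate([_stmt("R1", "R2", {"FILTERS", "RULES"})])
        assert m.weight("R1", "R2") == pytest.approx(0.72)

    def test_zero_statements_zero_matrix(self):
        m = aggregate([], regions=["R1", "R2"])
        assert not m.values.any()

    def test_unnormalized_statements_skipped(self):
        m1 = Mention(span=TextSpan("d", 0, 4), surface="aaaa", region_id=None, source="crf")
        m2 = Mention(span=TextSpan("d", 10, 14), surface="bbbb", region_id="R2", source="lexical")
        st = ConnectivityStatement(pair=make_pair("d", 0, m1, m2), fired_by=frozenset({"FILTERS"}))
        m = aggregate([st], regions=["R2"])
        assert not m.values.any()

    def test_random_multisets_match_accumulation_oracle(self):
        rng = random.Random(43)
        regions = [f"R{i}" for i in range(8)]
        for _ in range(100):
            stmts, triples = [], []
            for k in range(rng.randint(1, 25)):
                a, b = rng.sample(regions, 2)
                fired = set(rng.sample(["FILTERS", "KERNEL", "RULES"], rng.randint(1, 3)))
                stmts.append(_stmt(a, b, fired, k))
                triples.append((frozenset((a, b)), fired))
            m = aggregate(stmts, regions=regions)
            expected = oracle_aggregate(triples, DEFAULT_WEIGHTS)
            for ids, w in expected.items():
                a, b = sorted(ids)
                assert m.weight(a, b) == pytest.approx(w)
            assert m.values.sum() == pytest.approx(2 * sum(expected.values()))

    def test_aggregation_is_additive(self):
        rng = random.Random(47)
        regions = [f"R{i}" for i in range(6)]
        part1 = [_stmt(*rng.sample(regions, 2), {"KERNEL"}, k) for k in range(10)]
        part2 = [_stmt(*rng.sample(regions, 2), {"RULES"}, k) for k in range(10)]
        whole = aggregate(part1 + part2, regions=regions)
        split = aggregate(part1, regions=regions).values + aggregate(part2, regions=regions).values
        assert np.allclose(whole.values, split)


def _random_reference(rng, n):
    states = rng.choice([CONNECTED, NOT_CONNECTED, NOT_EVALUATED], size=(n, n))
    return ReferenceMatrix([f"R{i}" for i in range(n)], states.astype(np.int8))


class TestSymmetrize:
    def test_or_rule(self):
        states = np.full((2, 2), NOT_EVALUATED, dtype=np.int8)
        states[0, 1] = CONNECTED
        states[1, 0] = NOT_CONNECTED
        sym = symmetrize(ReferenceMatrix(["a", "b"], states))
        assert sym.states[0, 1] == CONNECTED and sym.states[1, 0] == CONNECTED

    def test_symmetric_input_unchanged(self):
        rng = np.random.default_rng(3)
        ref = symmetrize(_random_reference(rng, 6))
        again = symmetrize(ref)
        assert np.array_equal(ref.states, again.states)

    def test_random_matrices_match_truth_table_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ref = _random_reference(rng, int(rng.integers(2, 8)))
            sym = symmetrize(ref)
            assert np.array_equal(sym.states, oracle_symmetrize(ref.states))


class TestCompare:
    def test_reported_worked_counts_give_78_percent(self):
        # 904 evaluable-connected + 261 evaluable-unconnected literature pairs
        n = 49  # C(49, 2) = 1176 >= 1165
        regions = [f"R{i}" for i in range(n)]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        lit_vals = np.zeros((n, n))
        states = np.full((n, n), NOT_EVALUATED, dtype=np.int8)
        for k, (i, j) in enumerate(pairs[:1165]):
            lit_vals[i, j] = lit_vals[j, i] = 1.0
            s = CONNECTED if k < 904 else NOT_CONNECTED
            states[i, j] = states[j, i] = s
        result = compare(
            ConnectivityMatrix(regions, lit_vals), ReferenceMatrix(regions, states)
        )
        assert (result.n_tp, result.n_fp) == (904, 261)
        assert result.precision == pytest.approx(904 / 1165)
        assert round(100 * result.precision) == 78

    def test_all_unevaluable_precision_none(self):
        lit = ConnectivityMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        ref = ReferenceMatrix(["c", "d"], np.full((2, 2), NOT_EVALUATED, dtype=np.int8))
        result = compare(lit, ref)
        assert result.precision is None
        assert result.n_unevaluable == 1

    def test_threshold_excludes_weak_pairs(self):
        lit = ConnectivityMatrix(["a", "b"], np.array([[0.0, 0.45], [0.45, 0.0]]))
        states = np.full((2, 2), CONNECTED, dtype=np.int8)
        np.fill_diagonal(states, NOT_EVALUATED)
        ref = ReferenceMatrix(["a", "b"], states)
        assert compare(lit, ref, threshold=0.0).n_tp == 1
        assert compare(lit, ref, threshold=1.0).n_lit_pairs == 0

    def test_random_instances_match_classification_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            regions = [f"R{i}" for i in range(n)]
            vals = np.triu((rng.random((n, n)) < 0.4).astype(float), k=1)
            vals = vals + vals.T
            lit = ConnectivityMatrix(regions, vals)
            # reference over a shifted region universe (some absent from ref)
            ref_regions = [f"R{i}" for i in range(1, n + 1)]
            ref = symmetrize(
                ReferenceMatrix(
                    ref_regions,
                    rng.choice(
                        [CONNECTED, NOT_CONNECTED, NOT_EVALUATED], size=(n, n)
                    ).astype(np.int8),
                )
            )
            result = compare(lit, ref)
            n_pairs, tp, fp, un = oracle_compare(
                regions, vals, ref_regions, ref.states
            )
            assert (result.n_lit_pairs, result.n_tp, result.n_fp, result.n_unevaluable) == (
                n_pairs, tp, fp, un
            )

    def test_precision_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(13)
        n = 8
        regions = [f"R{i}" for i in range(n)]
        vals = np.triu((rng.random((n, n)) < 0.5).astype(float), k=1)
        vals = vals + vals.T
        lit = ConnectivityMatrix(regions, vals)
        ref = symmetrize(
            ReferenceMatrix(
                regions,
                rng.choice([CONNECTED, NOT_CONNECTED], size=(n, n)).astype(np.int8),
            )
        )
        base = compare(lit, ref).precision
        perm = list(rng.permutation(n))
        relabel = {regions[i]: regions[perm[i]] for i in range(n)}
        lit2 = ConnectivityMatrix([relabel[r] for r in regions], vals)
        ref2 = ReferenceMatrix([relabel[r] for r in ref.regions], ref.states)
        assert compare(lit2, ref2).precision == pytest.approx(base)


def _structured_fixture(n=30):
    regions = [f"R{i}" for i in range(n)]
    states = np.full((n, n), NOT_CONNECTED, dtype=np.int8)
    for i in range(n):
        for step in (1, 2):
            j = (i + step) % n
            states[i, j] = states[j, i] = CONNECTED
    np.fill_diagonal(states, NOT_EVALUATED)
    ref = symmetrize(ReferenceMatrix(regions, states))
    vals = (ref.states == CONNECTED).astype(float)
    np.fill_diagonal(vals, 0.0)
    return ConnectivityMatrix(regions, vals), ref


class TestPermutationTest:
    def test_structured_fixture_is_significant(self):
        lit, ref = _structured_fixture()
        p = permutation_test(lit, ref, n_shuffles=1000, seed=2)
        assert p <= 0.01

    def test_seed_reproducibility_and_range(self):
        lit, ref = _structured_fixture()
        p1 = permutation_test(lit, ref, n_shuffles=200, seed=9)
        p2 = permutation_test(lit, ref, n_shuffles=200, seed=9)
        assert p1 == p2
        assert 0.0 < p1 <= 1.0

    def test_degenerate_reference_errors(self):
        lit = ConnectivityMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        ref = ReferenceMatrix(["a", "b"], np.full((2, 2), NOT_EVALUATED, dtype=np.int8))
        with pytest.raises(ValueError, match="evaluable"):
            permutation_test(lit, ref, n_shuffles=10, seed=0)


class TestMeanDepth:
    def _lex(self):
        return Lexicon(
            [
                RegionEntry("r", "root"),
                RegionEntry("a", "child a", parent_id="r"),
                RegionEntry("b", "child b", parent_id="r"),
                RegionEntry("c", "grandchild", parent_id="a"),
            ]
        )

    def test_uniform_depth(self):
        lex = self._lex()
        assert mean_depth([("a", "b")], lex) == pytest.approx(1.0)

    def test_empty_pairs_give_none(self):
        assert mean_depth([], self._lex()) is None

    def test_unresolvable_endpoints_skipped(self):
        lex = self._lex()
        assert mean_depth([("a", "missing")], lex) == pytest.approx(1.0)

    def test_random_pairs_match_direct_average(self):
        rng = random.Random(53)
        lex = self._lex()
        depths = {"r": 0, "a": 1, "b": 1, "c": 2}
        for _ in range(100):
            pairs = [tuple(rng.sample(list(depths), 2)) for _ in range(rng.randint(1, 10))]
            expected = np.mean([depths[x] for p in pairs for x in sorted(p)])
            assert mean_depth(pairs, lex) == pytest.approx(expected)


class TestCsvRoundTrips:
    def test_connectivity_matrix(self, tmp_path):
        rng = np.random.default_rng(17)
        vals = np.triu(rng.random((4, 4)), k=1)
        vals = vals + vals.T
        m = ConnectivityMatrix(["a", "b", "c", "d"], vals)
        m.to_csv(tmp_path / "m.csv")
        back = ConnectivityMatrix.from_csv(tmp_path / "m.csv")
        assert back.regions == m.regions
        assert np.allclose(back.values, m.values)

    def test_reference_matrix(self, tmp_path):
        rng = np.random.default_rng(19)
        ref = _random_reference(rng, 5)
        ref.to_csv(tmp_path / "r.csv")
        back = ReferenceMatrix.from_csv(tmp_path / "r.csv")
        assert back.regions == ref.regions
        assert np.array_equal(back.states, ref.states)
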