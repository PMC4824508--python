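import itertools
import logging
import math
from fractions import Fraction

import numpy as np
import pytest

import phylobeta as pb
from phylobeta.cbl_measure import (
    _cbl_variance_exact,
    binomial_ratio,
    pair_exclusion_F,
    pair_presence_probability,
)
from phylobeta.null_oracle import spanning_edges


class TestBinomialRatio:
    def test_small_values(self):
        assert binomial_ratio(2, 3, 2) == pytest.approx(1 / 3)
        assert binomial_ratio(1, 3, 2) == 0.0  # C(1,2) = 0 by convention
        assert binomial_ratio(-4, 10, 3) == 0.0
        assert binomial_ratio(10, 10, 3) == 1.0
        assert binomial_ratio(5, 9, 0) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            binomial_ratio(3, 5, 6)
        with pytest.raises(ValueError):
            binomial_ratio(3, 5, -1)

    def test_large_ratio_against_big_integer_oracle(self):
        got = binomial_ratio(50_000, 71_181, 100)
        exact = float(Fraction(math.comb(50_000, 100), math.comb(71_181, 100)))
        assert got == pytest.approx(exact, rel=1e-12)

    def test_log_gamma_fallback_consistency(self):
        # a size where the log-gamma path is taken; compare to exact integers
        x, s, r = 150_000, 200_000, 5_000
        got = binomial_ratio(x, s, r)
        exact = float(Fraction(math.comb(x, r), math.comb(s, r)))
        assert got == pytest.approx(exact, rel=1e-10)


class TestCBLValue:
    def test_worked_examples(self, t3):
        assert pb.cbl_value(t3, {"x", "y"}, {"x", "z"}) == pytest.approx(1.0)
        assert pb.cbl_value(t3, {"x", "y"}, {"x", "y"}) == pytest.approx(2.0)
        assert pb.cbl_value(t3, {"x"}, {"y", "z"}) == 0.0  # singleton spans nothing

    def test_symmetry_and_bounds(self, suite):
        for label, tree in suite:
            names = tree.tip_names
            a = set(names[: max(2, len(names) // 2)])
            b = set(names[-2:])
            v = pb.cbl_value(tree, a, b)
            assert v == pb.cbl_value(tree, b, a), label
            cap = min(
                math.fsum(tree.weight[e] for e in spanning_edges(tree, tree.resolve_sample(a))),
                math.fsum(tree.weight[e] for e in spanning_edges(tree, tree.resolve_sample(b))),
            )
            assert 0.0 <= v <= cap + 1e-12, label


class TestCBLExpectation:
    def test_worked_examples(self, t3, balanced4):
        assert pb.cbl_expectation(t3, 2, 2) == pytest.approx(16 / 9)
        assert pb.cbl_expectation(balanced4, 2, 2) == pytest.approx(17 / 9)

    def test_singleton_gives_zero(self, suite):
        for label, tree in suite:
            assert pb.cbl_expectation(tree, 1, tree.n_tips) == 0.0, label

    def test_bounded_by_total_weight(self, suite):
        for label, tree in suite:
            s = tree.n_tips
            total = float(tree.weight.sum())
            for a in range(1, s + 1):
                e = pb.cbl_expectation(tree, a, max(1, s - 1))
                assert 0.0 <= e <= total + 1e-12, label

    def test_validation(self, t3):
        with pytest.raises(ValueError):
            pb.cbl_expectation(t3, 0, 2)


class TestPairExclusion:
    def test_worked_cases(self, t3):
        cherry = int(t3.parent[t3.node_of("x")])
        ex, ez = t3.node_of("x"), t3.node_of("z")
        nested = pair_exclusion_F(t3, cherry, ex, 2)
        assert nested.relation == "l-inside-e"
        assert nested.value == pytest.approx(2 / 3)
        disjoint = pair_exclusion_F(t3, ex, ez, 2)
        assert disjoint.relation == "disjoint"
        assert disjoint.value == pytest.approx(2 / 3)
        diag = pair_exclusion_F(t3, ex, ex, 2)
        assert diag.relation == "l-inside-e"
        assert diag.value == pytest.approx(1 / 3)

    def test_diagonal_reduces_to_single_edge_presence(self, suite):
        for label, tree in suite:
            s = tree.n_tips
            x = tree.subtree_tip_count
            for e in tree.edges:
                for r in range(1, s + 1):
                    f = pair_exclusion_F(tree, int(e), int(e), r).value
                    absent = binomial_ratio(int(x[e]), s, r) + binomial_ratio(
                        s - int(x[e]), s, r
                    )
                    assert 1 - f == pytest.approx(1 - absent, rel=1e-12, abs=1e-15)

    def test_relation_classification_is_exhaustive(self, suite):
        for label, tree in suite:
            for e, l in itertools.product(tree.edges, repeat=2):
                rel = pair_exclusion_F(tree, int(e), int(l), 1).relation
                assert rel in ("l-inside-e", "e-inside-l", "disjoint")

    def test_exclusion_and_inclusion_routes_agree(self, suite):
        for label, tree in suite:
            s = tree.n_tips
            for e, l in itertools.product(tree.edges, repeat=2):
                for r in (1, 2, s):
                    p1 = pair_presence_probability(tree, int(e), int(l), r,
                                                   route="exclusion")
                    p2 = pair_presence_probability(tree, int(e), int(l), r,
                                                   route="inclusion")
                    assert p1 == pytest.approx(p2, rel=1e-12, abs=1e-12), label

    def test_invalid_edge_rejected(self, t3):
        with pytest.raises(ValueError):
            pair_exclusion_F(t3, t3.root, t3.node_of("x"), 2)
        with pytest.raises(ValueError):
            pair_exclusion_F(t3, 99, t3.node_of("x"), 2)


class TestCBLStandardDeviation:
    def test_worked_example(self, t3):
        assert pb.cbl_standard_deviation(t3, 2, 2) == pytest.approx(
            math.sqrt(50 / 81)
        )

    def test_degenerate_zeros(self, suite):
        for label, tree in suite:
            s = tree.n_tips
            assert pb.cbl_standard_deviation(tree, 1, 1) == 0.0, label
            assert pb.cbl_standard_deviation(tree, s, s) == 0.0, label

    def test_unknown_mode_rejected(self, t3):
        with pytest.raises(ValueError, match="mode"):
            pb.cbl_standard_deviation(t3, 2, 2, mode="accelerated")

    def test_float_quadratic_agrees_with_exact_rational(self):
        # above the exact cutoff the blocked numpy evaluation runs; it must
        # match the exact rational double sum
        tree = pb.generate_tree(
            pb.TreeRecipe("yule", 60, branch_length="exponential", seed=5)
        )
        for a, b in [(2, 2), (10, 25), (59, 60)]:
            sd_float = pb.cbl_standard_deviation(tree, a, b)
            sd_exact = math.sqrt(float(_cbl_variance_exact(tree, a, b)))
            assert sd_float == pytest.approx(sd_exact, rel=1e-9)


class TestCommonLengthIndex:
    def test_worked_example(self, t3):
        got = pb.common_length_index(t3, {"x", "y"}, {"x", "z"})
        expected = (1 - 16 / 9) / math.sqrt(50 / 81)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(-0.98995, abs=1e-4)

    def test_degenerate_sd_returns_nan_with_warning(self, t3, caplog):
        with caplog.at_level(logging.WARNING, logger="phylobeta.cbl_measure"):
            value = pb.common_length_index(t3, {"x"}, {"y"})
        assert math.isnan(value)
        assert "undefined" in caplog.text

    def test_scaling_invariance(self, t3):
        scaled = pb.parse_newick("((x:4,y:4):4,z:4);")
        assert pb.common_length_index(
            scaled, {"x", "y"}, {"x", "z"}
        ) == pytest.approx(
            pb.common_length_index(t3, {"x", "y"}, {"x", "z"}), rel=1e-9
        )
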