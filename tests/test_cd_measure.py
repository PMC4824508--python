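import itertools
import logging
import math

import numpy as np
import pytest

import phylobeta as pb
from phylobeta.cd_measure import _k_constants, edge_total_costs


def all_pair_costs(tree):
    """Brute-force path costs for every unordered tip pair."""
    tips = tree.tips
    return {
        (int(u), int(v)): tree.path_cost(int(u), int(v))
        for u, v in itertools.combinations(tips, 2)
    }


class TestTotalPathCost:
    @pytest.mark.parametrize(
        "newick, expected",
        [
            ("((x:1,y:1):1,z:1);", 8.0),  # pairwise costs 2 + 3 + 3
            ("(x:2,y:3);", 5.0),
            ("(a:1,b:1,c:1,d:1);", 12.0),  # star: 6 pairs of cost 2
        ],
    )
    def test_worked_examples(self, newick, expected):
        assert pb.total_path_cost(pb.parse_newick(newick)) == pytest.approx(expected)

    def test_equals_all_pairs_sum(self, suite):
        for label, tree in suite:
            brute = math.fsum(all_pair_costs(tree).values())
            assert pb.total_path_cost(tree) == pytest.approx(brute, rel=1e-12), label


class TestEdgeTotalCosts:
    def test_worked_examples(self, t3):
        stats = edge_total_costs(t3)
        cherry = int(t3.parent[t3.node_of("x")])
        assert stats.tc_edge[cherry] == pytest.approx(6.0)  # x-z and y-z, cost 3 each
        assert stats.tc_edge[t3.node_of("x")] == pytest.approx(5.0)
        assert stats.tc_tip[t3.node_of("x")] == pytest.approx(5.0)

    def test_structural_identities(self, suite):
        for label, tree in suite:
            stats = edge_total_costs(tree)
            costs = all_pair_costs(tree)
            # every tip-to-tip path is counted once from each endpoint
            assert stats.tc_tip.sum() == pytest.approx(
                2.0 * stats.tc_tree, rel=1e-12
            ), label
            # the weighted edge sum collapses to the sum of squared path costs
            sq = math.fsum(c * c for c in costs.values())
            got = float(np.dot(tree.weight, stats.tc_edge))
            assert got == pytest.approx(sq, rel=1e-12), label
            # TC(u) equals TC(e) of the tip's own edge
            for u in tree.tips:
                assert stats.tc_tip[u] == pytest.approx(
                    stats.tc_edge[u], rel=1e-12
                ), label

    def test_tc_edge_matches_path_enumeration(self, suite):
        for label, tree in suite:
            stats = edge_total_costs(tree)
            lo, hi = tree.tip_intervals
            pos = {int(u): int(lo[u]) for u in tree.tips}
            for e in tree.edges:
                brute = math.fsum(
                    c for (u, v), c in all_pair_costs(tree).items()
                    if (lo[e] <= pos[u] < hi[e]) != (lo[e] <= pos[v] < hi[e])
                )
                assert stats.tc_edge[e] == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_shared_endpoint_identity(self, suite):
        # sum over path pairs sharing exactly one endpoint of cost*cost equals
        # sum_u TC(u)^2 - 2 sum_e w_e TC(e)
        for label, tree in suite:
            stats = edge_total_costs(tree)
            costs = all_pair_costs(tree)
            brute = math.fsum(
                c1 * c2
                for (u1, v1), c1 in costs.items()
                for (u2, v2), c2 in costs.items()
                if len({u1, v1} & {u2, v2}) == 1
            )
            analytic = float(np.dot(stats.tc_tip, stats.tc_tip)) - 2.0 * float(
                np.dot(tree.weight, stats.tc_edge)
            )
            assert analytic == pytest.approx(brute, rel=1e-11, abs=1e-9), label


class TestCDValue:
    def test_worked_examples(self, t3):
        assert pb.cd_value(t3, {"x", "y"}, {"z"}) == pytest.approx(3.0)
        assert pb.cd_value(t3, {"x"}, {"x"}) == 0.0
        # the CD of a community with itself is generally nonzero
        assert pb.cd_value(t3, {"x", "y"}, {"x", "y"}) == pytest.approx(1.0)

    def test_symmetry(self, suite):
        for label, tree in suite:
            names = tree.tip_names
            a = set(names[: max(1, len(names) // 2)])
            b = set(names[-2:])
            assert pb.cd_value(tree, a, b) == pb.cd_value(tree, b, a), label


class TestCDMoments:
    def test_expectation_examples(self, t3, t2):
        assert pb.cd_expectation(t3, 2, 1) == pytest.approx(16 / 9)
        assert pb.cd_expectation(t2, 1, 1) == pytest.approx(2.5)

    def test_expectation_is_size_independent(self, t3):
        assert pb.cd_expectation(t3, 1, 1) == pb.cd_expectation(t3, 2, 2)

    def test_sd_examples(self, t3, t2):
        assert pb.cd_standard_deviation(t3, 2, 1) == pytest.approx(
            math.sqrt(36.5 / 81)
        )
        assert pb.cd_standard_deviation(t2, 1, 1) == pytest.approx(2.5)

    def test_sd_zero_when_samples_exhaust_tips(self, suite):
        for label, tree in suite:
            s = tree.n_tips
            assert pb.cd_standard_deviation(tree, s, s) == 0.0, label

    def test_size_validation(self, t3):
        with pytest.raises(ValueError):
            pb.cd_expectation(t3, 0, 1)
        with pytest.raises(ValueError):
            pb.cd_standard_deviation(t3, 2, 4)

    def test_k_constants_match_proof_normalization(self):
        # the theorem-statement constants are the proof's un-normalized ones
        # divided by (ab)^2
        for a, b, s in [(2, 3, 7), (1, 5, 9), (4, 4, 4), (2, 2, 30)]:
            k1, k2, k3 = _k_constants(a, b, s)
            s2 = s * s * (s - 1) * (s - 1)
            k1p = 4 * a * (a - 1) * b * (b - 1) / s2
            k2p = (
                2 * a * (a - 1) * b * (b - 1) / s2
                + a * (a - 1) * b / (s * s * (s - 1))
                + a * b * (b - 1) / (s * s * (s - 1))
            )
            k3p = 2 * a * (a - 1) * b * (b - 1) / s2 + 2 * a * b / (s * s)
            norm = (a * b) ** 2
            assert k1 == pytest.approx(k1p / norm, rel=1e-14)
            assert k2 == pytest.approx(k2p / norm, rel=1e-14)
            assert k3 == pytest.approx(k3p / norm, rel=1e-14)

    def test_float_path_agrees_with_exact_path(self):
        # trees above the exact-arithmetic cutoff use the float evaluation;
        # both routes must agree tightly where both run
        tree = pb.generate_tree(
            pb.TreeRecipe("yule", 60, branch_length="exponential", seed=5)
        )
        from phylobeta.cd_measure import _cd_variance_exact

        for a, b in [(2, 2), (10, 25), (60, 59)]:
            stats = edge_total_costs(tree)
            from phylobeta.cd_measure import _cd_variance

            var_float, _, _ = _cd_variance(tree, a, b, stats)
            var_exact = float(_cd_variance_exact(tree, a, b))
            assert var_float == pytest.approx(var_exact, rel=1e-9, abs=1e-12)


class TestNRIBeta:
    def test_worked_example(self, t3):
        assert pb.nri_beta(t3, {"x", "y"}, {"z"}) == pytest.approx(1.8207, abs=1e-3)

    def test_symmetry(self, t3):
        assert pb.nri_beta(t3, {"x", "y"}, {"z"}) == pb.nri_beta(
            t3, {"z"}, {"x", "y"}
        )

    def test_degenerate_sd_returns_nan_with_warning(self, t3, caplog):
        full = set(t3.tip_names)
        with caplog.at_level(logging.WARNING, logger="phylobeta.cd_measure"):
            value = pb.nri_beta(t3, full, full)
        assert math.isnan(value)
        assert "undefined" in caplog.text


class TestScalingCovariance:
    def test_branch_scaling(self, t3):
        scaled = pb.parse_newick("((x:2.5,y:2.5):2.5,z:2.5);")
        c = 2.5
        a, b = {"x", "y"}, {"z"}
        assert pb.cd_value(scaled, a, b) == pytest.approx(c * pb.cd_value(t3, a, b))
        assert pb.cd_expectation(scaled, 2, 1) == pytest.approx(
            c * pb.cd_expectation(t3, 2, 1), rel=1e-12
        )
        assert pb.cd_standard_deviation(scaled, 2, 1) == pytest.approx(
            c * pb.cd_standard_deviation(t3, 2, 1), rel=1e-9
        )
        assert pb.nri_beta(scaled, a, b) == pytest.approx(
            pb.nri_beta(t3, a, b), rel=1e-9
        )
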