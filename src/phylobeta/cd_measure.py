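"""Community Distance (CD): raw values, exact null moments and NRI_beta.

The CD between two tip samples A (|A| = a) and B (|B| = b) is the mean cost
of the a*b paths connecting a tip of A with a tip of B::

    CD(T, A, B) = (1 / ab) * sum_{u in A} sum_{v in B} cost(u, v)

Under the uniform two-sample null model — A and B drawn independently and
uniformly from all a-subsets and b-subsets of the tips, overlap permitted —
the expectation and standard deviation of the CD have closed forms built
from three tree aggregates:

* ``TC(T)``  — total path cost, the sum of cost(u, v) over all tip pairs;
* ``TC(u)``  — per tip, the summed cost of all paths ending at u;
* ``sum_e w_e * TC(e)`` — which equals the sum of squared path costs.

The expectation is ``2 * TC(T) / s**2`` and is independent of the sample
sizes; the variance is a linear combination of ``TC(T)**2``,
``sum_u TC(u)**2`` and ``sum_e w_e TC(e)`` with coefficients k1, k2, k3 that
depend only on (a, b, s).  Everything here costs O(n) per tree.

NRI_beta standardizes the raw value: ``(CD - E[CD]) / sd[CD]``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .tree_core import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "PathCostStats",
    "CDMoments",
    "total_path_cost",
    "edge_total_costs",
    "cd_value",
    "cd_expectation",
    "cd_standard_deviation",
    "cd_moments",
    "nri_beta",
]

# relative slack below which a tiny negative variance is treated as
# floating-point cancellation and clamped to zero
_VARIANCE_CLAMP_RTOL = 1e-9

# below this tip count the variance is evaluated in exact rational
# arithmetic, so accidentally-zero variances come out exactly zero
_EXACT_VARIANCE_TIP_LIMIT = 30


@dataclass(frozen=True)
class PathCostStats:
    """Per-edge and per-tip total path costs of a tree.

    Attributes
    ----------
    tc_tree
        ``TC(T)``: the sum of the costs of all tip-to-tip paths.
    tc_edge
        Array over nodes; entry ``v`` is ``TC(e)`` for the edge above node
        ``v`` (the summed cost of all tip-to-tip paths that traverse that
        edge).  The root entry is 0.
    tc_tip
        Array over nodes; for a tip ``u`` the entry is ``TC(u)``, the summed
        cost of all paths ending at ``u`` (equal to ``tc_edge`` of the tip's
        edge).  Internal entries are 0.
    wt_edge
        Auxiliary accumulator ``wT(e) = sum_{l in T(e)} s(l) * w_l`` over the
        edges of the subtree hanging from each edge, the edge itself
        included.
    """

    tc_tree: float
    tc_edge: np.ndarray
    tc_tip: np.ndarray
    wt_edge: np.ndarray


def total_path_cost(tree: PhyloTree) -> float:
    """``TC(T) = sum_e w_e * s(e) * (s - s(e))`` (edge-decomposed form).

    Each edge is crossed by exactly ``s(e) * (s - s(e))`` tip-to-tip paths,
    so this equals the direct sum of all pairwise path costs.
    """
    s = tree.n_tips
    x = tree.subtree_tip_count.astype(np.float64)
    return float(np.dot(tree.weight, x * (s - x)))


def edge_total_costs(tree: PhyloTree) -> PathCostStats:
    """Compute ``TC(e)`` for every edge and ``TC(u)`` for every tip in O(n).

    Two sweeps: a post-order pass accumulates, for every node ``v``, the
    summed distance ``down(v)`` from ``v`` to the tips below it; a pre-order
    pass turns these into ``sumd(v)``, the summed distance from ``v`` to
    *all* tips.  Then for the edge ``e`` above node ``c`` with parent ``p``::

        TC(e) = (s - s(e)) * down(c) + s(e) * out(p) + s(e)(s - s(e)) * w_e

    where ``out(p) = sumd(p) - down(c) - s(e) * w_e`` is the summed distance
    from ``p`` to the tips outside the subtree of ``e``.
    """
    s = tree.n_tips
    n = tree.n_nodes
    x = tree.subtree_tip_count.astype(np.float64)
    w = tree.weight

    # post-order: down(v) = sum over children c of down(c) + s(c) * w_c
    down = np.zeros(n, dtype=np.float64)
    for group in tree.levels:  # deepest first
        np.add.at(down, tree.parent[group], down[group] + x[group] * w[group])

    # pre-order: sumd(c) = sumd(p) + w_c * (s - 2 s(c))
    sumd = np.zeros(n, dtype=np.float64)
    sumd[tree.root] = down[tree.root]
    step = w * (s - 2.0 * x)
    for group in reversed(tree.levels):  # shallowest first
        sumd[group] = sumd[tree.parent[group]] + step[group]

    tc_edge = np.zeros(n, dtype=np.float64)
    nonroot = np.arange(n) != tree.root
    p = tree.parent
    out = sumd[p[nonroot]] - down[nonroot] - x[nonroot] * w[nonroot]
    tc_edge[nonroot] = (
        (s - x[nonroot]) * down[nonroot]
        + x[nonroot] * out
        + x[nonroot] * (s - x[nonroot]) * w[nonroot]
    )

    tc_tip = np.zeros(n, dtype=np.float64)
    tc_tip[tree.tips] = sumd[tree.tips]

    wt_edge = tree.accumulate_up(x * w)
    return PathCostStats(
        tc_tree=total_path_cost(tree),
        tc_edge=tc_edge,
        tc_tip=tc_tip,
        wt_edge=wt_edge,
    )


def cd_value(tree: PhyloTree, sample_a, sample_b) -> float:
    """Raw CD between two samples via the edge decomposition, in O(n).

    The number of A-to-B paths crossing an edge ``e`` is
    ``Num(A, B, e) = s_A(e) * (b - s_B(e)) + s_B(e) * (a - s_A(e))``, so the
    CD is ``(1/ab) * sum_e w_e * Num(A, B, e)``.  Samples may overlap or be
    equal — note the CD of a community with itself is generally nonzero.
    """
    nodes_a = tree.resolve_sample(sample_a)
    nodes_b = tree.resolve_sample(sample_b)
    a, b = len(nodes_a), len(nodes_b)
    sa = tree.sample_tip_count(sample_a).astype(np.float64)
    sb = tree.sample_tip_count(sample_b).astype(np.float64)
    num = sa * (b - sb) + sb * (a - sa)
    return float(np.dot(tree.weight, num)) / (a * b)


def _check_sizes(tree: PhyloTree, a: int, b: int) -> None:
    s = tree.n_tips
    if not (1 <= a <= s and 1 <= b <= s):
        raise ValueError(f"sample sizes must satisfy 1 <= a, b <= {s}; got ({a}, {b})")


def cd_expectation(tree: PhyloTree, a: int, b: int) -> float:
    """Null expectation of the CD: ``2 * TC(T) / s**2``.

    Remarkably the expectation does not depend on the sample sizes; they are
    accepted (and validated) for interface symmetry with the sd.
    """
    _check_sizes(tree, a, b)
    s = tree.n_tips
    return 2.0 * total_path_cost(tree) / (s * s)


def _k_constants(a: int, b: int, s: int) -> tuple:
    """The (a, b, s)-dependent coefficients of the CD variance."""
    sm1 = float(s - 1)
    s2 = float(s) * s
    k1 = 4.0 * (a - 1) * (b - 1) / (a * b * s2 * sm1 * sm1)
    k2 = (
        2.0 * (a - 1) * (b - 1) / (a * b * s2 * sm1 * sm1)
        + (b - 1) / (a * b * s2 * sm1)
        + (a - 1) / (a * b * s2 * sm1)
    )
    k3 = 2.0 * (a - 1) * (b - 1) / (a * b * s2 * sm1 * sm1) + 2.0 / (a * b * s2)
    return k1, k2, k3


def _cd_variance(tree: PhyloTree, a: int, b: int, stats: PathCostStats) -> tuple:
    s = tree.n_tips
    k1, k2, k3 = _k_constants(a, b, s)
    tc = stats.tc_tree
    sum_tc_tip_sq = float(np.dot(stats.tc_tip, stats.tc_tip))
    sum_w_tc_edge = float(np.dot(tree.weight, stats.tc_edge))
    ecd = 2.0 * tc / (s * s)
    var = (
        k1 * tc * tc
        + (k2 - k1) * sum_tc_tip_sq
        + (k1 - 2.0 * k2 + k3) * sum_w_tc_edge
        - ecd * ecd
    )
    scale = max(1.0, abs(k1) * tc * tc + abs(k2) * sum_tc_tip_sq
                + abs(k3) * sum_w_tc_edge + ecd * ecd)
    return var, scale, (k1, k2, k3)


def _cd_variance_exact(tree: PhyloTree, a: int, b: int):
    """CD variance in exact rational arithmetic (small trees only).

    Branch lengths are floats, hence exact dyadic rationals; the whole
    two-sweep path-cost computation and the k-coefficients are carried as
    :class:`fractions.Fraction`, eliminating cancellation error entirely.
    """
    from fractions import Fraction

    s = tree.n_tips
    n = tree.n_nodes
    x = tree.subtree_tip_count
    w = [Fraction(float(tree.weight[v])) for v in range(n)]
    parent = tree.parent

    down = [Fraction(0)] * n
    for v in tree.postorder:
        for c in tree.children[v]:
            down[v] += down[c] + int(x[c]) * w[c]
    sumd = [Fraction(0)] * n
    sumd[tree.root] = down[tree.root]
    for v in tree.postorder[::-1]:
        if v != tree.root:
            sumd[v] = sumd[parent[v]] + w[v] * (s - 2 * int(x[v]))

    tc = Fraction(0)
    sum_w_tc_edge = Fraction(0)
    for v in range(n):
        if v == tree.root:
            continue
        xv = int(x[v])
        tc += w[v] * xv * (s - xv)
        out = sumd[parent[v]] - down[v] - xv * w[v]
        tc_edge = (s - xv) * down[v] + xv * out + xv * (s - xv) * w[v]
        sum_w_tc_edge += w[v] * tc_edge
    sum_tc_tip_sq = sum(sumd[int(u)] ** 2 for u in tree.tips)

    sm1 = s - 1
    k1 = Fraction(4 * (a - 1) * (b - 1), a * b * s * s * sm1 * sm1)
    k2 = (
        Fraction(2 * (a - 1) * (b - 1), a * b * s * s * sm1 * sm1)
        + Fraction(b - 1, a * b * s * s * sm1)
        + Fraction(a - 1, a * b * s * s * sm1)
    )
    k3 = Fraction(2 * (a - 1) * (b - 1), a * b * s * s * sm1 * sm1) + Fraction(
        2, a * b * s * s
    )
    ecd = 2 * tc / (s * s)
    return (
        k1 * tc * tc
        + (k2 - k1) * sum_tc_tip_sq
        + (k1 - 2 * k2 + k3) * sum_w_tc_edge
        - ecd * ecd
    )


def cd_standard_deviation(tree: PhyloTree, a: int, b: int,
                          stats: PathCostStats | None = None) -> float:
    """Null standard deviation of the CD for sample sizes (a, b), in O(n).

    Evaluates the exact variance
    ``k1*TC(T)**2 + (k2-k1)*sum_u TC(u)**2 + (k1-2k2+k3)*sum_e w_e TC(e)
    - E[CD]**2`` and returns its square root.  Tiny negative values from
    floating-point cancellation are clamped to zero; larger negatives signal
    an internal inconsistency and raise.
    """
    _check_sizes(tree, a, b)
    if tree.n_tips < 2:
        raise ValueError("standard deviation requires a tree with at least 2 tips")
    if a == tree.n_tips and b == tree.n_tips:
        return 0.0  # single possible outcome
    if tree.n_tips <= _EXACT_VARIANCE_TIP_LIMIT:
        var = _cd_variance_exact(tree, a, b)
        if var < 0:
            raise ArithmeticError(
                f"exact CD variance is negative ({var}): internal inconsistency"
            )
        return math.sqrt(float(var))
    if stats is None:
        stats = edge_total_costs(tree)
    var, scale, _ = _cd_variance(tree, a, b, stats)
    if var < 0.0:
        if var < -_VARIANCE_CLAMP_RTOL * scale:
            raise ArithmeticError(
                f"CD variance evaluated to {var}, far below zero: "
                "internal inconsistency"
            )
        var = 0.0
    return math.sqrt(var)


@dataclass(frozen=True)
class CDMoments:
    """Exact null moments of the CD on a fixed tree for sizes (a, b)."""

    a: int
    b: int
    expectation: float
    sd: float
    k1: float
    k2: float
    k3: float


def cd_moments(tree: PhyloTree, a: int, b: int,
               stats: PathCostStats | None = None) -> CDMoments:
    """Expectation and sd of the CD under the uniform two-sample null."""
    _check_sizes(tree, a, b)
    k1, k2, k3 = _k_constants(a, b, tree.n_tips)
    return CDMoments(
        a=a, b=b,
        expectation=cd_expectation(tree, a, b),
        sd=cd_standard_deviation(tree, a, b, stats=stats),
        k1=k1, k2=k2, k3=k3,
    )


def nri_beta(tree: PhyloTree, sample_a, sample_b) -> float:
    """Standardized CD: ``(CD - E[CD]) / sd[CD]`` for the samples' sizes.

    Symmetric in its two samples.  When the null sd is zero (e.g. both
    samples comprise the full tip set) the index is undefined: a warning is
    logged and NaN is returned, never a silent zero.
    """
    a = len(tree.resolve_sample(sample_a))
    b = len(tree.resolve_sample(sample_b))
    value = cd_value(tree, sample_a, sample_b)
    expectation = cd_expectation(tree, a, b)
    sd = cd_standard_deviation(tree, a, b)
    if sd == 0.0:
        logger.warning(
            "null sd of the CD is zero for sizes (%d, %d); NRI_beta undefined",
            a, b,
        )
        return float("nan")
    return (value - expectation) / sd
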