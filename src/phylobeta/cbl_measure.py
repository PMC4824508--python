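"""Common Branch Length (CBL): raw values, exact null moments and the CLI index.

The CBL between two tip samples A and B is the total weight of the edges
shared by their minimal spanning subtrees::

    CBL(T, A, B) = sum_{e in T(A) ∩ T(B)} w_e

An edge belongs to the spanning subtree T(R) of a sample R with r tips iff
the sample is split nontrivially by it: ``0 < s_R(e) < r``.  Unlike the CD,
the CBL is a similarity (larger = more shared evolutionary history).

Under the uniform two-sample null model the expectation factorizes per edge
into a product of presence probabilities, each a ratio of binomial
coefficients; the variance is a double sum over ordered edge pairs of
pairwise exclusion probabilities F(S, e, l, r) whose form depends on whether
the two subtrees are nested or disjoint.  The double sum is evaluated
directly (O(n^2), numpy-blocked); the Common Length Index standardizes the
raw value with these moments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .tree_core import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "CBLMoments",
    "PairExclusionTerm",
    "binomial_ratio",
    "cbl_value",
    "cbl_expectation",
    "pair_exclusion_F",
    "pair_presence_probability",
    "cbl_standard_deviation",
    "cbl_moments",
    "common_length_index",
]

_VARIANCE_CLAMP_RTOL = 1e-9

# below this tip count the variance double sum is evaluated in exact rational
# arithmetic, which keeps accidentally-zero variances exactly zero
_EXACT_VARIANCE_TIP_LIMIT = 30

# scalar binomial ratios fall back from exact integer arithmetic to
# log-gamma once the coefficients get genuinely huge
_EXACT_S_LIMIT = 10_000
_EXACT_R_LIMIT = 500


def binomial_ratio(x: int, s: int, r: int) -> float:
    """``C(x, r) / C(s, r)`` with the convention ``C(x, r) = 0`` for x < r.

    Exact integer arithmetic is used whenever the coefficients are of
    manageable size; otherwise the ratio is evaluated through log-factorial
    (gammaln) differences, accurate to ~1e-12 relative for s up to ~1e6.
    The result always lies in [0, 1] for x <= s.
    """
    if r < 0 or r > s:
        raise ValueError(f"need 0 <= r <= s; got r={r}, s={s}")
    if x < r:
        return 0.0
    if r == 0:
        return 1.0
    if s <= _EXACT_S_LIMIT or min(r, s - r) <= _EXACT_R_LIMIT:
        num = math.comb(x, r)
        den = math.comb(s, r)
        return num / den
    lg = (
        gammaln(x + 1) - gammaln(x - r + 1)
        - gammaln(s + 1) + gammaln(s - r + 1)
    )
    return float(np.exp(lg))


def _ratio_table(s: int, r: int) -> np.ndarray:
    """Vector ``c[k] = C(k, r) / C(s, r)`` for k = 0..s (0 where k < r).

    Built by the downward recurrence ``C(k, r)/C(k+1, r) = (k+1-r)/(k+1)``
    starting from ``c[s] = 1``: one rounded multiplication per entry, far
    more accurate than exponentiating log-gamma differences.
    """
    c = np.zeros(s + 1, dtype=np.float64)
    c[s] = 1.0
    if r <= s - 1:
        k = np.arange(s - 1, r - 1, -1, dtype=np.float64)
        c[s - 1:r - 1 if r > 0 else None:-1] = np.cumprod((k + 1 - r) / (k + 1))
    return c


def _table_lookup(c: np.ndarray, arg: np.ndarray, r: int) -> np.ndarray:
    """``c[arg]`` with out-of-range arguments (below r) mapped to 0."""
    clipped = np.clip(arg, 0, c.shape[0] - 1)
    return np.where(arg >= r, c[clipped], 0.0)


def cbl_value(tree: PhyloTree, sample_a, sample_b) -> float:
    """Raw CBL between two samples via the edge membership rule, in O(n)."""
    nodes_a = tree.resolve_sample(sample_a)
    nodes_b = tree.resolve_sample(sample_b)
    a, b = len(nodes_a), len(nodes_b)
    sa = tree.sample_tip_count(sample_a)
    sb = tree.sample_tip_count(sample_b)
    shared = (sa > 0) & (sa < a) & (sb > 0) & (sb < b)
    return float(tree.weight[shared].sum())


def _check_sizes(tree: PhyloTree, a: int, b: int) -> None:
    s = tree.n_tips
    if not (1 <= a <= s and 1 <= b <= s):
        raise ValueError(f"sample sizes must satisfy 1 <= a, b <= {s}; got ({a}, {b})")


def cbl_expectation(tree: PhyloTree, a: int, b: int) -> float:
    """Null expectation of the CBL, in O(n).

    Each edge contributes ``w_e * Pr[e in T(A)] * Pr[e in T(B)]`` where the
    presence probability for sample size r is
    ``1 - (C(s(e), r) + C(s - s(e), r)) / C(s, r)`` — the edge is absent
    exactly when the whole sample falls inside, or entirely outside, its
    subtree.
    """
    _check_sizes(tree, a, b)
    s = tree.n_tips
    if a == 1 or b == 1:
        return 0.0  # a singleton spans no edges, so the CBL is identically 0
    x = tree.subtree_tip_count
    ca = _ratio_table(s, a)
    cb = _ratio_table(s, b)
    pa = 1.0 - (_table_lookup(ca, x, a) + _table_lookup(ca, s - x, a))
    pb = 1.0 - (_table_lookup(cb, x, b) + _table_lookup(cb, s - x, b))
    return float(np.dot(tree.weight, pa * pb))


@dataclass(frozen=True)
class PairExclusionTerm:
    """Classified pairwise exclusion probability for one ordered edge pair."""

    edge: int
    other: int
    relation: str  # "l-inside-e" | "e-inside-l" | "disjoint"
    r: int
    value: float


def _edge_relation(tree: PhyloTree, e: int, l: int) -> str:
    lo, hi = tree.tip_intervals
    if lo[e] <= lo[l] and hi[l] <= hi[e]:
        return "l-inside-e"  # covers e == l as well
    if lo[l] <= lo[e] and hi[e] <= hi[l]:
        return "e-inside-l"
    return "disjoint"


def _check_edge(tree: PhyloTree, e: int) -> None:
    if not (0 <= e < tree.n_nodes) or e == tree.root:
        raise ValueError(f"node {e} does not identify an edge of this tree")


def pair_exclusion_F(tree: PhyloTree, e: int, l: int, r: int) -> PairExclusionTerm:
    """``F(S, e, l, r) = Pr[e not in T(A) or l not in T(A)]`` for |A| = r.

    The three-case closed form depends on the relation of the two subtrees
    (decided by half-open DFS tip intervals; ``e == l`` is routed to the
    nested case, where the expression collapses to the single-edge absence
    probability).  ``1 - F`` is the probability that both edges lie in the
    spanning subtree of a uniform r-sample.
    """
    _check_edge(tree, e)
    _check_edge(tree, l)
    s = tree.n_tips
    if not 1 <= r <= s:
        raise ValueError(f"need 1 <= r <= {s}; got r={r}")
    x = tree.subtree_tip_count
    se, sl = int(x[e]), int(x[l])
    relation = _edge_relation(tree, e, l)
    if relation == "l-inside-e":
        f = (
            binomial_ratio(se, s, r)
            + binomial_ratio(s - sl, s, r)
            - binomial_ratio(se - sl, s, r)
        )
    elif relation == "e-inside-l":
        f = (
            binomial_ratio(sl, s, r)
            + binomial_ratio(s - se, s, r)
            - binomial_ratio(sl - se, s, r)
        )
    else:
        f = (
            binomial_ratio(s - se, s, r)
            + binomial_ratio(s - sl, s, r)
            - binomial_ratio(s - se - sl, s, r)
        )
    return PairExclusionTerm(edge=e, other=l, relation=relation, r=r, value=f)


def pair_presence_probability(tree: PhyloTree, e: int, l: int, r: int,
                              route: str = "exclusion") -> float:
    """``Pr[e, l in T(A)]`` for a uniform r-sample A.

    ``route="exclusion"`` evaluates ``1 - F(S, e, l, r)``;
    ``route="inclusion"`` evaluates the equivalent inclusion–exclusion form
    ``1 - Pr[e out] - Pr[l out] + Pr[both out]`` term by term.  The two
    routes are algebraically identical and serve as a consistency check.
    """
    if route == "exclusion":
        return 1.0 - pair_exclusion_F(tree, e, l, r).value
    if route != "inclusion":
        raise ValueError(f"unknown route {route!r}")
    _check_edge(tree, e)
    _check_edge(tree, l)
    s = tree.n_tips
    x = tree.subtree_tip_count
    se, sl = int(x[e]), int(x[l])
    p_e_out = binomial_ratio(se, s, r) + binomial_ratio(s - se, s, r)
    p_l_out = binomial_ratio(sl, s, r) + binomial_ratio(s - sl, s, r)
    relation = _edge_relation(tree, e, l)
    if relation == "l-inside-e":
        p_both_out = (
            binomial_ratio(s - se, s, r)
            + binomial_ratio(sl, s, r)
            + binomial_ratio(se - sl, s, r)
        )
    elif relation == "e-inside-l":
        p_both_out = (
            binomial_ratio(s - sl, s, r)
            + binomial_ratio(se, s, r)
            + binomial_ratio(sl - se, s, r)
        )
    else:
        p_both_out = (
            binomial_ratio(se, s, r)
            + binomial_ratio(sl, s, r)
            + binomial_ratio(s - se - sl, s, r)
        )
    return 1.0 - p_e_out - p_l_out + p_both_out


def _pair_survival_block(tree, rows, x, s, c, r):
    """``1 - F(e, l, r)`` for every ordered pair (e in rows, l in all edges)."""
    lo, hi = tree.tip_intervals
    edges = np.flatnonzero(np.arange(tree.n_nodes) != tree.root)
    lo_e, hi_e = lo[rows][:, None], hi[rows][:, None]
    lo_l, hi_l = lo[edges][None, :], hi[edges][None, :]
    x_e = x[rows][:, None]
    x_l = x[edges][None, :]
    nested_le = (lo_e <= lo_l) & (hi_l <= hi_e)  # l inside e (incl. e == l)
    nested_el = (lo_l <= lo_e) & (hi_e <= hi_l) & ~nested_le

    f = (
        _table_lookup(c, s - x_e + np.zeros_like(x_l), r)
        + _table_lookup(c, s - x_l + np.zeros_like(x_e), r)
        - _table_lookup(c, s - x_e - x_l, r)
    )
    f_le = (
        _table_lookup(c, x_e + np.zeros_like(x_l), r)
        + _table_lookup(c, s - x_l + np.zeros_like(x_e), r)
        - _table_lookup(c, x_e - x_l, r)
    )
    f_el = (
        _table_lookup(c, x_l + np.zeros_like(x_e), r)
        + _table_lookup(c, s - x_e + np.zeros_like(x_l), r)
        - _table_lookup(c, x_l - x_e, r)
    )
    f = np.where(nested_le, f_le, np.where(nested_el, f_el, f))
    return 1.0 - f


def _cbl_variance_exact(tree: PhyloTree, a: int, b: int):
    """CBL variance over ordered edge pairs in exact rational arithmetic.

    Edge weights (floats, hence exact dyadic rationals) and all binomial
    ratios are handled as :class:`fractions.Fraction`, so cancellations —
    including variances that are exactly zero — are computed without
    rounding.  Quadratic in the edge count; reserved for small trees.
    """
    from fractions import Fraction

    s = tree.n_tips
    n = tree.n_nodes
    x = tree.subtree_tip_count
    lo, hi = tree.tip_intervals
    edges = [v for v in range(n) if v != tree.root]
    w = {v: Fraction(float(tree.weight[v])) for v in edges}
    den = {r: math.comb(s, r) for r in {a, b}}

    def ratio(k: int, r: int) -> "Fraction":
        if k < r:
            return Fraction(0)
        return Fraction(math.comb(k, r), den[r])

    def survival(e: int, l: int, r: int) -> "Fraction":
        se, sl = int(x[e]), int(x[l])
        if lo[e] <= lo[l] and hi[l] <= hi[e]:  # l inside e (incl. e == l)
            f = ratio(se, r) + ratio(s - sl, r) - ratio(se - sl, r)
        elif lo[l] <= lo[e] and hi[e] <= hi[l]:
            f = ratio(sl, r) + ratio(s - se, r) - ratio(sl - se, r)
        else:
            f = ratio(s - se, r) + ratio(s - sl, r) - ratio(s - se - sl, r)
        return 1 - f

    total = Fraction(0)
    expectation = Fraction(0)
    for e in edges:
        pa = survival(e, e, a)  # diagonal term is the single-edge presence prob
        pb = survival(e, e, b)
        expectation += w[e] * pa * pb
        for l in edges:
            ga = survival(e, l, a)
            gb = ga if b == a else survival(e, l, b)
            total += w[e] * w[l] * ga * gb
    return total - expectation * expectation


def cbl_standard_deviation(tree: PhyloTree, a: int, b: int,
                           mode: str = "direct-quadratic",
                           block_size: int | None = None) -> float:
    """Null standard deviation of the CBL for sample sizes (a, b).

    Evaluates ``sum_{e,l} w_e w_l (1 - F(S,e,l,a)) (1 - F(S,e,l,b))
    - E[CBL]**2`` over all ordered edge pairs, the diagonal included, and
    returns the square root.  The direct-quadratic mode is the reference
    contract: O(n^2) pair terms, processed in row blocks so memory stays
    O(block * n).  The same clamping policy as the CD applies to tiny
    negative variances.
    """
    _check_sizes(tree, a, b)
    if mode != "direct-quadratic":
        raise ValueError(
            f"unknown mode {mode!r}; only 'direct-quadratic' is available"
        )
    s = tree.n_tips
    if a == 1 or b == 1:
        return 0.0  # the CBL is identically 0 when either sample is a singleton
    if a == s and b == s:
        return 0.0  # single possible outcome: both spanning subtrees are fixed
    if s <= _EXACT_VARIANCE_TIP_LIMIT:
        var = _cbl_variance_exact(tree, a, b)
        if var < 0:
            raise ArithmeticError(
                f"exact CBL variance is negative ({var}): internal inconsistency"
            )
        return math.sqrt(float(var))
    n = tree.n_nodes
    x = tree.subtree_tip_count
    edges = np.flatnonzero(np.arange(n) != tree.root)
    w = tree.weight[edges]
    ca = _ratio_table(s, a)
    cb = _ratio_table(s, b)
    if block_size is None:
        block_size = max(1, 4_000_000 // max(1, edges.size))

    total = 0.0
    for start in range(0, edges.size, block_size):
        rows = edges[start:start + block_size]
        ga = _pair_survival_block(tree, rows, x, s, ca, a)
        gb = ga if b == a else _pair_survival_block(tree, rows, x, s, cb, b)
        total += float(tree.weight[rows] @ (ga * gb) @ w)

    ecbl = cbl_expectation(tree, a, b)
    var = total - ecbl * ecbl
    scale = max(1.0, total + ecbl * ecbl)
    if var < 0.0:
        if var < -_VARIANCE_CLAMP_RTOL * scale:
            raise ArithmeticError(
                f"CBL variance evaluated to {var}, far below zero: "
                "internal inconsistency"
            )
        var = 0.0
    return math.sqrt(var)


@dataclass(frozen=True)
class CBLMoments:
    """Exact null moments of the CBL on a fixed tree for sizes (a, b)."""

    a: int
    b: int
    expectation: float
    sd: float
    mode: str = "direct-quadratic"


def cbl_moments(tree: PhyloTree, a: int, b: int,
                mode: str = "direct-quadratic") -> CBLMoments:
    """Expectation and sd of the CBL under the uniform two-sample null."""
    return CBLMoments(
        a=a, b=b,
        expectation=cbl_expectation(tree, a, b),
        sd=cbl_standard_deviation(tree, a, b, mode=mode),
        mode=mode,
    )


def common_length_index(tree: PhyloTree, sample_a, sample_b) -> float:
    """Standardized CBL: ``(CBL - E[CBL]) / sd[CBL]``.

    Symmetric in its samples.  Returns NaN with a logged warning when the
    null sd is zero (e.g. both sizes 1, or both equal to the tip count).
    """
    a = len(tree.resolve_sample(sample_a))
    b = len(tree.resolve_sample(sample_b))
    value = cbl_value(tree, sample_a, sample_b)
    expectation = cbl_expectation(tree, a, b)
    sd = cbl_standard_deviation(tree, a, b)
    if sd == 0.0:
        logger.warning(
            "null sd of the CBL is zero for sizes (%d, %d); index undefined",
            a, b,
        )
        return float("nan")
    return (value - expectation) / sd
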