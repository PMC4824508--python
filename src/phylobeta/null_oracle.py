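"""Brute-force and Monte-Carlo ground truth for the analytic moment formulas.

Everything here evaluates the measures by their *definitions* — explicit
path walks for the CD, explicit spanning-subtree construction for the CBL —
and averages over the null model by enumeration or simulation.  These
routines are deliberately slow and independent of the O(n) production code;
they exist so every closed-form moment can be checked against an oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .tree_core import PhyloTree

__all__ = [
    "OracleMoments",
    "direct_cd",
    "direct_cbl",
    "spanning_edges",
    "exhaustive_moments",
    "monte_carlo_moments",
    "uniform_subset",
]

_MC_CHUNK = 8192  # fixed so the random stream depends only on (reps, seed)


@dataclass(frozen=True)
class OracleMoments:
    """Null moments obtained by enumeration or simulation.

    The sd uses the population convention (divide by the number of pairs,
    not pairs - 1) because the analytic formulas are exact population
    moments over the finite outcome space.
    """

    measure: str
    a: int
    b: int
    mean: float
    sd: float
    n_pairs: int
    method: str  # "exhaustive" | "monte-carlo"
    seed: int | None = None


def direct_cd(tree: PhyloTree, sample_a, sample_b) -> float:
    """CD by its definition: mean over explicit pairwise path walks."""
    nodes_a = tree.resolve_sample(sample_a)
    nodes_b = tree.resolve_sample(sample_b)
    total = math.fsum(
        tree.path_cost(int(u), int(v)) for u in nodes_a for v in nodes_b
    )
    return total / (len(nodes_a) * len(nodes_b))


def spanning_edges(tree: PhyloTree, nodes: np.ndarray) -> frozenset:
    """Edges of the minimal subtree connecting the given tip nodes.

    Built explicitly: find the common ancestor of all the tips by pairwise
    climbing, then walk each tip up to it, collecting edges (each edge is
    identified by its child node).
    """
    depth = tree.depth
    parent = tree.parent

    def lca(u: int, v: int) -> int:
        while depth[u] > depth[v]:
            u = parent[u]
        while depth[v] > depth[u]:
            v = parent[v]
        while u != v:
            u = parent[u]
            v = parent[v]
        return u

    anc = int(nodes[0])
    for v in nodes[1:]:
        anc = lca(anc, int(v))

    edges: set[int] = set()
    for v in nodes:
        u = int(v)
        while u != anc and u not in edges:
            edges.add(u)
            u = parent[u]
    return frozenset(edges)


def direct_cbl(tree: PhyloTree, sample_a, sample_b) -> float:
    """CBL by its definition: total weight shared by the two spanning subtrees."""
    ea = spanning_edges(tree, tree.resolve_sample(sample_a))
    eb = spanning_edges(tree, tree.resolve_sample(sample_b))
    return float(math.fsum(tree.weight[e] for e in ea & eb))


def _tip_distance_matrix(tree: PhyloTree) -> np.ndarray:
    """All tip-pair path costs via explicit walks (oracle use only)."""
    tips = tree.tips
    s = tips.shape[0]
    d = np.zeros((s, s), dtype=np.float64)
    for i in range(s):
        for j in range(i + 1, s):
            c = tree.path_cost(int(tips[i]), int(tips[j]))
            d[i, j] = d[j, i] = c
    return d


def exhaustive_moments(tree: PhyloTree, a: int, b: int, measure: str,
                       cap: int = 1_000_000) -> OracleMoments:
    """Population mean and sd over *all* ordered sample pairs.

    Enumerates every (A, B) in Sub(S, a) x Sub(S, b) and evaluates the
    measure by its direct definition.  Sums are exactly rounded
    (``math.fsum``), so the result is independent of enumeration order.
    """
    s = tree.n_tips
    if not (1 <= a <= s and 1 <= b <= s):
        raise ValueError(f"sample sizes must satisfy 1 <= a, b <= {s}")
    n_pairs = math.comb(s, a) * math.comb(s, b)
    if n_pairs > cap:
        raise ValueError(
            f"{n_pairs} ordered sample pairs exceed the cap of {cap}; "
            "use monte_carlo_moments instead"
        )
    tips = tree.tips
    values: list[float] = []
    if measure == "cd":
        d = _tip_distance_matrix(tree)
        idx = range(s)
        for ai in itertools.combinations(idx, a):
            rows = d[np.array(ai)]
            for bi in itertools.combinations(idx, b):
                values.append(float(rows[:, np.array(bi)].mean()))
    elif measure == "cbl":
        subsets_a = [
            spanning_edges(tree, tips[np.array(c)]) if a > 1 else frozenset()
            for c in itertools.combinations(range(s), a)
        ]
        subsets_b = (
            subsets_a if b == a
            else [
                spanning_edges(tree, tips[np.array(c)]) if b > 1 else frozenset()
                for c in itertools.combinations(range(s), b)
            ]
        )
        for ea in subsets_a:
            for eb in subsets_b:
                values.append(
                    float(math.fsum(tree.weight[e] for e in ea & eb))
                )
    else:
        raise ValueError(f"unknown measure {measure!r}")

    mean = math.fsum(values) / n_pairs
    var = math.fsum((v - mean) ** 2 for v in values) / n_pairs
    return OracleMoments(
        measure=measure, a=a, b=b, mean=mean, sd=math.sqrt(max(var, 0.0)),
        n_pairs=n_pairs, method="exhaustive",
    )


def uniform_subset(rng: np.random.Generator, s: int, k: int) -> np.ndarray:
    """Uniform k-subset of {0..s-1} by partial Fisher–Yates.

    Swap positions i = 0..k-1 with a uniform position j in [i, s); the first
    k entries are the sample.  One swap per drawn element, so the consumed
    random stream is exactly k integers — documented so that draws are
    reproducible across versions of this package.
    """
    arr = np.arange(s)
    for i in range(k):
        j = int(rng.integers(i, s))
        arr[i], arr[j] = arr[j], arr[i]
    return arr[:k].copy()


def _batched_subsets(rng: np.random.Generator, s: int, k: int,
                     count: int) -> np.ndarray:
    """``count`` independent partial Fisher–Yates draws, vectorized."""
    arr = np.tile(np.arange(s), (count, 1))
    for i in range(k):
        j = rng.integers(i, s, size=count)
        col_j = np.take_along_axis(arr, j[:, None], axis=1)[:, 0]
        col_i = arr[:, i].copy()
        arr[:, i] = col_j
        np.put_along_axis(arr, j[:, None], col_i[:, None], axis=1)
    return arr[:, :k]


def _subtree_membership_matrix(tree: PhyloTree) -> np.ndarray:
    """Boolean (tip, node) matrix: tip i lies in the subtree of node v."""
    lo, hi = tree.tip_intervals
    pos = lo[tree.tips]  # DFS position of each tip
    return (lo[None, :] <= pos[:, None]) & (pos[:, None] < hi[None, :])


def monte_carlo_moments(tree: PhyloTree, a: int, b: int, measure: str,
                        reps: int, seed: int) -> OracleMoments:
    """Empirical null moments from ``reps`` independent uniform sample pairs.

    A and B are drawn independently (A first, then B, within fixed-size
    batches) with the partial Fisher–Yates scheme of :func:`uniform_subset`.
    Values are evaluated by the edge-decomposition formulas, vectorized
    across draws.  Population sd; fully reproducible for a fixed seed.
    """
    s = tree.n_tips
    if not (1 <= a <= s and 1 <= b <= s):
        raise ValueError(f"sample sizes must satisfy 1 <= a, b <= {s}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if measure not in ("cd", "cbl"):
        raise ValueError(f"unknown measure {measure!r}")

    rng = np.random.default_rng(seed)
    m = _subtree_membership_matrix(tree).astype(np.float64)
    w = tree.weight
    values = np.empty(reps, dtype=np.float64)
    done = 0
    while done < reps:
        count = min(_MC_CHUNK, reps - done)
        ia = _batched_subsets(rng, s, a, count)
        ib = _batched_subsets(rng, s, b, count)
        ind_a = np.zeros((count, s), dtype=np.float64)
        np.put_along_axis(ind_a, ia, 1.0, axis=1)
        ind_b = np.zeros((count, s), dtype=np.float64)
        np.put_along_axis(ind_b, ib, 1.0, axis=1)
        sa = ind_a @ m
        sb = ind_b @ m
        if measure == "cd":
            num = sa * (b - sb) + sb * (a - sa)
            values[done:done + count] = (num @ w) / (a * b)
        else:
            shared = (sa > 0) & (sa < a) & (sb > 0) & (sb < b)
            values[done:done + count] = shared @ w
        done += count

    mean = float(values.mean())
    sd = float(values.std())  # population convention
    return OracleMoments(
        measure=measure, a=a, b=b, mean=mean, sd=sd,
        n_pairs=reps, method="monte-carlo", seed=seed,
    )
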