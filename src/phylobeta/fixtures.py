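"""Synthetic trees and tip samples: the package tests itself with zero downloads.

Shapes
------
``star``
    One root, all tips at depth 1; minimal Sackin index.
``caterpillar``
    Fully pectinate tree; maximal Sackin index (O(n^2)), the worst case for
    quadratic-cost edge-pair computations.
``balanced``
    As close to a complete binary tree as the tip count allows;
    Sackin index O(n log n).
``yule``
    Pure-birth topology: starting from a two-tip cherry, a uniformly chosen
    extant lineage splits until the requested tip count is reached.  This
    reproduces the relatively balanced shape of real phylogenies.
``random-multifurcating``
    Random recursive partition with 2–4 children per internal node, so
    polytomies occur.

Branch lengths are either constant or i.i.d. exponential.  A recipe plus a
seed determines the tree exactly (same recipe, same Newick).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree_core import PhyloTree, TipSample
from .null_oracle import uniform_subset

__all__ = ["TreeRecipe", "generate_tree", "sample_random_tips", "small_tree_suite"]

SHAPES = ("yule", "caterpillar", "balanced", "star", "random-multifurcating")


@dataclass(frozen=True)
class TreeRecipe:
    """Deterministic description of a synthetic tree.

    Parameters
    ----------
    shape
        One of ``yule``, ``caterpillar``, ``balanced``, ``star``,
        ``random-multifurcating``.
    n_tips
        Number of tips, at least 2.
    branch_length
        ``"constant"`` (every edge gets ``constant_value``) or
        ``"exponential"`` (i.i.d. with the given ``rate``).
    """

    shape: str
    n_tips: int
    branch_length: str = "constant"
    constant_value: float = 1.0
    rate: float = 1.0
    seed: int = 0


class _Builder:
    """Accumulates parent/weight/name arrays for a tree under construction."""

    def __init__(self):
        self.parent: list[int] = [-1]
        self.names: list[str | None] = [None]

    def add(self, parent: int, name: str | None = None) -> int:
        self.parent.append(parent)
        self.names.append(name)
        return len(self.parent) - 1


def _topology(recipe: TreeRecipe, rng: np.random.Generator) -> _Builder:
    n = recipe.n_tips
    b = _Builder()
    tip_no = iter(range(1, n + 1))

    def tip(parent: int) -> int:
        return b.add(parent, f"t{next(tip_no)}")

    if recipe.shape == "star":
        for _ in range(n):
            tip(0)
    elif recipe.shape == "caterpillar":
        cur = 0
        for _ in range(n - 2):
            tip(cur)
            cur = b.add(cur)
        tip(cur)
        tip(cur)
    elif recipe.shape == "balanced":
        def split(parent: int, k: int) -> None:
            if k == 1:
                tip(parent)
                return
            node = b.add(parent)
            split(node, (k + 1) // 2)
            split(node, k // 2)

        split(0, (n + 1) // 2)
        split(0, n // 2)
    elif recipe.shape == "yule":
        leaves = [b.add(0), b.add(0)]
        while len(leaves) < n:
            i = int(rng.integers(len(leaves)))
            v = leaves.pop(i)
            leaves.append(b.add(v))
            leaves.append(b.add(v))
        for v in sorted(leaves):
            b.names[v] = f"t{next(tip_no)}"
    elif recipe.shape == "random-multifurcating":
        def compose(k: int, c: int) -> list:
            # random composition of k into c positive parts
            if c == k:
                return [1] * c
            cuts = np.sort(uniform_subset(rng, k - 1, c - 1)) + 1
            bounds = np.concatenate(([0], cuts, [k]))
            return [int(p) for p in np.diff(bounds)]

        def split(node: int, k: int) -> None:
            c = int(rng.integers(2, min(4, k) + 1))
            for p in compose(k, c):
                if p == 1:
                    tip(node)
                else:
                    split(b.add(node), p)

        split(0, n)
    else:
        raise ValueError(f"unknown shape {recipe.shape!r}; choose from {SHAPES}")
    return b


def generate_tree(recipe: TreeRecipe) -> PhyloTree:
    """Generate the tree described by a recipe, deterministically for its seed."""
    if recipe.n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(recipe.seed)
    b = _topology(recipe, rng)
    n_nodes = len(b.parent)
    if recipe.branch_length == "constant":
        weight = np.full(n_nodes, float(recipe.constant_value))
    elif recipe.branch_length == "exponential":
        if recipe.rate <= 0:
            raise ValueError("exponential rate must be positive")
        weight = rng.exponential(scale=1.0 / recipe.rate, size=n_nodes)
    else:
        raise ValueError(f"unknown branch-length law {recipe.branch_length!r}")
    weight[0] = 0.0
    return PhyloTree(b.parent, weight, b.names)


def sample_random_tips(tree: PhyloTree, k: int, seed: int) -> TipSample:
    """Uniform k-subset of the tree's tips, reproducible for a fixed seed."""
    s = tree.n_tips
    if not 1 <= k <= s:
        raise ValueError(f"need 1 <= k <= {s}; got k={k}")
    rng = np.random.default_rng(seed)
    names = tree.tip_names
    idx = uniform_subset(rng, s, k)
    return TipSample(names[i] for i in idx)


def small_tree_suite() -> list:
    """The (label, tree) fixtures used by every oracle-equivalence check.

    Every shape at every tip count 2..7 with unit branch lengths, plus one
    multifurcating tree and one tree with unequal (exponential) branch
    lengths.  All trees have at most 7 tips so exhaustive enumeration over
    all sample pairs stays cheap.
    """
    suite = []
    for shape in ("caterpillar", "balanced", "star", "yule"):
        for n in range(2, 8):
            recipe = TreeRecipe(shape=shape, n_tips=n, seed=n)
            suite.append((f"{shape}-{n}", generate_tree(recipe)))
    suite.append((
        "multifurcating-6",
        generate_tree(TreeRecipe(shape="random-multifurcating", n_tips=6, seed=3)),
    ))
    suite.append((
        "unequal-5",
        generate_tree(TreeRecipe(
            shape="caterpillar", n_tips=5, branch_length="exponential", seed=11,
        )),
    ))
    return suite
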