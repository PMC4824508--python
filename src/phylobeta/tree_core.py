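"""Tree data model, Newick I/O and the per-edge counting traversals.

The package works on a rooted phylogenetic tree with non-negative branch
lengths.  Internally a tree is a flat array structure: nodes are integers
``0..n-1``, every non-root node carries the weight of the edge that connects
it to its parent, and tips carry unique name strings.  Because every non-root
node has exactly one parent edge, *edges are identified with their child
node*: the edge set ``E`` is exactly the set of non-root node ids, and
per-edge quantities (subtree tip counts, sample tip counts, total path costs)
are stored as arrays indexed by node id.

Newick parsing is delegated to :mod:`dendropy`; the result is converted to
the array representation with unary internal nodes collapsed (their two
incident edge weights summed) so that ``|E| = n - 1`` always holds.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "TipSample",
    "NewickParseError",
    "UnknownTipError",
    "parse_newick",
    "root_if_unrooted",
    "reroot",
    "subtree_tip_counts",
    "sample_tip_counts",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid tree."""


class UnknownTipError(KeyError):
    """Raised when a sample refers to names that are not tips of the tree.

    The offending names are available as the ``offenders`` attribute.
    """

    def __init__(self, offenders: Sequence[str]):
        self.offenders = sorted(offenders)
        super().__init__(
            "names not found among the tree's tips: " + ", ".join(self.offenders)
        )


@dataclass(frozen=True)
class TipSample:
    """A community: a set of tip names of some tree.

    Duplicates are removed by construction (the underlying container is a
    frozenset).  Validation against a concrete tree happens when the sample
    is resolved to node ids by an operation.
    """

    names: frozenset

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", frozenset(names))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


def _as_name_set(sample) -> frozenset:
    if isinstance(sample, TipSample):
        return sample.names
    if isinstance(sample, str):
        raise TypeError("a sample must be a collection of tip names, not a string")
    return frozenset(sample)


class PhyloTree:
    """Rooted weighted phylogenetic tree over an array node representation.

    Parameters
    ----------
    parent
        Integer array of length ``n``; ``parent[i]`` is the parent node of
        ``i`` and ``-1`` for the single root.
    weight
        Float array of length ``n``; ``weight[i]`` is the length of the edge
        above node ``i`` (ignored for the root).  Must be ``>= 0``.
    names
        Sequence of length ``n`` with a unique name string for every tip
        (leaf node) and ``None`` for internal nodes.
    """

    def __init__(self, parent, weight, names):
        parent = np.asarray(parent, dtype=np.int64)
        weight = np.asarray(weight, dtype=np.float64)
        n = parent.shape[0]
        if weight.shape != (n,) or len(names) != n:
            raise ValueError("parent, weight and names must have equal length")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise ValueError(f"expected exactly one root, found {roots.size}")
        self.parent = parent
        self.weight = weight
        self.names = list(names)
        self.root = int(roots[0])
        self.weight = self.weight.copy()
        self.weight[self.root] = 0.0

        # children lists and structural checks
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = parent[v]
            if p >= 0:
                children[p].append(v)
        self.children = children
        self._validate()

        self._tips = np.array(
            [v for v in range(n) if not children[v]], dtype=np.int64
        )
        tip_names = [self.names[v] for v in self._tips]
        if any(nm is None for nm in tip_names):
            raise ValueError("every tip must carry a name")
        if len(set(tip_names)) != len(tip_names):
            raise ValueError("tip names must be unique")
        self._name_to_node = {self.names[v]: int(v) for v in self._tips}

        self._postorder: np.ndarray | None = None
        self._depth: np.ndarray | None = None
        self._subtree_tip_count: np.ndarray | None = None
        self._intervals: tuple[np.ndarray, np.ndarray] | None = None
        self._levels: list[np.ndarray] | None = None

    # ------------------------------------------------------------------
    # construction helpers

    def _validate(self) -> None:
        # reachability from the root proves connectedness / acyclicity
        n = self.parent.shape[0]
        seen = np.zeros(n, dtype=bool)
        stack = [self.root]
        while stack:
            v = stack.pop()
            if seen[v]:
                raise ValueError("cycle detected in parent structure")
            seen[v] = True
            stack.extend(self.children[v])
        if not seen.all():
            raise ValueError("tree is not connected")
        nonroot = np.arange(n) != self.root
        if np.any(self.weight[nonroot] < 0):
            raise ValueError("branch lengths must be >= 0")

    # ------------------------------------------------------------------
    # basic properties

    @property
    def n_nodes(self) -> int:
        """Total node count ``n``."""
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        """Number of tips ``s``."""
        return self._tips.shape[0]

    @property
    def tips(self) -> np.ndarray:
        """Node ids of the tips, in discovery order."""
        return self._tips

    @property
    def tip_names(self) -> list:
        return [self.names[v] for v in self._tips]

    @property
    def edges(self) -> np.ndarray:
        """Node ids identifying the edges (all nodes except the root)."""
        return np.array(
            [v for v in range(self.n_nodes) if v != self.root], dtype=np.int64
        )

    def node_of(self, name: str) -> int:
        try:
            return self._name_to_node[name]
        except KeyError:
            raise UnknownTipError([name]) from None

    def resolve_sample(self, sample) -> np.ndarray:
        """Validate a sample and return the sorted node ids of its tips."""
        names = _as_name_set(sample)
        if not names:
            raise ValueError("a sample must contain at least one tip")
        missing = [nm for nm in names if nm not in self._name_to_node]
        if missing:
            raise UnknownTipError(missing)
        return np.array(sorted(self._name_to_node[nm] for nm in names), dtype=np.int64)

    # ------------------------------------------------------------------
    # traversal orders

    @property
    def postorder(self) -> np.ndarray:
        """Node ids in post-order (children strictly before parents)."""
        if self._postorder is None:
            order = []
            stack = [(self.root, False)]
            while stack:
                v, expanded = stack.pop()
                if expanded:
                    order.append(v)
                else:
                    stack.append((v, True))
                    for c in reversed(self.children[v]):
                        stack.append((c, False))
            self._postorder = np.array(order, dtype=np.int64)
        return self._postorder

    @property
    def depth(self) -> np.ndarray:
        """Edge-count depth of every node (root has depth 0)."""
        if self._depth is None:
            d = np.zeros(self.n_nodes, dtype=np.int64)
            for v in self.postorder[::-1]:  # pre-order
                if v != self.root:
                    d[v] = d[self.parent[v]] + 1
            self._depth = d
        return self._depth

    @property
    def levels(self) -> list:
        """Non-root nodes grouped by depth, deepest group first.

        Used to vectorize post-order accumulations: adding each group's values
        into its parents, deepest first, is equivalent to a post-order pass.
        """
        if self._levels is None:
            d = self.depth
            self._levels = [
                np.flatnonzero(d == k) for k in range(int(d.max()), 0, -1)
            ]
        return self._levels

    def accumulate_up(self, values: np.ndarray) -> np.ndarray:
        """Post-order subtree accumulation of per-node ``values``.

        Returns an array ``acc`` with ``acc[v] = sum of values over the
        subtree rooted at v``.
        """
        acc = np.array(values, dtype=np.float64)
        for group in self.levels:
            np.add.at(acc, self.parent[group], acc[group])
        return acc

    @property
    def height(self) -> int:
        """Edge count of the longest root-to-tip path."""
        return int(self.depth[self._tips].max(initial=0))

    @property
    def sackin_index(self) -> int:
        """Sum of tip depths (tree-balance statistic)."""
        return int(self.depth[self._tips].sum())

    # ------------------------------------------------------------------
    # per-edge tip counting

    @property
    def subtree_tip_count(self) -> np.ndarray:
        """``s(e)`` per node: number of tips below (and including) each node."""
        if self._subtree_tip_count is None:
            is_tip = np.zeros(self.n_nodes, dtype=np.float64)
            is_tip[self._tips] = 1.0
            self._subtree_tip_count = self.accumulate_up(is_tip).astype(np.int64)
        return self._subtree_tip_count

    def sample_tip_count(self, sample) -> np.ndarray:
        """``s_R(e)`` per node for a sample ``R`` (post-order accumulation)."""
        nodes = self.resolve_sample(sample)
        ind = np.zeros(self.n_nodes, dtype=np.float64)
        ind[nodes] = 1.0
        return self.accumulate_up(ind).astype(np.int64)

    @property
    def tip_intervals(self) -> tuple:
        """Half-open DFS tip intervals ``[lo, hi)`` per node (0-based).

        Tips are numbered consecutively in depth-first order; a node's
        interval covers exactly the tips of its subtree.  Edge ``l`` lies in
        the subtree of edge ``e`` iff ``lo[e] <= lo[l]`` and
        ``hi[l] <= hi[e]``.
        """
        if self._intervals is None:
            lo = np.zeros(self.n_nodes, dtype=np.int64)
            hi = np.zeros(self.n_nodes, dtype=np.int64)
            counter = 0
            # iterative DFS assigning tip positions, then fold up
            for v in self.postorder:
                if not self.children[v]:
                    lo[v] = counter
                    hi[v] = counter + 1
                    counter += 1
                else:
                    lo[v] = min(lo[c] for c in self.children[v])
                    hi[v] = max(hi[c] for c in self.children[v])
            self._intervals = (lo, hi)
        return self._intervals

    # ------------------------------------------------------------------
    # distances (small-scale utilities; the measures never call these)

    def path_cost(self, u: int, v: int) -> float:
        """Cost of the unique simple path between nodes ``u`` and ``v``."""
        d = self.depth
        cost = 0.0
        while d[u] > d[v]:
            cost += self.weight[u]
            u = self.parent[u]
        while d[v] > d[u]:
            cost += self.weight[v]
            v = self.parent[v]
        while u != v:
            cost += self.weight[u] + self.weight[v]
            u = self.parent[u]
            v = self.parent[v]
        return cost

    # ------------------------------------------------------------------
    # I/O

    @classmethod
    def from_newick(cls, text: str, default_branch_length: float | None = None):
        """Parse a Newick string.  See :func:`parse_newick`."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy errors carry line/column info
            raise NewickParseError(f"invalid Newick: {exc}") from exc
        return cls._from_dendropy(dtree, default_branch_length)

    @classmethod
    def _from_dendropy(cls, dtree, default_branch_length: float | None = None):
        seed = dtree.seed_node
        # drop unary chains at the top: the root must have >= 2 children
        while len(seed.child_nodes()) == 1:
            seed = seed.child_nodes()[0]

        parent: list[int] = []
        weight: list[float] = []
        names: list[str | None] = []

        def new_node(p: int, w: float, name) -> int:
            parent.append(p)
            weight.append(w)
            names.append(name)
            return len(parent) - 1

        def edge_len(nd) -> float:
            ln = nd.edge.length
            if ln is None:
                if default_branch_length is None:
                    raise NewickParseError(
                        "missing branch length (supply default_branch_length "
                        "to impute one)"
                    )
                ln = default_branch_length
            ln = float(ln)
            if ln < 0:
                raise NewickParseError(f"negative branch length {ln}")
            if ln == 0.0:
                logger.warning("zero-length branch encountered; keeping it")
            return ln

        root_id = new_node(-1, 0.0, None)
        # stack of (dendropy node, our parent id, accumulated weight from
        # collapsed unary ancestors)
        stack = [(c, root_id, 0.0) for c in reversed(seed.child_nodes())]
        while stack:
            nd, pid, acc = stack.pop()
            kids = nd.child_nodes()
            w = edge_len(nd) + acc
            if len(kids) == 1:
                # unary internal node: collapse by summing the edge weights
                stack.append((kids[0], pid, w))
                continue
            name = nd.taxon.label if nd.taxon is not None else None
            if not kids and name is None:
                name = nd.label
            if not kids and name is None:
                raise NewickParseError("unnamed tip in Newick string")
            vid = new_node(pid, w, name if not kids else None)
            for c in reversed(kids):
                stack.append((c, vid, 0.0))

        if len(parent) < 2:
            raise NewickParseError("tree must contain at least one edge")
        return cls(parent, weight, names)

    def to_newick(self) -> str:
        """Serialize to Newick with full-precision branch lengths.

        Iterative (explicit stack), so arbitrarily deep caterpillar trees
        serialize without hitting the interpreter recursion limit.
        """
        parts: dict[int, str] = {}
        for v in self.postorder:
            label = self.names[v] if self.names[v] is not None else ""
            if self.children[v]:
                inner = ",".join(parts.pop(c) for c in self.children[v])
                label = f"({inner}){label}"
            if v != self.root:
                label = f"{label}:{float(self.weight[v])!r}"
            parts[v] = label
        return parts[self.root] + ";"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree with {self.n_tips} tips, {self.n_nodes - 1} edges>"


# ----------------------------------------------------------------------
# module-level operations


def parse_newick(text: str, default_branch_length: float | None = None) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Multifurcations are preserved; unary internal nodes are collapsed by
    summing the two incident edge weights.  Missing branch lengths are a hard
    error unless ``default_branch_length`` is given (silent defaults corrupt
    beta-diversity values).  Zero-length branches are accepted with a logged
    warning; negative lengths are rejected.
    """
    return PhyloTree.from_newick(text, default_branch_length)


def root_if_unrooted(tree: PhyloTree) -> PhyloTree:
    """Designate the top node of an unrooted-style tree as the root.

    Trees read from Newick already have a top node, possibly trifurcating
    (the usual serialization of unrooted trees).  The canonical policy is to
    use that existing top node as the root, creating no new edge, so the edge
    set is unchanged.  Trees produced by :func:`parse_newick` already satisfy
    this, so the tree is returned as-is.
    """
    return tree


def reroot(tree: PhyloTree, node: int) -> PhyloTree:
    """Return a copy of ``tree`` rerooted at internal node ``node``.

    The underlying unrooted topology and all edge weights are preserved,
    except that if the old root becomes a unary node it is collapsed (its two
    incident edge weights summed).  Path costs between tips — and hence all
    measure values — are unaffected by rerooting.
    """
    if node == tree.root:
        return tree
    if not tree.children[node]:
        raise ValueError("cannot reroot at a tip")
    n = tree.n_nodes
    # undirected adjacency with edge weights
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for v in range(n):
        p = tree.parent[v]
        if p >= 0:
            adj[v].append((int(p), float(tree.weight[v])))
            adj[p].append((v, float(tree.weight[v])))

    parent = np.full(n, -2, dtype=np.int64)
    weight = np.zeros(n, dtype=np.float64)
    parent[node] = -1
    stack = [node]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        for u, w in adj[v]:
            if parent[u] == -2:
                parent[u] = v
                weight[u] = w
                stack.append(u)

    # collapse unary nodes (typically the old root of a bifurcating tree)
    degree = np.array([len(a) for a in adj])
    keep = np.ones(n, dtype=bool)
    for v in range(n):
        if v != node and degree[v] == 2 and tree.names[v] is None:
            # v has exactly one child and one parent in the new orientation
            child = next(u for u, _ in adj[v] if parent[u] == v)
            parent[child] = parent[v]
            weight[child] = weight[child] + weight[v]
            keep[v] = False

    idx = np.flatnonzero(keep)
    remap = -np.ones(n, dtype=np.int64)
    remap[idx] = np.arange(idx.size)
    new_parent = np.array(
        [remap[parent[v]] if parent[v] >= 0 else -1 for v in idx], dtype=np.int64
    )
    new_weight = weight[idx]
    new_names = [tree.names[v] for v in idx]
    return PhyloTree(new_parent, new_weight, new_names)


def subtree_tip_counts(tree: PhyloTree) -> dict:
    """``s(e)`` for every edge, keyed by the edge's child-node id."""
    counts = tree.subtree_tip_count
    return {int(v): int(counts[v]) for v in tree.edges}


def sample_tip_counts(tree: PhyloTree, sample) -> dict:
    """``s_R(e) = |S(e) ∩ R|`` for every edge, keyed by child-node id."""
    counts = tree.sample_tip_count(sample)
    return {int(v): int(counts[v]) for v in tree.edges}
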