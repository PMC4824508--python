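"""Site-by-species matrices, batch queries with moment caching, focal maps.

A community matrix is the standard ecological layout: rows are samples
(sites, grid cells), columns are taxa matching the tree's tip names, cells
are presence (1) or absence (0).  Batch queries compute raw values and
standardized indices for many row pairs while computing each distinct set of
null moments only once — the moments depend only on the tree and the sample
sizes (a, b), not on which tips are present, so a hundred equal-sized pairs
cost one moment evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cbl_measure, cd_measure
from .tree_core import PhyloTree, TipSample

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "QueryResult",
    "MomentCache",
    "read_community_matrix",
    "batch_query",
    "focal_map",
]


@dataclass(frozen=True)
class QueryResult:
    """One sample pair's value, null moments and standardized index."""

    pair: tuple
    measure: str
    a: int
    b: int
    value: float
    expectation: float | None = None
    sd: float | None = None
    index: float | None = None


class CommunityMatrix:
    """A validated 0/1 site-by-species matrix bound to a tree."""

    def __init__(self, data: pd.DataFrame, tree: PhyloTree):
        bad = ~data.isin([0, 1]).to_numpy()
        if bad.any():
            raise ValueError("community matrix cells must be 0 or 1")
        empty = data.sum(axis=1) == 0
        if empty.any():
            rows = list(data.index[empty])
            raise ValueError(f"rows with no present species: {rows}")
        unknown = [c for c in data.columns if c not in set(tree.tip_names)]
        if unknown:
            raise ValueError(f"columns are not tips of the tree: {unknown}")
        self.data = data.astype(np.int8)
        self.tree = tree

    @property
    def sample_names(self) -> list:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def row_sample(self, row) -> TipSample:
        """The :class:`TipSample` of one row, addressed by name."""
        if row not in self.data.index:
            raise KeyError(f"no sample named {row!r} in the matrix")
        vec = self.data.loc[row]
        return TipSample(vec.index[vec == 1])


def read_community_matrix(path, tree: PhyloTree, strict: bool = True,
                          nonzero_as_presence: bool = False) -> CommunityMatrix:
    """Read a delimited presence/absence matrix and bind it to a tree.

    The delimiter (comma or tab) is auto-detected from the header line; the
    first column holds sample names, the remaining column names must be tips
    of the tree.  With ``strict=False`` unknown columns are dropped with a
    logged warning instead of raising; with ``nonzero_as_presence`` any
    nonzero cell counts as presence (abundance tables are accepted but their
    abundances are discarded).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if nonzero_as_presence:
        df = (df != 0).astype(int)
    tip_set = set(tree.tip_names)
    unknown = [c for c in df.columns if c not in tip_set]
    if unknown and not strict:
        logger.warning("dropping %d non-tip columns: %s", len(unknown), unknown)
        df = df.drop(columns=unknown)
    return CommunityMatrix(df, tree)


class MomentCache:
    """Caches null moments per (measure, a, b) on one tree.

    ``n_computations`` counts actual moment evaluations, so tests can assert
    that a batch sharing one size pair computes its moments exactly once.
    The CD path-cost statistics are computed at most once per tree.
    """

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self._moments: dict = {}
        self._cd_stats = None
        self.n_computations = 0

    def _stats(self):
        if self._cd_stats is None:
            self._cd_stats = cd_measure.edge_total_costs(self.tree)
        return self._cd_stats

    def get(self, measure: str, a: int, b: int):
        key = (measure, min(a, b), max(a, b))  # moments are symmetric in (a, b)
        if key not in self._moments:
            self.n_computations += 1
            if measure == "cd":
                self._moments[key] = cd_measure.cd_moments(
                    self.tree, a, b, stats=self._stats()
                )
            elif measure == "cbl":
                self._moments[key] = cbl_measure.cbl_moments(self.tree, a, b)
            else:
                raise ValueError(f"unknown measure {measure!r}")
        return self._moments[key]


def _one_query(tree, matrix, cache, row_a, row_b, measure, standardized):
    sample_a = matrix.row_sample(row_a)
    sample_b = matrix.row_sample(row_b)
    a, b = len(sample_a), len(sample_b)
    if measure == "cd":
        value = cd_measure.cd_value(tree, sample_a, sample_b)
    else:
        value = cbl_measure.cbl_value(tree, sample_a, sample_b)
    if not standardized:
        return QueryResult(pair=(row_a, row_b), measure=measure,
                           a=a, b=b, value=value)
    mom = cache.get(measure, a, b)
    if mom.sd > 0.0:
        index = (value - mom.expectation) / mom.sd
    else:
        logger.warning(
            "null sd is zero for %s with sizes (%d, %d); index undefined",
            measure, a, b,
        )
        index = float("nan")
    return QueryResult(pair=(row_a, row_b), measure=measure, a=a, b=b,
                       value=value, expectation=mom.expectation,
                       sd=mom.sd, index=index)


def batch_query(tree: PhyloTree, matrix: CommunityMatrix, pairs,
                measure: str = "cd", standardized: bool = True,
                cache: MomentCache | None = None) -> list:
    """Compute (standardized) values for a list of row-name pairs.

    Output order matches input order; moments are cached per distinct
    (measure, a, b) in ``cache`` (a fresh one is created if not supplied).
    """
    if measure not in ("cd", "cbl"):
        raise ValueError(f"unknown measure {measure!r}")
    if cache is None:
        cache = MomentCache(tree)
    results = []
    for pair in pairs:
        row_a, row_b = pair
        results.append(
            _one_query(tree, matrix, cache, row_a, row_b, measure, standardized)
        )
    return results


def focal_map(tree: PhyloTree, matrix: CommunityMatrix, focal_row,
              measure: str = "cbl", standardized: bool = True,
              cache: MomentCache | None = None) -> list:
    """Similarity of one focal sample to every sample of the matrix.

    Equivalent to ``batch_query`` over (focal, j) for every row j, the
    self-pair included; the resulting table joins back to grid coordinates
    by sample name.
    """
    pairs = [(focal_row, other) for other in matrix.sample_names]
    return batch_query(tree, matrix, pairs, measure=measure,
                       standardized=standardized, cache=cache)


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate query results (one row per pair, stable column order)."""
    return pd.DataFrame(
        {
            "sample_a": [r.pair[0] for r in results],
            "sample_b": [r.pair[1] for r in results],
            "measure": [r.measure for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "value": [r.value for r in results],
            "expectation": [r.expectation for r in results],
            "sd": [r.sd for r in results],
            "index": [r.index for r in results],
        }
    )
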