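"""Spatial neighbour weights: queen contiguity from polygons and k-nearest
neighbours from centroids, with optional row standardization.

A :class:`SpatialWeights` stores, for each unit, the indices of its
neighbours and a nonnegative weight per pair. Queen weights are symmetric by
construction; kNN weights are directed and symmetry is deliberately not
enforced (matching common spatial-econometrics practice — the likelihood-based
lag model below is only ever fitted with queen weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse
from shapely.strtree import STRtree


class WeightsError(ValueError):
    pass


@dataclass(frozen=True)
class SpatialWeights:
    ids: tuple
    neighbors: tuple  # tuple of int tuples, one per unit
    values: tuple  # tuple of float tuples, aligned with neighbors
    scheme: str  # "queen" | "knn" | "custom"
    style: str = "binary"  # "binary" | "row_standardized"
    k: int | None = None

    def __post_init__(self):
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise WeightsError("duplicate tract ids in weights")
        if len(self.neighbors) != n or len(self.values) != n:
            raise WeightsError("neighbors/values not aligned with ids")
        for i, (nb, vals) in enumerate(zip(self.neighbors, self.values)):
            if i in nb:
                raise WeightsError(f"self-neighbor at unit {self.ids[i]}")
            if len(nb) != len(vals):
                raise WeightsError("ragged neighbor/value rows")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(sum(sum(v) for v in self.values))

    def sparse(self) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for i, (nb, vals) in enumerate(zip(self.neighbors, self.values)):
            rows.extend([i] * len(nb))
            cols.extend(nb)
            data.extend(vals)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def dense(self) -> np.ndarray:
        return self.sparse().toarray()

    def row_standardize(self) -> "SpatialWeights":
        """Scale each nonempty row to sum to one. Empty rows (islands) are
        left empty; the operation is idempotent."""
        new_vals = []
        for vals in self.values:
            s = sum(vals)
            new_vals.append(tuple(v / s for v in vals) if s > 0 else tuple(vals))
        return replace(self, values=tuple(new_vals), style="row_standardized")

    def subset(self, keep: np.ndarray) -> "SpatialWeights":
        """Restrict to the units selected by boolean mask ``keep``,
        dropping edges to removed units. Row-standardized weights are
        re-standardized over the surviving neighbours."""
        keep = np.asarray(keep, dtype=bool)
        old_idx = np.flatnonzero(keep)
        remap = {o: i for i, o in enumerate(old_idx)}
        ids = tuple(self.ids[o] for o in old_idx)
        neighbors, values = [], []
        for o in old_idx:
            nb, vals = [], []
            for j, v in zip(self.neighbors[o], self.values[o]):
                if keep[j]:
                    nb.append(remap[j])
                    vals.append(v)
            neighbors.append(tuple(nb))
            values.append(tuple(vals))
        out = SpatialWeights(
            ids=ids,
            neighbors=tuple(neighbors),
            values=tuple(values),
            scheme=self.scheme,
            style="binary",
            k=self.k,
        )
        return out.row_standardize() if self.style == "row_standardized" else out

    def to_triplets(self):
        """(i_id, j_id, w) triplet rows, for CSV export."""
        rows = []
        for i, (nb, vals) in enumerate(zip(self.neighbors, self.values)):
            for j, v in zip(nb, vals):
                rows.append((self.ids[i], self.ids[j], v))
        return rows


def queen_weights(ids: Sequence, polygons: Sequence) -> SpatialWeights:
    """Queen-contiguity weights: units sharing at least one boundary point
    (including a single corner) are neighbours with weight 1.

    Islands (units with no neighbours) are allowed and produce a warning.
    """
    ids = tuple(ids)
    if len(set(ids)) != len(ids):
        raise WeightsError("duplicate tract ids")
    geoms = list(polygons)
    tree = STRtree(geoms)
    neighbors = []
    for i, g in enumerate(geoms):
        cand = tree.query(g, predicate="intersects")
        nb = sorted(int(j) for j in cand if j != i and not geoms[int(j)].disjoint(g))
        # 'intersects' on a tiling returns touching polygons; exclude any
        # degenerate duplicate geometry overlap silently (still a neighbour).
        neighbors.append(tuple(nb))
    n_islands = sum(1 for nb in neighbors if not nb)
    if n_islands:
        warnings.warn(f"{n_islands} island unit(s) with no queen neighbours")
    values = tuple(tuple(1.0 for _ in nb) for nb in neighbors)
    return SpatialWeights(ids, tuple(neighbors), values, scheme="queen")


def knn_weights(ids: Sequence, points: Sequence, k: int) -> SpatialWeights:
    """Directed k-nearest-neighbour weights from unit centroids.

    Distance ties are broken in favour of the smaller tract id. Symmetry is
    not enforced.
    """
    ids = tuple(ids)
    n = len(ids)
    if k >= n:
        raise WeightsError(f"k={k} must be smaller than the number of units ({n})")
    if k < 1:
        raise WeightsError("k must be >= 1")
    xy = np.array([[p.x, p.y] for p in points], dtype=float)
    # rank of each id in lexicographic order, used as the tie-break key
    id_order = np.empty(n, dtype=int)
    id_order[np.argsort(np.asarray(ids, dtype=object))] = np.arange(n)
    neighbors = []
    for i in range(n):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        d[i] = np.inf
        order = sorted(range(n), key=lambda j: (d[j], id_order[j]))
        neighbors.append(tuple(order[:k]))
    values = tuple(tuple(1.0 for _ in nb) for nb in neighbors)
    return SpatialWeights(ids, tuple(neighbors), values, scheme="knn", k=k)
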