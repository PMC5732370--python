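"""Connection networks and spatial weight matrices.

The spatial information enters the analysis as an n x n weight matrix L
whose i-th row holds the proximities of every unit to unit i.  Networks are
built from planar coordinates (k-nearest-neighbour or distance-band graphs)
or supplied directly as an adjacency matrix, and are row-standardised by
default so each non-isolated row sums to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .genodata import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateSet",
    "SpatialWeights",
    "read_coordinates",
    "knn_graph",
    "distance_graph",
    "weights_from_adjacency",
    "jitter_duplicates",
]


@dataclass
class CoordinateSet:
    """Planar coordinates per analysis unit (arbitrary units)."""

    unit_ids: list[str]
    xy: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("coordinates must be an (n, 2) array")
        if len(self.unit_ids) != self.xy.shape[0]:
            raise ValidationError("unit_ids do not match coordinate rows")
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n(self) -> int:
        return self.xy.shape[0]


@dataclass
class SpatialWeights:
    """Non-negative weight matrix with zero diagonal.

    ``style`` is ``"row_standardised"`` (every row sums to 1) or
    ``"binary"``; ``graph_spec`` records how the network was built.
    """

    L: np.ndarray
    style: str = "row_standardised"
    graph_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        n = self.L.shape[0]
        if self.L.ndim != 2 or self.L.shape[1] != n:
            raise ValidationError("weight matrix must be square")
        if np.any(self.L < 0):
            raise ValidationError("weights must be non-negative")
        # a nonzero diagonal (e.g. identity weights, the non-spatial limit in
        # which sPCA collapses to ordinary PCA) is admissible for binary style
        if self.style != "binary" and np.any(np.diag(self.L) != 0):
            raise ValidationError("weight matrix diagonal must be zero")
        rowsums = self.L.sum(axis=1)
        if np.any(rowsums == 0):
            isolated = [str(i) for i in np.where(rowsums == 0)[0][:5]]
            raise ValidationError(f"isolated unit(s) in connection network: {isolated}")
        if self.style == "row_standardised":
            if np.max(np.abs(rowsums - 1.0)) > 1e-12:
                raise ValidationError("row-standardised rows must sum to 1")
        elif self.style != "binary":
            raise ValidationError(f"unknown weight style: {self.style!r}")

    @property
    def n(self) -> int:
        return self.L.shape[0]


def read_coordinates(path) -> CoordinateSet:
    """Read a "unit,x,y" coordinates CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: expected columns unit,x,y")
    return CoordinateSet(
        unit_ids=[str(u) for u in df.iloc[:, 0]],
        xy=df.iloc[:, 1:3].to_numpy(dtype=float),
    )


def _row_standardise(A: np.ndarray) -> np.ndarray:
    rowsums = A.sum(axis=1, keepdims=True)
    if np.any(rowsums == 0):
        isolated = [str(i) for i in np.where(rowsums[:, 0] == 0)[0][:5]]
        raise ValidationError(f"isolated unit(s) in connection network: {isolated}")
    return A / rowsums


def knn_graph(c: CoordinateSet, k: int) -> SpatialWeights:
    """Union-symmetrised k-nearest-neighbour graph, row-standardised.

    Distance ties are broken towards the smaller unit index so the graph is
    deterministic.
    """
    n = c.n
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    d = cdist(c.xy, c.xy)
    np.fill_diagonal(d, np.inf)
    A = np.zeros((n, n))
    for i in range(n):
        # stable sort on (distance, index): ties go to the smaller index
        order = np.lexsort((np.arange(n), d[i]))
        A[i, order[:k]] = 1.0
    A = np.maximum(A, A.T)  # union symmetrisation
    return SpatialWeights(
        L=_row_standardise(A),
        style="row_standardised",
        graph_spec={"method": "knn", "k": k},
    )


def distance_graph(c: CoordinateSet, d_min: float, d_max: float) -> SpatialWeights:
    """Distance-band graph: edge iff d_min < distance <= d_max."""
    if not 0 <= d_min < d_max:
        raise ValidationError("require 0 <= d_min < d_max")
    d = cdist(c.xy, c.xy)
    A = ((d > d_min) & (d <= d_max)).astype(float)
    np.fill_diagonal(A, 0.0)
    if np.any(A.sum(axis=1) == 0):
        bad = [c.unit_ids[i] for i in np.where(A.sum(axis=1) == 0)[0][:5]]
        raise ValidationError(
            f"isolated unit(s) {bad} within distance band ({d_min}, {d_max}]; "
            "consider raising d_max"
        )
    return SpatialWeights(
        L=_row_standardise(A),
        style="row_standardised",
        graph_spec={"method": "distance_band", "d_min": d_min, "d_max": d_max},
    )


def weights_from_adjacency(
    A: np.ndarray,
    standardise: bool = True,
    symmetrise: bool = False,
) -> SpatialWeights:
    """Spatial weights from a user-supplied non-negative adjacency matrix."""
    A = np.array(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency matrix must be square")
    if np.any(A < 0):
        raise ValidationError("adjacency entries must be non-negative")
    if np.any(np.diag(A) != 0):
        logger.warning("adjacency diagonal forced to zero")
        np.fill_diagonal(A, 0.0)
    if symmetrise:
        A = np.maximum(A, A.T)
    spec = {"method": "adjacency", "symmetrised": symmetrise}
    if standardise:
        return SpatialWeights(L=_row_standardise(A), style="row_standardised", graph_spec=spec)
    if np.any(A.sum(axis=1) == 0):
        raise ValidationError("adjacency contains isolated unit(s)")
    return SpatialWeights(L=A, style="binary", graph_spec=spec)


def jitter_duplicates(
    c: CoordinateSet, magnitude: float, rng: np.random.Generator | None = None
) -> CoordinateSet:
    """Displace duplicated coordinates by uniform noise in [-magnitude, magnitude]^2."""
    if magnitude <= 0:
        raise ValidationError("jitter magnitude must be positive")
    rng = np.random.default_rng() if rng is None else rng
    xy = c.xy.copy()
    _, inverse, counts = np.unique(xy, axis=0, return_inverse=True, return_counts=True)
    dup = counts[inverse] > 1
    if dup.any():
        xy[dup] += rng.uniform(-magnitude, magnitude, size=(int(dup.sum()), 2))
    return CoordinateSet(unit_ids=list(c.unit_ids), xy=xy)
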