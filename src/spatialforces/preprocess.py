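"""Turn raw counts and spatial coordinates into model-ready inputs.

The model consumes a :class:`SpatialSample`: a cells x genes expression
matrix whose rows are spherically normalized (unit L2 norm), the 2-D
coordinates of each cell, and the binary symmetric adjacency matrix of the
k-nearest-neighbor spatial graph built from those coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialSample",
    "filter_genes",
    "log_normalize",
    "build_knn_graph",
    "crop_region",
    "drop_empty_cells",
    "sample_from_counts",
]


@dataclass
class SpatialSample:
    """A spatial expression sample: state, geometry, and neighbor graph.

    Parameters
    ----------
    expression
        cells x genes non-negative matrix; after :func:`log_normalize`
        every row has unit L2 norm.
    coords
        cells x 2 spatial coordinates, in the file's own length units.
        Distance thresholds applied downstream are interpreted in the
        same units.
    adjacency
        cells x cells binary symmetric hollow matrix (the kNN graph).
    gene_names, cell_ids
        Ordered labels for columns and rows.
    meta
        Provenance: source paths, normalization applied, graph parameters.
    """

    expression: np.ndarray
    coords: np.ndarray
    adjacency: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.gene_names = list(self.gene_names)
        self.cell_ids = list(self.cell_ids)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def validate(self) -> None:
        n, g = self.expression.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} cells x 2 dimensions"
            )
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} cells"
            )
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} genes")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} cells")
        if np.any(self.expression < 0):
            raise ValueError("expression contains negative entries")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency is not symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency has nonzero diagonal")
        vals = np.unique(self.adjacency)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("adjacency entries must be 0 or 1")


def filter_genes(
    counts: np.ndarray, min_cells: int
) -> tuple[np.ndarray, np.ndarray]:
    """Keep genes with nonzero counts in at least ``min_cells`` cells.

    Returns the reduced matrix and the indices of the kept genes, in the
    original column order.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_expressing = np.count_nonzero(counts, axis=0)
    kept = np.flatnonzero(n_expressing >= min_cells)
    if kept.size == 0:
        raise ValueError(
            f"empty gene set: no gene is expressed in >= {min_cells} cells"
        )
    return counts[:, kept], kept


def log_normalize(counts: np.ndarray, cpm: bool = False) -> np.ndarray:
    """log1p transform (base e) then spherical (unit L2) row normalization.

    With ``cpm`` each cell is first scaled to a library size of 1e6
    (counts per million). Cells with all-zero counts are an error; drop
    them first with :func:`drop_empty_cells`.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    libsize = counts.sum(axis=1)
    zero_cells = np.flatnonzero(libsize == 0)
    if zero_cells.size:
        raise ValueError(
            f"cells with all-zero counts at rows {zero_cells.tolist()}; "
            "drop them before normalizing"
        )
    if cpm:
        counts = counts / libsize[:, None] * 1e6
    logged = np.log1p(counts)
    norms = np.linalg.norm(logged, axis=1)
    # log1p keeps every positive count positive, so norms are > 0 here
    return logged / norms[:, None]


def build_knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Binary adjacency of the k-nearest-neighbor graph, symmetrized by union.

    Each cell points at its ``k`` nearest Euclidean neighbors (self
    excluded); an undirected edge exists if either direction is present.
    Distance ties are broken by lowest cell index, so the result is
    deterministic even with duplicate coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} cells, got {n}")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    # stable argsort -> ties resolved toward the lowest index
    nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
    adj = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    adj[rows, nearest.ravel()] = 1.0
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    return adj


def crop_region(
    sample: SpatialSample,
    xmin: float,
    xmax: float,
    ymin: float,
    ymax: float,
    k: int | None = None,
) -> SpatialSample:
    """Select cells strictly inside a rectangular window.

    The adjacency is rebuilt from the cropped coordinates (edges to
    removed cells would otherwise leave boundary cells under-connected).
    ``k`` defaults to the value recorded in ``sample.meta`` or 6.
    """
    if not (np.isfinite([xmin, xmax, ymin, ymax]).all() and xmin < xmax and ymin < ymax):
        raise ValueError("window bounds must be finite with xmin<xmax, ymin<ymax")
    x, y = sample.coords[:, 0], sample.coords[:, 1]
    keep = np.flatnonzero((x > xmin) & (x < xmax) & (y > ymin) & (y < ymax))
    if keep.size == 0:
        raise ValueError("crop window contains no cells")
    if k is None:
        k = int(sample.meta.get("n_neighbors", 6))
    k = min(k, keep.size - 1)
    coords = sample.coords[keep]
    if k >= 1:
        adjacency = build_knn_graph(coords, k)
    else:
        adjacency = np.zeros((keep.size, keep.size))
    return SpatialSample(
        expression=sample.expression[keep],
        coords=coords,
        adjacency=adjacency,
        gene_names=sample.gene_names,
        cell_ids=[sample.cell_ids[i] for i in keep],
        meta={**sample.meta, "crop": [xmin, xmax, ymin, ymax], "n_neighbors": k},
    )


def drop_empty_cells(
    counts: np.ndarray, coords: np.ndarray, cell_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str] | None]:
    """Remove cells whose counts are all zero, with a logged warning."""
    counts = np.asarray(counts, dtype=float)
    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        msg = f"dropping {n_dropped} cell(s) with all-zero counts"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    kept_ids = [c for c, k in zip(cell_ids, keep) if k] if cell_ids is not None else None
    return counts[keep], np.asarray(coords, dtype=float)[keep], kept_ids


def sample_from_counts(
    counts: np.ndarray,
    coords: np.ndarray,
    gene_names: list[str] | None = None,
    cell_ids: list[str] | None = None,
    min_cells: int | None = None,
    cpm: bool = False,
    n_neighbors: int = 6,
    already_normalized: bool = False,
) -> SpatialSample:
    """Convenience pipeline: filter, drop empty cells, normalize, build graph."""
    counts = np.asarray(counts, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, g = counts.shape
    if gene_names is None:
        gene_names = [f"gene{i}" for i in range(g)]
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    if min_cells is not None:
        counts, kept = filter_genes(counts, min_cells)
        gene_names = [gene_names[i] for i in kept]
    if already_normalized:
        expression = counts
    else:
        counts, coords, cell_ids = drop_empty_cells(counts, coords, cell_ids)
        expression = log_normalize(counts, cpm=cpm)
    k = min(n_neighbors, expression.shape[0] - 1)
    adjacency = build_knn_graph(coords, k)
    return SpatialSample(
        expression=expression,
        coords=coords,
        adjacency=adjacency,
        gene_names=gene_names,
        cell_ids=cell_ids,
        meta={
            "n_neighbors": k,
            "cpm": cpm,
            "normalized": "input" if already_normalized else "log1p+spherical",
        },
    )
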