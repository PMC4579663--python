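"""Tessellation of slide patterns and per-polygon cell counting.

The colocalization indices are defined on *quadrat counts*: the slide window
is partitioned into non-overlapping polygons — an axis-aligned square grid
(default side 250 μm, chosen around the effective cell-cell communication
distance) or a Voronoi tessellation of random generator points — and the
cancer (x_i), immune (y_i) and total (t_i) cell counts of each polygon are
recorded.  Polygons with too little tissue (t_i below a threshold) are
excluded before any index is computed.

Square-grid binning uses half-open intervals [lo, lo+side) anchored at the
window's minimum corner, so each cell maps to exactly one square; a cell on
the window's maximum edge is kept in the last row/column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .patterns import SlidePattern

DEFAULT_SQUARE_SIDE_UM = 250.0
DEFAULT_MIN_CELLS = 10


@dataclass
class Tessellation:
    """A partition of a slide window into non-overlapping polygons.

    ``polygons`` are shapely geometries clipped to the window; ``kind`` is
    ``"square"`` or ``"voronoi"``.  For square grids ``side_or_scale`` is the
    square side in μm and ``grid_shape``/``origin`` carry the binning
    arithmetic; for Voronoi tessellations ``seeds`` holds the generator
    points and ``side_or_scale`` an equivalent length scale
    sqrt(window area / n_seeds).
    """

    kind: str
    polygons: list
    polygon_ids: np.ndarray
    side_or_scale: float
    window: tuple[float, float, float, float]
    origin: tuple[float, float] | None = None
    grid_shape: tuple[int, int] | None = None  # (ncols, nrows)
    seeds: np.ndarray | None = None
    rng_seed: int | None = None

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons])

    @property
    def centroids(self) -> np.ndarray:
        if self.n_polygons == 0:
            return np.empty((0, 2))
        return np.array([[p.centroid.x, p.centroid.y] for p in self.polygons])


@dataclass
class QuadratCounts:
    """Per-polygon cancer/immune/total counts plus provenance.

    ``x`` are cancer counts, ``y`` immune counts and ``t`` total cell counts
    (stromal/other cells contribute to ``t`` only, for tissue filtering).
    ``centroids`` keep the polygon positions so spatially contiguous
    subsampling remains possible downstream.
    """

    polygon_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    centroids: np.ndarray
    tessellation_kind: str = "square"
    polygon_scale: float = DEFAULT_SQUARE_SIDE_UM
    n_dropped: int = 0
    min_cells: int = 0

    def __post_init__(self) -> None:
        self.polygon_ids = np.asarray(self.polygon_ids)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if (self.x < 0).any() or (self.y < 0).any() or (self.t < 0).any():
            raise ValueError("counts must be non-negative")
        if ((self.x + self.y) > self.t).any():
            raise ValueError("x_i + y_i must not exceed t_i")

    @property
    def n_polygons(self) -> int:
        return len(self.x)

    @property
    def X(self) -> int:
        """Total cancer cells across retained polygons."""
        return int(self.x.sum())

    @property
    def Y(self) -> int:
        """Total immune cells across retained polygons."""
        return int(self.y.sum())

    @classmethod
    def from_arrays(cls, x, y, t=None, **kw) -> "QuadratCounts":
        """Build counts from bare arrays (t defaults to x + y)."""
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        if t is None:
            t = x + y
        n = len(x)
        kw.setdefault("polygon_ids", np.arange(n))
        kw.setdefault("centroids", np.zeros((n, 2)))
        return cls(x=x, y=y, t=np.asarray(t, dtype=np.int64), **kw)


def build_square_tessellation(
    pattern: SlidePattern, side: float = DEFAULT_SQUARE_SIDE_UM
) -> Tessellation:
    """Tile the pattern window with axis-aligned squares of the given side.

    The grid is anchored at the window's minimum corner; the last row and
    column are clipped to the window, so the polygons always partition it.
    """
    if side <= 0:
        raise ValueError("square side must be positive")
    xmin, ymin, xmax, ymax = pattern.window
    w, h = xmax - xmin, ymax - ymin
    if len(pattern) == 0 or w <= 0 or h <= 0:
        warnings.warn("empty or degenerate pattern: returning empty tessellation")
        return Tessellation(
            kind="square",
            polygons=[],
            polygon_ids=np.array([], dtype=np.int64),
            side_or_scale=side,
            window=pattern.window,
            origin=(xmin, ymin),
            grid_shape=(0, 0),
        )
    ncols = int(np.ceil(w / side))
    nrows = int(np.ceil(h / side))
    polys, ids = [], []
    for row in range(nrows):
        for col in range(ncols):
            x0 = xmin + col * side
            y0 = ymin + row * side
            polys.append(box(x0, y0, min(x0 + side, xmax), min(y0 + side, ymax)))
            ids.append(row * ncols + col)
    return Tessellation(
        kind="square",
        polygons=polys,
        polygon_ids=np.asarray(ids, dtype=np.int64),
        side_or_scale=side,
        window=pattern.window,
        origin=(xmin, ymin),
        grid_shape=(ncols, nrows),
    )


def build_voronoi_tessellation(
    pattern: SlidePattern, n_seeds: int, seed: int | None = None
) -> Tessellation:
    """Voronoi tessellation of uniform random generator points in the window.

    The Voronoi cells are clipped to the window, so they partition it exactly.
    Reproducible for a fixed ``seed``.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 Voronoi generator points")
    xmin, ymin, xmax, ymax = pattern.window
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, n_seeds), rng.uniform(ymin, ymax, n_seeds)]
    )
    window_poly = box(xmin, ymin, xmax, ymax)
    diagram = voronoi_diagram(MultiPoint(pts.tolist()), envelope=window_poly)
    # voronoi_diagram does not preserve seed order: match cells back to seeds.
    cells = [None] * n_seeds
    raw = list(diagram.geoms)
    for geom in raw:
        clipped = geom.intersection(window_poly)
        if clipped.is_empty:
            continue
        # a Voronoi cell contains exactly its own generator
        for i, (sx, sy) in enumerate(pts):
            if cells[i] is None and geom.covers(Point(sx, sy)):
                cells[i] = clipped
                break
    polys = [c for c in cells if c is not None]
    kept = np.array([i for i, c in enumerate(cells) if c is not None])
    scale = float(np.sqrt(window_poly.area / n_seeds))
    return Tessellation(
        kind="voronoi",
        polygons=polys,
        polygon_ids=np.arange(len(polys), dtype=np.int64),
        side_or_scale=scale,
        window=pattern.window,
        seeds=pts[kept],
        rng_seed=seed,
    )


def _square_bin_indices(pattern: SlidePattern, tess: Tessellation) -> np.ndarray:
    xmin, ymin = tess.origin
    side = tess.side_or_scale
    ncols, nrows = tess.grid_shape
    col = np.floor((pattern.x - xmin) / side).astype(np.int64)
    row = np.floor((pattern.y - ymin) / side).astype(np.int64)
    # cells exactly on the window max edge belong to the last row/column
    col = np.clip(col, 0, ncols - 1)
    row = np.clip(row, 0, nrows - 1)
    return row * ncols + col


def count_cells(pattern: SlidePattern, tess: Tessellation) -> QuadratCounts:
    """Count cancer, immune and total cells in every tessellation polygon.

    Every cell is assigned to exactly one polygon: by half-open binning for
    square grids, by nearest generator for Voronoi cells (equivalent to
    point-in-polygon for the clipped diagram).
    """
    n = tess.n_polygons
    if n == 0:
        return QuadratCounts.from_arrays(
            x=np.array([], dtype=np.int64),
            y=np.array([], dtype=np.int64),
            t=np.array([], dtype=np.int64),
            polygon_ids=np.array([], dtype=np.int64),
            centroids=np.empty((0, 2)),
            tessellation_kind=tess.kind,
            polygon_scale=tess.side_or_scale,
        )
    if tess.kind == "square":
        dense_ids = _square_bin_indices(pattern, tess)
        # polygon order in tess.polygons follows polygon_ids
        id_to_pos = {int(pid): k for k, pid in enumerate(tess.polygon_ids)}
        assign = np.array([id_to_pos[int(i)] for i in dense_ids], dtype=np.int64)
    elif tess.kind == "voronoi":
        tree = cKDTree(tess.seeds)
        _, assign = tree.query(np.column_stack([pattern.x, pattern.y]))
        assign = assign.astype(np.int64)
    else:  # pragma: no cover - no other kinds constructed
        raise ValueError(f"unknown tessellation kind {tess.kind!r}")

    cancer = pattern.class_mask("cancer")
    immune = pattern.class_mask("immune")
    x = np.bincount(assign[cancer], minlength=n)
    y = np.bincount(assign[immune], minlength=n)
    t = np.bincount(assign, minlength=n)
    return QuadratCounts(
        polygon_ids=tess.polygon_ids,
        x=x,
        y=y,
        t=t,
        centroids=tess.centroids,
        tessellation_kind=tess.kind,
        polygon_scale=tess.side_or_scale,
    )


def filter_low_tissue(counts: QuadratCounts, min_cells: int = DEFAULT_MIN_CELLS) -> QuadratCounts:
    """Drop polygons whose total cell count falls below ``min_cells``.

    Mirrors the exclusion of tessellation squares with less than a
    predefined amount of tissue; the number of dropped polygons is recorded.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    keep = counts.t >= min_cells
    return QuadratCounts(
        polygon_ids=counts.polygon_ids[keep],
        x=counts.x[keep],
        y=counts.y[keep],
        t=counts.t[keep],
        centroids=counts.centroids[keep],
        tessellation_kind=counts.tessellation_kind,
        polygon_scale=counts.polygon_scale,
        n_dropped=counts.n_dropped + int((~keep).sum()),
        min_cells=min_cells,
    )
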