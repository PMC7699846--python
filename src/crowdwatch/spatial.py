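"""Gridded spatial statistics for check-in surfaces.

The study area is divided into a regular lon/lat grid (default cell size
2 arc-minutes). Check-ins are counted per cell and per time bin, and the
global Moran's I statistic

    I = n * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / ( sum_ij w_ij * sum_i (x_i - xbar)^2 )

summarizes the spatial autocorrelation of each hourly count surface: I > 0
when neighbouring cells hold similar counts (crowd aggregation), with
expectation -1/(n-1) under the permutation null. Weights are binary queen
contiguity by default and are not row-standardized — the statistic already
normalizes by the total weight sum; rook contiguity and row standardization
are available as switches.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .records import CheckInRecord

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

#: Sentinel returned by :func:`assign_cell` for points outside the grid extent.
OUTSIDE = None


class GridError(ValueError):
    """Raised for degenerate grid or bounding-box specifications."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid anchored at its southwest corner.

    Cells are half-open in both axes except along the global max edge,
    which is closed so the grid covers its extent exactly. Cells are
    indexed (row, col) from the southwest origin.
    """

    lon_min: float
    lat_min: float
    cell_size_arcmin: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_arcmin <= 0:
            raise GridError("cell_size_arcmin must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise GridError("grid must have at least one cell")

    @property
    def cell_size_deg(self) -> float:
        return self.cell_size_arcmin / 60.0

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size_deg

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size_deg

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_index(self, row: int, col: int) -> int:
        """Flatten (row, col) row-major to a unit index for weights/values."""
        return row * self.n_cols + col


def build_grid(
    bbox: tuple[float, float, float, float], cell_size_arcmin: float = 2.0
) -> GridSpec:
    """Cover ``bbox = (lon_min, lat_min, lon_max, lat_max)`` with a regular grid.

    The number of columns/rows is the ceiling of the bbox span over the cell
    size, so the grid always covers the bbox entirely (possibly overhanging
    on the north/east edges).
    """
    lon_min, lat_min, lon_max, lat_max = bbox
    if not (lon_min < lon_max and lat_min < lat_max):
        raise GridError(f"degenerate bbox {bbox}")
    span_lon_arcmin = (lon_max - lon_min) * 60.0
    span_lat_arcmin = (lat_max - lat_min) * 60.0
    n_cols = max(1, math.ceil(span_lon_arcmin / cell_size_arcmin - 1e-9))
    n_rows = max(1, math.ceil(span_lat_arcmin / cell_size_arcmin - 1e-9))
    return GridSpec(lon_min, lat_min, cell_size_arcmin, n_cols, n_rows)


def assign_cell(lon: float, lat: float, grid: GridSpec) -> tuple[int, int] | None:
    """Map a point to its (row, col) cell, or :data:`OUTSIDE`.

    Floor rule: a point on a shared interior edge belongs to the
    higher-index cell; points exactly on the global max edge fall in
    the last cell.
    """
    w = grid.cell_size_deg
    if lon < grid.lon_min or lat < grid.lat_min:
        return OUTSIDE
    if lon > grid.lon_max or lat > grid.lat_max:
        return OUTSIDE
    # relative epsilon keeps points lying exactly on a shared edge in the
    # higher-index cell despite float subtraction error
    col = int(math.floor((lon - grid.lon_min) / w + 1e-9))
    row = int(math.floor((lat - grid.lat_min) / w + 1e-9))
    col = min(col, grid.n_cols - 1)  # closed max edge
    row = min(row, grid.n_rows - 1)
    return row, col


@dataclass
class CountSurface:
    """Per-cell check-in counts for one time window."""

    grid: GridSpec
    window: tuple[datetime, datetime]
    counts: np.ndarray  # (n_rows, n_cols) int64
    n_outside: int = 0

    def values(self) -> np.ndarray:
        """Counts flattened row-major, aligned with weight unit indices."""
        return self.counts.reshape(-1).astype(float)


def count_surface(
    records: Iterable[CheckInRecord],
    grid: GridSpec,
    window: tuple[datetime, datetime],
) -> CountSurface:
    """Count records per grid cell over the half-open window [start, end)."""
    start, end = window
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=np.int64)
    n_outside = 0
    for rec in records:
        if not (start <= rec.timestamp < end):
            continue
        cell = assign_cell(rec.lon, rec.lat, grid)
        if cell is OUTSIDE:
            n_outside += 1
        else:
            counts[cell] += 1
    return CountSurface(grid=grid, window=window, counts=counts, n_outside=n_outside)


@dataclass
class SpatialWeights:
    """Sparse symmetric spatial weights (zero diagonal).

    Stored as parallel arrays of (i, j, w) triples covering both
    directions of every pair.
    """

    n: int
    i: np.ndarray
    j: np.ndarray
    w: np.ndarray

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.w.sum())

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        out[self.i, self.j] = self.w
        return out

    def row_standardized(self) -> "SpatialWeights":
        """Weights rescaled so every non-isolated row sums to 1."""
        row_sums = np.zeros(self.n)
        np.add.at(row_sums, self.i, self.w)
        safe = np.where(row_sums[self.i] > 0, row_sums[self.i], 1.0)
        return SpatialWeights(self.n, self.i.copy(), self.j.copy(), self.w / safe)


def _contiguity_weights(grid: GridSpec, corners: bool) -> SpatialWeights:
    n_rows, n_cols = grid.n_rows, grid.n_cols
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if corners:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    ii: list[int] = []
    jj: list[int] = []
    for r in range(n_rows):
        for c in range(n_cols):
            a = grid.cell_index(r, c)
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols:
                    ii.append(a)
                    jj.append(grid.cell_index(r2, c2))
    if not ii:
        warnings.warn(
            "grid has a single cell: weights have no positive entries; "
            "Moran's I will be undefined",
            stacklevel=3,
        )
        return SpatialWeights(
            grid.n_cells,
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0),
        )
    return SpatialWeights(
        grid.n_cells,
        np.asarray(ii, dtype=np.int64),
        np.asarray(jj, dtype=np.int64),
        np.ones(len(ii)),
    )


def queen_weights(grid: GridSpec) -> SpatialWeights:
    """Binary queen contiguity: cells sharing an edge or a corner."""
    return _contiguity_weights(grid, corners=True)


def rook_weights(grid: GridSpec) -> SpatialWeights:
    """Binary rook contiguity: cells sharing an edge only."""
    return _contiguity_weights(grid, corners=False)


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I, or a flagged degenerate outcome."""

    I: float | None
    n_units: int
    s0: float
    degenerate: bool = False
    reason: Literal["zero variance", "no weights", None] = None

    def __float__(self) -> float:
        return math.nan if self.I is None else self.I


def morans_i(values: Sequence[float], weights: SpatialWeights) -> MoranResult:
    """Global Moran's I of ``values`` under ``weights``.

    Returns a degenerate result (I undefined) for constant surfaces or
    all-zero weights rather than raising: empty night-hour surfaces are a
    routine input.
    """
    x = np.asarray(values, dtype=float).reshape(-1)
    if x.size != weights.n:
        raise ValueError(f"{x.size} values for {weights.n} spatial units")
    if x.size < 2:
        return MoranResult(None, x.size, weights.s0, True, "no weights")
    s0 = weights.s0
    if s0 <= 0:
        return MoranResult(None, x.size, s0, True, "no weights")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return MoranResult(None, x.size, s0, True, "zero variance")
    num = float(np.sum(weights.w * z[weights.i] * z[weights.j]))
    return MoranResult(x.size * num / (s0 * denom), x.size, s0)


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km (haversine, mean Earth radius)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def within_buffer(
    lon: float, lat: float, center: tuple[float, float], radius_km: float
) -> bool:
    """True iff the point lies within ``radius_km`` of ``center`` (closed)."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    if not (-180 <= lon <= 180 and -90 <= lat <= 90):
        raise ValueError(f"invalid coordinates ({lon}, {lat})")
    return haversine_km(lon, lat, center[0], center[1]) <= radius_km


def buffer_filter(
    records: Iterable[CheckInRecord],
    center: tuple[float, float],
    radius_km: float,
) -> list[CheckInRecord]:
    """Records within the geodesic buffer around ``center``."""
    return [r for r in records if within_buffer(r.lon, r.lat, center, radius_km)]


# ---------------------------------------------------------------------------
# Time binning


@dataclass
class BinSeries:
    """One value per contiguous half-open time bin of equal width.

    Undefined values (degenerate bins) are NaN.
    """

    starts: list[datetime]
    width: timedelta
    values: np.ndarray
    label: str = ""

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> list[datetime]:
        return [t + self.width for t in self.starts]

    def defined(self) -> np.ndarray:
        """Boolean mask of bins with a defined value."""
        return ~np.isnan(self.values)

    def argmax_defined(self) -> int | None:
        """Index of the largest defined value, or None if all undefined."""
        if not self.defined().any():
            return None
        return int(np.nanargmax(self.values))

    def to_csv(self, path: str | Path) -> None:
        import csv as _csv

        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["bin_start", "bin_end", "value"])
            for s, e, v in zip(self.starts, self.ends, self.values):
                w.writerow([s.isoformat(), e.isoformat(), "" if np.isnan(v) else repr(float(v))])


_GRANULARITY = {"hour": timedelta(hours=1), "day": timedelta(days=1)}


def _floor_to_bin(t: datetime, granularity: str) -> datetime:
    if granularity == "hour":
        return t.replace(minute=0, second=0, microsecond=0)
    return t.replace(hour=0, minute=0, second=0, microsecond=0)


def time_bins(
    window: tuple[datetime, datetime], granularity: str = "hour"
) -> tuple[list[datetime], timedelta]:
    """Clock-aligned half-open bins covering ``window``."""
    if granularity not in _GRANULARITY:
        raise ValueError(f"unknown granularity {granularity!r}")
    width = _GRANULARITY[granularity]
    start = _floor_to_bin(window[0], granularity)
    starts = []
    t = start
    while t < window[1]:
        starts.append(t)
        t = t + width
    return starts, width


def bin_index(
    t: datetime, starts: Sequence[datetime], width: timedelta
) -> int | None:
    """Index of the bin containing instant ``t``, or None if out of range."""
    if not starts or t < starts[0] or t >= starts[-1] + width:
        return None
    return int((t - starts[0]) // width)


def series_by_bin(
    records: Sequence[CheckInRecord],
    granularity: str = "hour",
    statistic: str = "count",
    grid: GridSpec | None = None,
    weights: SpatialWeights | None = None,
    window: tuple[datetime, datetime] | None = None,
) -> BinSeries:
    """Hourly/daily series of check-in counts or per-bin Moran's I.

    Bins are half-open ``[t, t + width)`` aligned to clock boundaries in the
    records' UTC offset. The ``moran`` statistic computes Moran's I on each
    bin's count surface; degenerate bins (constant or empty surfaces)
    propagate as NaN.
    """
    if statistic not in ("count", "moran"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if granularity not in _GRANULARITY:
        raise ValueError(f"unknown granularity {granularity!r}")
    if window is None:
        if not records:
            return BinSeries([], _GRANULARITY[granularity], np.empty(0), statistic)
        window = (min(r.timestamp for r in records), max(r.timestamp for r in records) + timedelta(microseconds=1))
    starts, width = time_bins(window, granularity)
    if statistic == "count":
        values = np.zeros(len(starts))
        for rec in records:
            k = bin_index(rec.timestamp, starts, width)
            if k is not None:
                values[k] += 1
        return BinSeries(starts, width, values, "count")
    if grid is None or weights is None:
        raise ValueError("moran statistic requires grid and weights")
    values = np.full(len(starts), np.nan)
    per_bin: list[list[CheckInRecord]] = [[] for _ in starts]
    for rec in records:
        k = bin_index(rec.timestamp, starts, width)
        if k is not None:
            per_bin[k].append(rec)
    for k, bucket in enumerate(per_bin):
        surf = count_surface(bucket, grid, (starts[k], starts[k] + width))
        res = morans_i(surf.values(), weights)
        if not res.degenerate:
            values[k] = res.I
    return BinSeries(starts, width, values, "moran_i")


# ---------------------------------------------------------------------------
# Exports


def surface_to_csv(surface: CountSurface, path: str | Path) -> None:
    """Write per-cell counts as ``row,col,count``."""
    import csv as _csv

    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["row", "col", "count"])
        for r in range(surface.grid.n_rows):
            for c in range(surface.grid.n_cols):
                w.writerow([r, c, int(surface.counts[r, c])])


def surface_to_geojson(surface: CountSurface, path: str | Path) -> None:
    """Write the grid as a GeoJSON FeatureCollection of cell polygons."""
    grid = surface.grid
    w = grid.cell_size_deg
    features = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0 = grid.lon_min + c * w
            y0 = grid.lat_min + r * w
            ring = [
                [x0, y0],
                [x0 + w, y0],
                [x0 + w, y0 + w],
                [x0, y0 + w],
                [x0, y0],
            ]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"row": r, "col": c, "count": int(surface.counts[r, c])},
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
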