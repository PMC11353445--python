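"""Study regions, regular grids, point patterns and their discretization.

The inference machinery works on a finite partition of a rectangular study
region: each cell ``G_z`` is represented by its centroid ``s_z`` and Lebesgue
measure (area) ``nu(G_z)``, and an observed point pattern is reduced to the
vector of per-cell event counts ``y``.  Cells are half-open
``[x_lo, x_hi) x [y_lo, y_hi)`` with the top/right region boundary closed, so
every event in the region belongs to exactly one cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "SpatialGrid",
    "PointPattern",
    "ObservedCounts",
    "AffineMap",
    "build_grid",
    "discretize",
    "rescale_to_unit",
    "read_pattern_csv",
    "write_pattern_csv",
    "read_counts_csv",
    "write_counts_csv",
]


@dataclass(frozen=True)
class Region:
    """Rectangular planar study region (already-projected coordinates).

    ``rotation_deg`` records an optional pre-rotation applied to raw
    coordinates before they were boxed into this rectangle; it is metadata
    used when mapping results back to the original frame.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                f"degenerate region: [{self.xmin}, {self.xmax}] x "
                f"[{self.ymin}, {self.ymax}]"
            )

    @property
    def area(self) -> float:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def diameter(self) -> float:
        return float(np.hypot(self.xmax - self.xmin, self.ymax - self.ymin))

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )


UNIT_SQUARE = Region(0.0, 1.0, 0.0, 1.0)


@dataclass(frozen=True)
class SpatialGrid:
    """Partition of a region into Z cells with centroids and measures.

    Downstream operations only consume ``centroids`` and ``cell_measures``,
    so an irregular partition can be supplied directly; :func:`build_grid`
    constructs the regular nx-by-ny rectangular case.  Cell order is
    row-major: x fastest, bottom row first.
    """

    region: Region
    nx: int
    ny: int
    centroids: np.ndarray = field(repr=False)  # (Z, 2)
    cell_measures: np.ndarray = field(repr=False)  # (Z,)

    @property
    def Z(self) -> int:
        return int(self.centroids.shape[0])

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        m = np.asarray(self.cell_measures, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or m.shape != (c.shape[0],):
            raise ValueError("centroids must be (Z, 2) and cell_measures (Z,)")
        if np.any(m <= 0):
            raise ValueError("cell measures must be positive")
        if abs(m.sum() - self.region.area) > 1e-9 * self.region.area:
            raise ValueError("cell measures do not sum to the region area")

    def cell_index(self, xy: np.ndarray) -> np.ndarray:
        """Row-major cell index of each point; half-open cell convention."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        r = self.region
        inside = self.contains_or_raise(xy)
        del inside
        fx = (xy[:, 0] - r.xmin) / (r.xmax - r.xmin) * self.nx
        fy = (xy[:, 1] - r.ymin) / (r.ymax - r.ymin) * self.ny
        ix = np.minimum(np.floor(fx).astype(int), self.nx - 1)
        iy = np.minimum(np.floor(fy).astype(int), self.ny - 1)
        return iy * self.nx + ix

    def contains_or_raise(self, xy: np.ndarray) -> None:
        ok = self.region.contains(xy)
        if not np.all(ok):
            bad = np.atleast_2d(xy)[~ok][0]
            raise ValueError(
                f"event ({bad[0]}, {bad[1]}) lies outside the region"
            )


@dataclass(frozen=True)
class PointPattern:
    """A spatial point pattern: n event locations in a region."""

    events: np.ndarray  # (n, 2)
    region: Region

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "events", ev)
        if ev.size and not np.all(self.region.contains(ev)):
            bad = ev[~self.region.contains(ev)][0]
            raise ValueError(
                f"event ({bad[0]}, {bad[1]}) lies outside the region"
            )

    @property
    def n(self) -> int:
        return int(self.events.shape[0])


@dataclass(frozen=True)
class ObservedCounts:
    """Per-cell event counts y over a grid."""

    y: np.ndarray  # (Z,) non-negative ints
    grid: SpatialGrid

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.shape != (self.grid.Z,):
            raise ValueError("count vector length must equal grid.Z")
        if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "y", y.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.y.sum())

    def data_hash(self) -> str:
        """Stable fingerprint of (grid, counts) for compare() safety checks."""
        import hashlib

        h = hashlib.sha256()
        g = self.grid
        h.update(np.asarray([g.region.xmin, g.region.xmax, g.region.ymin,
                             g.region.ymax, g.nx, g.ny], dtype=float).tobytes())
        h.update(self.y.tobytes())
        return h.hexdigest()[:16]


def build_grid(region: Region, nx: int, ny: int) -> SpatialGrid:
    """Partition ``region`` into nx-by-ny equal rectangular cells."""
    if nx < 1 or ny < 1:
        raise ValueError(f"grid resolution must be positive, got {nx}x{ny}")
    r = region
    xs = r.xmin + (np.arange(nx) + 0.5) * (r.xmax - r.xmin) / nx
    ys = r.ymin + (np.arange(ny) + 0.5) * (r.ymax - r.ymin) / ny
    gx, gy = np.meshgrid(xs, ys)  # row-major: x fastest
    centroids = np.column_stack([gx.ravel(), gy.ravel()])
    measures = np.full(nx * ny, r.area / (nx * ny))
    return SpatialGrid(region=r, nx=nx, ny=ny, centroids=centroids,
                       cell_measures=measures)


def discretize(pattern: PointPattern, grid: SpatialGrid) -> ObservedCounts:
    """Count events per grid cell; conserves the total event count."""
    y = np.zeros(grid.Z, dtype=np.int64)
    if pattern.n:
        idx = grid.cell_index(pattern.events)
        np.add.at(y, idx, 1)
    return ObservedCounts(y=y, grid=grid)


@dataclass(frozen=True)
class AffineMap:
    """Separable affine map (x, y) -> (ax*x+bx, ay*y+by) with exact inverse."""

    ax: float
    bx: float
    ay: float
    by: float

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = np.empty_like(xy)
        out[..., 0] = self.ax * xy[..., 0] + self.bx
        out[..., 1] = self.ay * xy[..., 1] + self.by
        return out

    def inverse(self) -> "AffineMap":
        return AffineMap(1.0 / self.ax, -self.bx / self.ax,
                         1.0 / self.ay, -self.by / self.ay)


def rescale_to_unit(pattern: PointPattern) -> tuple[PointPattern, AffineMap]:
    """Affinely map a pattern's region onto the unit square.

    Returns the rescaled pattern and the forward map so estimates can be
    carried back to the original frame via ``amap.inverse()``.
    """
    r = pattern.region
    amap = AffineMap(1.0 / (r.xmax - r.xmin), -r.xmin / (r.xmax - r.xmin),
                     1.0 / (r.ymax - r.ymin), -r.ymin / (r.ymax - r.ymin))
    ev = amap(pattern.events) if pattern.n else pattern.events
    # clip FP spill at the closed top/right boundary
    ev = np.clip(ev, 0.0, 1.0) if len(ev) else ev
    out = PointPattern(events=ev,
                       region=Region(0, 1, 0, 1, rotation_deg=r.rotation_deg))
    return out, amap


# ---------------------------------------------------------------------------
# File I/O.  Pattern CSV: columns x,y (one event/row).  Counts CSV: columns
# cell_id,cx,cy,measure,count.  A JSON sidecar-free region header is encoded
# in a leading comment line for lossless round-trips.
# ---------------------------------------------------------------------------

def _region_comment(region: Region) -> str:
    return "# region " + json.dumps(
        {"xmin": region.xmin, "xmax": region.xmax, "ymin": region.ymin,
         "ymax": region.ymax, "rotation_deg": region.rotation_deg})


def _parse_region_comment(line: str) -> Region | None:
    if not line.startswith("# region "):
        return None
    d = json.loads(line[len("# region "):])
    return Region(**d)


def write_pattern_csv(pattern: PointPattern, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_region_comment(pattern.region) + "\n")
        fh.write("x,y\n")
        for x, y in pattern.events:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_pattern_csv(path: str | Path,
                     region: Region | None = None) -> PointPattern:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        hdr_region = _parse_region_comment(first)
        skip = 1 if hdr_region else 0
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas names the line
        raise ValueError(f"malformed pattern CSV {path}: {exc}") from exc
    if list(df.columns) != ["x", "y"]:
        raise ValueError(f"{path}: expected header 'x,y', got {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2 + skip}")
    reg = region or hdr_region
    if reg is None:
        ev = df.to_numpy(float)
        if len(ev) < 2:
            raise ValueError("no region header and too few events to infer one")
        reg = Region(ev[:, 0].min(), ev[:, 0].max(), ev[:, 1].min(), ev[:, 1].max())
    return PointPattern(events=df.to_numpy(float), region=reg)


def write_counts_csv(counts: ObservedCounts, path: str | Path) -> None:
    path = Path(path)
    g = counts.grid
    with path.open("w") as fh:
        fh.write(_region_comment(g.region) + "\n")
        fh.write(f"# grid {g.nx} {g.ny}\n")
        fh.write("cell_id,cx,cy,measure,count\n")
        for z in range(g.Z):
            cx, cy = g.centroids[z]
            fh.write(f"{z},{float(cx)!r},{float(cy)!r},"
                     f"{float(g.cell_measures[z])!r},{counts.y[z]}\n")


def read_counts_csv(path: str | Path) -> ObservedCounts:
    path = Path(path)
    with path.open() as fh:
        region = _parse_region_comment(fh.readline().rstrip("\n"))
        grid_line = fh.readline().split()
    if region is None or len(grid_line) != 4 or grid_line[1] != "grid":
        raise ValueError(f"{path}: missing region/grid header lines")
    nx, ny = int(grid_line[2]), int(grid_line[3])
    df = pd.read_csv(path, skiprows=2, float_precision="round_trip")
    if list(df.columns) != ["cell_id", "cx", "cy", "measure", "count"]:
        raise ValueError(f"{path}: unexpected counts header {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed row at line {bad[0] + 4}")
    df = df.sort_values("cell_id")
    grid = SpatialGrid(region=region, nx=nx, ny=ny,
                       centroids=df[["cx", "cy"]].to_numpy(float),
                       cell_measures=df["measure"].to_numpy(float))
    return ObservedCounts(y=df["count"].to_numpy(np.int64), grid=grid)
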