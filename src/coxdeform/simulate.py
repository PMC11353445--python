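"""Benchmark data generation.

Two sources of synthetic point patterns:

1. a deterministic, highly oscillatory intensity on the unit square whose
   oscillation frequency grows towards two corners — a surface that rewards
   anisotropic/nonstationary modelling — sampled exactly by Poisson
   thinning;
2. the hierarchical model itself at a known parameter state (known range,
   maximal intensity and deformation), for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import cholesky

from .geometry import (ObservedCounts, PointPattern, Region, SpatialGrid,
                       UNIT_SQUARE)
from .model import ModelState, build_beta_covariance

__all__ = [
    "IntensitySurface",
    "benchmark_intensity",
    "benchmark_surface",
    "benchmark_cell_truth",
    "sample_inhomogeneous_pp",
    "simulate_from_model",
]


@dataclass(frozen=True)
class IntensitySurface:
    """A non-negative intensity evaluator over a region.

    ``bound`` must dominate the supremum of the intensity over the region;
    it is the proposal rate for thinning.
    """

    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    region: Region
    bound: float

    def __call__(self, x, y):
        return self.func(np.asarray(x, float), np.asarray(y, float))


def benchmark_intensity(x, y):
    """Oscillatory benchmark intensity on the open unit square.

    Base surface ``191 sin(22.8 x^2 (1-y)^2) exp(x^2 + (1-y)^2) + 1150``
    everywhere; on the upper triangle ``x < y`` an additional
    ``450 cos(10 y^1.2 (1-x)^1.2)`` term is superposed.  The boundary
    ``y = x`` follows the lower-triangle branch (a measure-zero convention).
    The two branches make the oscillation frequency and amplitude grow
    towards the (1, 0) and (0, 1) corners in different ways, creating strong
    directional nonstationarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x <= 0) | (x >= 1) | (y <= 0) | (y >= 1)):
        raise ValueError("benchmark intensity is defined on the open unit "
                         "square only")
    base = 191.0 * np.sin(22.8 * x**2 * (1.0 - y)**2) \
        * np.exp(x**2 + (1.0 - y)**2) + 1150.0
    upper = 450.0 * np.cos(10.0 * y**1.2 * (1.0 - x)**1.2)
    return np.where(x < y, base + upper, base)


def _benchmark_bound(n_grid: int = 400) -> float:
    g = (np.arange(n_grid) + 0.5) / n_grid
    gx, gy = np.meshgrid(g, g)
    return float(benchmark_intensity(gx, gy).max()) * 1.05


def benchmark_surface() -> IntensitySurface:
    """The benchmark intensity packaged with a thinning bound.

    The bound is the maximum over a fine evaluation grid inflated by 5%.
    """
    return IntensitySurface(func=benchmark_intensity, region=UNIT_SQUARE,
                            bound=_benchmark_bound())


def benchmark_cell_truth(grid: SpatialGrid, average: bool = False,
                         sub: int = 20) -> np.ndarray:
    """True per-cell intensity of the benchmark surface.

    By default the cell-midpoint value (matching the piecewise-constant
    representative-point convention used by the discretized model); with
    ``average=True`` a ``sub x sub`` midpoint quadrature average per cell.
    """
    if not average:
        c = grid.centroids
        return benchmark_intensity(c[:, 0], c[:, 1])
    out = np.empty(grid.Z)
    r = grid.region
    wx = (r.xmax - r.xmin) / grid.nx
    wy = (r.ymax - r.ymin) / grid.ny
    off = (np.arange(sub) + 0.5) / sub
    ox, oy = np.meshgrid(off, off)
    for z in range(grid.Z):
        cx, cy = grid.centroids[z]
        xs = cx - wx / 2 + ox * wx
        ys = cy - wy / 2 + oy * wy
        out[z] = benchmark_intensity(xs, ys).mean()
    return out


def sample_inhomogeneous_pp(surface: IntensitySurface,
                            seed) -> PointPattern:
    """Sample a Poisson process with intensity ``surface`` by thinning.

    A homogeneous Poisson proposal at rate ``surface.bound`` is thinned with
    acceptance probability ``lambda(s)/bound``.  Raises if the bound is
    found to be violated (the realization would be biased).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    r = surface.region
    if not np.isfinite(surface.bound) or surface.bound < 0:
        raise ValueError("thinning requires a finite non-negative bound")
    n_prop = rng.poisson(surface.bound * r.area)
    if n_prop == 0:
        return PointPattern(events=np.empty((0, 2)), region=r)
    xs = rng.uniform(r.xmin, r.xmax, n_prop)
    ys = rng.uniform(r.ymin, r.ymax, n_prop)
    lam = np.asarray(surface(xs, ys), dtype=float)
    if np.any(lam < 0):
        raise ValueError("intensity evaluated negative during thinning")
    if np.any(lam > surface.bound):
        raise ValueError(
            f"intensity {lam.max():.6g} exceeds the stated bound "
            f"{surface.bound:.6g}; the bound is wrong")
    keep = rng.uniform(0.0, 1.0, n_prop) < lam / surface.bound
    return PointPattern(events=np.column_stack([xs, ys])[keep], region=r)


def simulate_from_model(state: ModelState, grid: SpatialGrid,
                        seed, jitter: float = 1e-8,
                        resample_beta: bool = True,
                        ) -> tuple[PointPattern, ObservedCounts]:
    """Generate counts (and a pattern) from the hierarchical model.

    Draws ``beta | d, theta, delta`` from its multivariate normal (unless
    ``resample_beta=False``, in which case ``state.beta`` is used as given),
    forms the piecewise-constant intensity
    ``lambda_star g(mu + beta_z)`` and samples per-cell Poisson counts with
    mean ``lambda_z nu(G_z)``.  Events are then scattered uniformly within
    their cells, which is the exact event distribution for a
    piecewise-constant intensity.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    h = state.hyper
    if resample_beta:
        Sigma = build_beta_covariance(grid, h.theta, h.delta, state.mode,
                                      state.deformation, jitter)
        L = cholesky(Sigma, lower=True)
        beta = L @ rng.standard_normal(grid.Z)
    else:
        beta = np.asarray(state.beta, dtype=float)
    lam_cells = h.lambda_star * state.link.g(h.mu + beta)
    means = lam_cells * grid.cell_measures
    y = rng.poisson(means)
    # scatter events uniformly inside their cells
    r = grid.region
    wx = (r.xmax - r.xmin) / grid.nx
    wy = (r.ymax - r.ymin) / grid.ny
    pts = []
    for z in np.nonzero(y)[0]:
        cx, cy = grid.centroids[z]
        u = rng.uniform(-0.5, 0.5, size=(y[z], 2))
        pts.append(np.column_stack([cx + u[:, 0] * wx, cy + u[:, 1] * wy]))
    events = np.concatenate(pts) if pts else np.empty((0, 2))
    pattern = PointPattern(events=events, region=r)
    return pattern, ObservedCounts(y=y.astype(np.int64), grid=grid)
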