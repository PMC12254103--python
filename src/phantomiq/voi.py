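"""Cubic volume-of-interest identification and statistics.

The target VOI is a cube (in mm) of half-width ``r_s`` — the sphere radius —
centered on a midpoint voxel.  Starting from an initial guess of the sphere
midpoint, the center is refined over a local grid of candidates (±5 voxels in
x and y, ±3 slices in z, reflecting the lower through-plane resolution) and
the candidate maximizing the VOI *mean* activity is selected.

The background VOI reuses the half-width of the largest sphere and sits at a
fixed, configured position in the left-posterior background of the body
compartment; its position is never optimized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import GridSpec, PhantomSpec, VoxelImage

XY_SEARCH_RANGE = 5   # voxels, in-plane refinement half-range
Z_SEARCH_RANGE = 3    # slices, through-plane refinement half-range


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class VOI:
    """Cubic VOI: center voxel, sphere radius, and inclusive index bounds."""

    center: tuple[int, int, int]
    r_s: float                                   # mm
    bounds: tuple[tuple[int, int], ...]          # inclusive (lo, hi) per axis

    @property
    def n_voxels(self) -> int:
        return int(np.prod([hi - lo + 1 for lo, hi in self.bounds]))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi + 1) for lo, hi in self.bounds)


@dataclass(frozen=True)
class VOIStats:
    t_mean: float
    t_max: float
    n_voxels: int


def voi_half_widths(r_s: float, grid: GridSpec) -> tuple[int, int, int]:
    """Per-axis half-width in voxels: round(r_s / pitch), at least 1."""
    if r_s <= 0:
        raise ValueError(f"r_s must be > 0, got {r_s}")
    return tuple(max(1, _round_half_away(r_s / v)) for v in grid.voxel_size)


def cubic_voi(center: tuple[int, int, int], r_s: float, grid: GridSpec) -> VOI:
    """Cube of half-width ``r_s`` (mm) around a center voxel.

    Raises an out-of-bounds error naming the axis if the cube does not fit;
    silent clipping would bias the VOI mean.
    """
    half = voi_half_widths(r_s, grid)
    bounds = []
    for a in range(3):
        lo = center[a] - half[a]
        hi = center[a] + half[a]
        if lo < 0 or hi >= grid.shape[a]:
            raise ValueError(
                f"VOI of half-width {half[a]} voxels around index {center[a]} "
                f"exceeds image bounds on axis {a} (size {grid.shape[a]})")
        bounds.append((lo, hi))
    return VOI(center=tuple(center), r_s=r_s, bounds=tuple(bounds))


def voi_stats(image: VoxelImage, voi: VOI) -> VOIStats:
    """Mean and maximum activity over the VOI voxels."""
    block = image.values[voi.slices()]
    return VOIStats(t_mean=float(block.mean()), t_max=float(block.max()),
                    n_voxels=int(block.size))


def refine_midpoint(image: VoxelImage, initial: tuple[int, int, int], r_s: float,
                    xy_range: int = XY_SEARCH_RANGE, z_range: int = Z_SEARCH_RANGE,
                    ) -> tuple[tuple[int, int, int], VOIStats]:
    """Exhaustively refine the sphere-midpoint guess over the local grid.

    All ``(2*xy_range+1)^2 * (2*z_range+1)`` candidates (847 by default) are
    evaluated and the one with maximal VOI mean is returned.  Ties are broken
    by smallest Euclidean index distance to the initial guess, then by
    lexicographic index order, so the result is deterministic.
    """
    grid = image.grid
    half = voi_half_widths(r_s, grid)
    ranges = (xy_range, xy_range, z_range)
    for a in range(3):
        lo = initial[a] - ranges[a] - half[a]
        hi = initial[a] + ranges[a] + half[a]
        if lo < 0 or hi >= grid.shape[a]:
            raise ValueError(
                f"refinement grid around {initial} would leave the image on "
                f"axis {a}; pad or crop the image first")

    best = None
    for dx in range(-xy_range, xy_range + 1):
        for dy in range(-xy_range, xy_range + 1):
            for dz in range(-z_range, z_range + 1):
                cand = (initial[0] + dx, initial[1] + dy, initial[2] + dz)
                voi = cubic_voi(cand, r_s, grid)
                t_mean = float(image.values[voi.slices()].mean())
                key = (-t_mean, dx * dx + dy * dy + dz * dz, cand)
                if best is None or key < best[0]:
                    best = (key, cand)
    center = best[1]
    return center, voi_stats(image, cubic_voi(center, r_s, grid))


def background_voi(grid: GridSpec, r_largest: float,
                   center_mm: tuple[float, float, float] = (-80.0, -52.0, 0.0),
                   phantom: PhantomSpec | None = None,
                   min_clearance_mm: float = 0.0) -> VOI:
    """Fixed background VOI with the largest sphere's half-width.

    ``center_mm`` is the configured left-posterior position in physical
    coordinates.  If ``phantom`` is given, the cube is checked geometrically
    against every sphere and an error is raised on overlap.
    """
    center_idx = grid.nearest_voxel(center_mm)
    voi = cubic_voi(center_idx, r_largest, grid)
    if phantom is not None:
        half_mm = [h * v for h, v in zip(voi_half_widths(r_largest, grid),
                                         grid.voxel_size)]
        c = [grid.origin[a] + center_idx[a] * grid.voxel_size[a] for a in range(3)]
        corners = np.array([[c[0] + sx * half_mm[0], c[1] + sy * half_mm[1],
                             c[2] + sz * half_mm[2]]
                            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        inside = phantom.body.contains(corners[:, 0], corners[:, 1], corners[:, 2])
        if not np.all(inside):
            raise ValueError(
                f"background VOI at {center_mm} extends outside the body "
                "compartment; choose a position further inside")
        for k, (d, sc) in enumerate(phantom.spheres):
            # distance from sphere center to the nearest point of the box
            gap = 0.0
            for a in range(3):
                excess = max(abs(sc[a] - c[a]) - half_mm[a], 0.0)
                gap += excess * excess
            if math.sqrt(gap) < d / 2.0 + min_clearance_mm:
                raise ValueError(
                    f"background VOI at {center_mm} overlaps sphere {k} "
                    f"({d} mm at {sc})")
    return voi


def background_stats(image: VoxelImage, voi: VOI) -> tuple[float, float]:
    """(B_mean, sigma_B): mean and sample SD (n-1) over the background VOI."""
    block = image.values[voi.slices()]
    if block.size < 2:
        raise ValueError("background VOI must contain at least 2 voxels "
                         "for a sample standard deviation")
    return float(block.mean()), float(block.std(ddof=1))
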