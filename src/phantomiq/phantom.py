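"""NEMA-IEC body phantom description and voxelization.

The phantom is modeled as an elliptical-cylinder body compartment filled with
a background activity concentration ``B_in`` and six fillable spheres at
``T_in = TBR * B_in``.  Sphere walls are ignored: each sphere is a filled
region of the inside diameter, because only inside diameters are known.

Axis convention (fixed throughout the package): axis 0 = x (left-right),
axis 1 = y (anterior-posterior), axis 2 = z (inferior-superior).  Respiratory
motion acts along axis 2.  Voxel indexing is 0-based and a voxel's physical
coordinate is the coordinate of its *center*: ``origin + index * voxel_size``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Fluorine-18 half-life in minutes (physical constant, not a tunable).
F18_HALF_LIFE_MIN = 109.77

#: Inside diameters (mm) of the six NEMA-IEC spheres.
DEFAULT_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

#: Radius (mm) of the ring on which the sphere centers sit.
SPHERE_RING_RADIUS_MM = 57.2


def sphere_volume_ml(inside_diameter: float) -> float:
    """Volume (mL) of a sphere with the given inside diameter (mm).

    The NEMA sphere set's nominal volumes (0.5, 1.2, 2.6, 5.6, 11.5,
    26.5 mL) are recovered to one decimal from the inside diameters.
    """
    if inside_diameter <= 0:
        raise ValueError(f"inside_diameter must be > 0, got {inside_diameter}")
    radius_mm = inside_diameter / 2.0
    return (4.0 / 3.0) * math.pi * radius_mm**3 / 1000.0


def decay_correct(activity_0: float, elapsed: float,
                  half_life: float = F18_HALF_LIFE_MIN) -> float:
    """Decay a prepared activity concentration forward by ``elapsed`` minutes.

    Used to convert the dose-calibrator reading at fill time into the true
    activity at scan initiation, which enters the RC denominator.
    """
    if elapsed < 0:
        raise ValueError(f"elapsed must be >= 0, got {elapsed}")
    if half_life <= 0:
        raise ValueError(f"half_life must be > 0, got {half_life}")
    if activity_0 < 0:
        raise ValueError(f"activity_0 must be >= 0, got {activity_0}")
    return activity_0 * math.exp(-math.log(2.0) * elapsed / half_life)


def default_sphere_centers(ring_radius: float = SPHERE_RING_RADIUS_MM,
                           z: float = 0.0) -> list[tuple[float, float, float]]:
    """Sphere centers on the standard ring, one per default diameter.

    Spheres are placed at 60 degree spacing starting with the largest at 0
    degrees, all in the transaxial plane ``z``.
    """
    centers = []
    for k in range(6):
        theta = math.radians(60.0 * k)
        centers.append((ring_radius * math.cos(theta),
                        ring_radius * math.sin(theta), z))
    # pair largest-first diameters with angles 0, 60, ... so callers zipping
    # with DEFAULT_SPHERE_DIAMETERS_MM (ascending) get the reversed ring
    return list(reversed(centers))


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: shape, spacing (mm) and the center coordinate of voxel 0."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (500.0 / 440.0, 500.0 / 440.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")

    @classmethod
    def centered(cls, extent_mm: tuple[float, float, float],
                 voxel_size: tuple[float, float, float] = (500.0 / 440.0, 500.0 / 440.0, 2.0),
                 ) -> "GridSpec":
        """Grid symmetric about the physical origin covering ``extent_mm``."""
        shape = tuple(int(math.ceil(e / v)) + 1 for e, v in zip(extent_mm, voxel_size))
        origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, voxel_size))
        return cls(shape=shape, voxel_size=voxel_size, origin=origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates of all voxels along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def nearest_voxel(self, point_mm: tuple[float, float, float]) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to a physical point."""
        idx = []
        for a in range(3):
            i = int(round((point_mm[a] - self.origin[a]) / self.voxel_size[a]))
            if not 0 <= i < self.shape[a]:
                raise ValueError(
                    f"point {point_mm} falls outside the grid on axis {a}")
            idx.append(i)
        return tuple(idx)


@dataclass
class VoxelImage:
    """3-D activity-concentration field (kBq/mL) on a :class:`GridSpec`.

    Values may be negative only downstream of noise addition or deconvolution.
    """

    grid: GridSpec
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    def total_activity_kbq(self) -> float:
        """Sum of voxel values times voxel volume (kBq)."""
        return float(self.values.sum() * self.grid.voxel_volume_ml())

    def copy_with(self, values: np.ndarray, **meta) -> "VoxelImage":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return VoxelImage(grid=self.grid, values=values, meta=new_meta)


@dataclass(frozen=True)
class BodySpec:
    """Elliptical-cylinder body compartment, centered on the phantom origin."""

    semi_axis_x: float = 150.0   # mm, lateral
    semi_axis_y: float = 115.0   # mm, anterior-posterior
    length: float = 180.0        # mm, inferior-superior interior length
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        inside_xy = ((x - cx) / self.semi_axis_x) ** 2 + ((y - cy) / self.semi_axis_y) ** 2 <= 1.0
        inside_z = np.abs(z - cz) <= self.length / 2.0
        return inside_xy & inside_z


@dataclass(frozen=True)
class PhantomSpec:
    """Activities and geometry of one filled NEMA-IEC phantom instance.

    ``background_activity`` (``B_in``) and ``tbr`` are the concentrations at
    scan initiation after :func:`decay_correct` has been applied to the
    prepared values; ``calibration_to_scan_minutes`` records the interval.
    """

    spheres: tuple[tuple[float, tuple[float, float, float]], ...] = ()
    background_activity: float = 2.0          # B_in, kBq/mL
    tbr: float = 5.0                          # T_in / B_in
    body: BodySpec = field(default_factory=BodySpec)
    background_volume_l: float = 9.7          # metadata only
    calibration_to_scan_minutes: float = 0.0

    def __post_init__(self):
        if not self.spheres:
            centers = default_sphere_centers()
            object.__setattr__(
                self, "spheres",
                tuple((d, c) for d, c in zip(DEFAULT_SPHERE_DIAMETERS_MM, centers)))
        if self.tbr <= 0:
            raise ValueError(f"tbr must be > 0, got {self.tbr}")
        if self.background_activity < 0:
            raise ValueError("background_activity must be >= 0")
        for d, _ in self.spheres:
            if d <= 0:
                raise ValueError(f"sphere diameter must be > 0, got {d}")
        for i, (di, ci) in enumerate(self.spheres):
            for j, (dj, cj) in enumerate(self.spheres):
                if j <= i:
                    continue
                dist = math.dist(ci, cj)
                if dist < (di + dj) / 2.0:
                    raise ValueError(
                        f"spheres {i} ({di} mm) and {j} ({dj} mm) overlap "
                        f"(center distance {dist:.1f} mm)")

    @property
    def sphere_activity(self) -> float:
        """T_in = TBR * B_in (kBq/mL)."""
        return self.tbr * self.background_activity

    def decayed(self, elapsed_min: float) -> "PhantomSpec":
        """Same phantom with activities decayed by ``elapsed_min`` minutes."""
        return PhantomSpec(
            spheres=self.spheres,
            background_activity=decay_correct(self.background_activity, elapsed_min),
            tbr=self.tbr,
            body=self.body,
            background_volume_l=self.background_volume_l,
            calibration_to_scan_minutes=elapsed_min,
        )


def _edge_fractions(centers_x, centers_y, centers_z, inside_fn, edge_mask,
                    voxel_size, supersample):
    """Inside-volume fraction for the voxels flagged in ``edge_mask``.

    Each flagged voxel is subdivided ``supersample**3`` times and the fraction
    of sub-centers satisfying ``inside_fn`` is returned (vectorized over the
    edge voxels, looping only over the supersample offsets).
    """
    ex, ey, ez = np.nonzero(edge_mask)
    if ex.size == 0:
        return ex, ey, ez, np.empty(0)
    x0 = centers_x[ex]
    y0 = centers_y[ey]
    z0 = centers_z[ez]
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    counts = np.zeros(ex.size)
    for ox in offs * voxel_size[0]:
        for oy in offs * voxel_size[1]:
            for oz in offs * voxel_size[2]:
                counts += inside_fn(x0 + ox, y0 + oy, z0 + oz)
    return ex, ey, ez, counts / s**3


def rasterize_phantom(spec: PhantomSpec, grid: GridSpec,
                      supersample: int = 4) -> VoxelImage:
    """Voxelize the phantom onto ``grid`` with partial-volume edge handling.

    Voxels fully inside a sphere get ``T_in``, voxels fully inside the body
    compartment get ``B_in``, voxels outside the body get 0.  Voxels cut by
    a boundary are subdivided ``supersample**3`` times and mixed accordingly.
    """
    if supersample < 1:
        raise ValueError(f"supersample must be >= 1, got {supersample}")
    cx = grid.axis_coords(0)
    cy = grid.axis_coords(1)
    cz = grid.axis_coords(2)
    lo = [c[0] - v / 2 for c, v in zip((cx, cy, cz), grid.voxel_size)]
    hi = [c[-1] + v / 2 for c, v in zip((cx, cy, cz), grid.voxel_size)]

    for k, (d, center) in enumerate(spec.spheres):
        r = d / 2.0
        for a in range(3):
            if center[a] - r < lo[a] or center[a] + r > hi[a]:
                raise ValueError(
                    f"sphere {k} (diameter {d} mm at {center}) extends outside "
                    f"the grid on axis {a}")

    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]
    half_diag = math.dist((0, 0, 0), tuple(v / 2 for v in grid.voxel_size))

    # body compartment: 0 outside, B_in inside, fractional at the wall
    body = spec.body
    values = np.where(body.contains(X, Y, Z), spec.background_activity, 0.0)
    bx, by, bz = body.center
    # distance proxy to the ellipse wall: exact for circles, conservative band
    # for the ellipse via the smaller semi-axis scaling
    norm = np.sqrt(((X - bx) / body.semi_axis_x) ** 2 + ((Y - by) / body.semi_axis_y) ** 2)
    a_min = min(body.semi_axis_x, body.semi_axis_y)
    wall_band = (np.abs(norm - 1.0) * a_min <= half_diag * 2.0)
    cap_band = np.abs(np.abs(Z - bz) - body.length / 2.0) <= half_diag
    edge = (wall_band & (np.abs(Z - bz) <= body.length / 2.0 + half_diag)) | \
           (cap_band & (norm <= 1.0 + half_diag * 2.0 / a_min))
    ex, ey, ez, frac = _edge_fractions(cx, cy, cz, body.contains, edge,
                                       grid.voxel_size, supersample)
    values[ex, ey, ez] = frac * spec.background_activity

    # spheres override the background locally
    t_in = spec.sphere_activity
    for d, center in spec.spheres:
        r = d / 2.0
        sx, sy, sz = center
        dist = np.sqrt((X - sx) ** 2 + (Y - sy) ** 2 + (Z - sz) ** 2)
        values[dist <= r - half_diag] = t_in
        sphere_edge = np.abs(dist - r) <= half_diag

        def inside_sphere(x, y, z, _c=center, _r=r):
            return (x - _c[0]) ** 2 + (y - _c[1]) ** 2 + (z - _c[2]) ** 2 <= _r**2

        ex, ey, ez, frac = _edge_fractions(cx, cy, cz, inside_sphere, sphere_edge,
                                           grid.voxel_size, supersample)
        values[ex, ey, ez] = frac * t_in + (1.0 - frac) * spec.background_activity

    return VoxelImage(grid=grid, values=values,
                      meta={"b_in": spec.background_activity,
                            "t_in": t_in, "tbr": spec.tbr,
                            "supersample": supersample})
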