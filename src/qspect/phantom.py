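"""Voxelized digital twin of the NEMA IEC body phantom.

The phantom is the standardized torso-shaped tank used for image-quality and
quantitation studies in emission tomography: six fillable spheres (10–37 mm
diameter) mounted on a ring in a warm background, with a low-density
cylindrical "lung" insert on the central axis.  This module turns a
parametric description (:class:`PhantomSpec`) into voxel volumes of activity
concentration (kBq/ml), linear attenuation at 140.5 keV (1/cm) and
volume-of-interest labels on a :class:`VoxelGrid`.

Conventions
-----------
* Voxel indices are 0-based; physical coordinates are voxel-center positions.
* All lengths in mm, volumes in ml, activity concentrations in kBq/ml.
* Volume arrays are indexed ``[x, y, z]``; the spheres lie on the central
  transverse (z = 0) plane.
* VOI labels: 0 none, 1–6 the spheres from smallest to largest, 7 the
  background VOI, 8 the lung insert.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._util import ConfigurationError, OutOfBoundsError, round_half_away

#: Narrow-beam linear attenuation coefficient of water at 140.5 keV (1/cm).
MU_WATER_140KEV = 0.154

#: Label codes for the VOI volume.
SPHERE_LABELS = (1, 2, 3, 4, 5, 6)
BACKGROUND_LABEL = 7
LUNG_LABEL = 8


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid covering the phantom.

    ``origin`` is the physical position (mm) of the center of voxel
    ``(0, 0, 0)``; by default the grid is centered on the phantom origin.
    """

    shape: tuple[int, int, int] = (144, 144, 64)
    voxel_size: float = 2.21
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape must be positive")
        if self.origin is None:
            o = tuple(-(n - 1) / 2.0 * self.voxel_size for n in self.shape)
            object.__setattr__(self, "origin", o)

    @property
    def v_voxel(self) -> float:
        """Voxel volume in ml: (voxel_size/10)^3."""
        return (self.voxel_size / 10.0) ** 3

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.voxel_size * np.arange(self.shape[axis])

    def meshgrid(self):
        return np.meshgrid(*(self.axis_coords(i) for i in range(3)), indexing="ij")

    def extent(self, axis: int) -> tuple[float, float]:
        """Outer physical extent (mm) of the grid along one axis."""
        lo = self.origin[axis] - self.voxel_size / 2.0
        hi = self.origin[axis] + (self.shape[axis] - 0.5) * self.voxel_size
        return lo, hi


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the phantom fill and geometry.

    Defaults are the measured study conditions: spheres at 85.1 kBq/ml over
    a 10.6 kBq/ml background (ratio ~8:1) with an unfilled lung insert.  The
    body outline is a 300 x 230 mm rounded rectangle (corner radius 77 mm);
    the interior length defaults to 120 mm so the default grid covers it.
    """

    sphere_diameters: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    sphere_ac: float = 85.1
    background_ac: float = 10.6
    lung_insert_diameter: float = 50.0
    lung_insert_mu_scale: float = 0.30
    body_width: float = 300.0
    body_height: float = 230.0
    body_corner_radius: float = 77.0
    body_length: float = 120.0
    sphere_ring_radius: float = 57.2
    background_voi_volume: float | None = 49.9
    background_voi_center: tuple[float, float, float] = (0.0, 70.0, 0.0)
    mu_water: float = MU_WATER_140KEV

    def __post_init__(self):
        d = self.sphere_diameters
        if any(x <= 0 for x in d):
            raise ValueError("sphere diameters must be positive")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("sphere diameters must be strictly increasing")
        if self.background_ac > 0 and d and self.sphere_ac / self.background_ac <= 1:
            raise ValueError("hot-sphere study requires sphere_ac > background_ac")
        if self.body_corner_radius * 2 > min(self.body_width, self.body_height):
            raise ValueError("corner radius too large for body outline")

    @property
    def sphere_centers(self) -> list[tuple[float, float, float]]:
        """Sphere centers (mm): coplanar on the mounting ring at 60° spacing.

        Angles are assigned so the two smallest spheres flank the background
        VOI (placed at +y) and the largest sits opposite it.
        """
        order = [60.0, 120.0, 0.0, 180.0, 300.0, 240.0]
        n = len(self.sphere_diameters)
        step = 360.0 / n if n else 0.0
        angles = order if n == 6 else [i * step for i in range(n)]
        r = self.sphere_ring_radius
        return [
            (r * math.cos(math.radians(a)), r * math.sin(math.radians(a)), 0.0)
            for a in angles[:n]
        ]


@dataclass
class PhantomRealization:
    """Voxelized phantom: activity (kBq/ml), mu (1/cm), VOI labels."""

    activity: np.ndarray
    mu: np.ndarray
    voi_labels: np.ndarray
    grid: VoxelGrid
    spec: PhantomSpec

    @property
    def total_activity_mbq(self) -> float:
        """Total activity in MBq (sum of kBq/ml over voxels times V_voxel)."""
        return float(self.activity.sum()) * self.grid.v_voxel * 1e-3


def sphere_volume(diameter: float) -> float:
    """Volume (ml) of a sphere of the given diameter (mm): pi/6 * (d/10)^3."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return math.pi / 6.0 * (diameter / 10.0) ** 3


def sphere_diameter_from_volume(volume_ml: float) -> float:
    """Inverse of :func:`sphere_volume` (mm from ml)."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return 10.0 * (6.0 * volume_ml / math.pi) ** (1.0 / 3.0)


def _sphere_mask(
    center: tuple[float, float, float], diameter: float, grid: VoxelGrid
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere."""
    r = diameter / 2.0
    coords = [grid.axis_coords(i) - center[i] for i in range(3)]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    return d2 <= r * r


def voxelize_sphere(
    center: tuple[float, float, float], diameter: float, grid: VoxelGrid
) -> np.ndarray:
    """Voxel indices (n, 3 int array) inside a sphere, center-in-sphere rule.

    A voxel belongs to the sphere iff its geometric center is within
    ``diameter/2`` of ``center``.  Raises :class:`OutOfBoundsError` if the
    sphere extends beyond the physical grid extent.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r = diameter / 2.0
    for ax in range(3):
        lo, hi = grid.extent(ax)
        if center[ax] - r < lo or center[ax] + r > hi:
            raise OutOfBoundsError(
                f"sphere (d={diameter} mm at {center}) extends beyond grid axis {ax}"
            )
    return np.argwhere(_sphere_mask(center, diameter, grid))


def _body_mask_2d(spec: PhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rounded-rectangle cross-section: core rectangle dilated by the corner radius."""
    rc = spec.body_corner_radius
    hx = spec.body_width / 2.0 - rc
    hy = spec.body_height / 2.0 - rc
    dx = np.maximum(np.abs(x) - hx, 0.0)
    dy = np.maximum(np.abs(y) - hy, 0.0)
    return dx * dx + dy * dy <= rc * rc


def build_phantom(spec: PhantomSpec, grid: VoxelGrid) -> PhantomRealization:
    """Voxelize a phantom spec onto a grid.

    Activity is ``sphere_ac`` inside spheres, ``background_ac`` in the body
    outside spheres and lung, and zero outside the body and inside the lung
    insert (which is never filled).  Attenuation is water inside the body and
    a scaled-down value inside the lung.
    """
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    body2d = _body_mask_2d(spec, xs[:, None], ys[None, :])
    inz = np.abs(zs) <= spec.body_length / 2.0
    if not inz.any() or not body2d.any():
        raise ConfigurationError("grid does not cover the phantom body")
    body = body2d[:, :, None] & inz[None, None, :]

    lung = np.zeros(grid.shape, dtype=bool)
    if spec.lung_insert_diameter > 0:
        rl = spec.lung_insert_diameter / 2.0
        lung2d = xs[:, None] ** 2 + ys[None, :] ** 2 <= rl * rl
        lung = lung2d[:, :, None] & inz[None, None, :]

    labels = np.zeros(grid.shape, dtype=np.int16)
    sphere_mask = np.zeros(grid.shape, dtype=bool)
    for i, (d, c) in enumerate(zip(spec.sphere_diameters, spec.sphere_centers)):
        m = _sphere_mask(c, d, grid)
        if not (m <= body).all():
            raise ConfigurationError(f"sphere {i + 1} (d={d} mm) not inside body")
        if (m & lung).any() or (m & sphere_mask).any():
            raise ConfigurationError(f"sphere {i + 1} overlaps another structure")
        labels[m] = SPHERE_LABELS[i]
        sphere_mask |= m

    if spec.background_voi_volume is not None:
        d_bg = sphere_diameter_from_volume(spec.background_voi_volume)
        m_bg = _sphere_mask(spec.background_voi_center, d_bg, grid)
        if not (m_bg <= body).all():
            raise ConfigurationError("background VOI not inside body")
        if (m_bg & (sphere_mask | lung)).any():
            raise ConfigurationError("background VOI overlaps spheres or lung insert")
        labels[m_bg] = BACKGROUND_LABEL
    labels[lung] = LUNG_LABEL

    activity = np.zeros(grid.shape, dtype=np.float64)
    activity[body & ~lung] = spec.background_ac
    activity[sphere_mask] = spec.sphere_ac

    mu = np.zeros(grid.shape, dtype=np.float64)
    mu[body] = spec.mu_water
    mu[lung] = spec.mu_water * spec.lung_insert_mu_scale

    return PhantomRealization(activity=activity, mu=mu, voi_labels=labels, grid=grid, spec=spec)


# ---------------------------------------------------------------------------
# I/O

def load_spec(path: str | Path) -> PhantomSpec:
    """Read a :class:`PhantomSpec` from a YAML mapping (missing keys default)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown phantom keys: {sorted(unknown)}")
    for key in ("sphere_diameters", "background_voi_center"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PhantomSpec(**data)


def save_nifti(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as NIfTI with the grid's voxel size and origin in the affine."""
    import nibabel as nib

    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def save_raw(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a volume as raw float32 with a JSON sidecar describing the grid."""
    path = Path(path)
    np.asarray(volume, dtype=np.float32).tofile(path)
    sidecar = {
        "shape": list(grid.shape),
        "voxel_size_mm": grid.voxel_size,
        "origin_mm": list(grid.origin),
        "dtype": "float32",
        "order": "C",
        "axes": "xyz",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def report_volume(diameter: float) -> float:
    """Sphere volume rounded half-away-from-zero to 1 decimal, as reported."""
    return round_half_away(sphere_volume(diameter), 1)
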