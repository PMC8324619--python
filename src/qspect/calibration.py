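"""Camera calibration: planar sensitivity, quantitative factor, object SCF.

Quantitation rests on three constants: the planar system sensitivity S
(cps/MBq, mean of the two detector heads), the effective scan time T (s)
and the voxel volume V_voxel (ml).  Reconstructed counts convert to
activity concentration through the quantitative factor

    QF = 1 / (S * T * V_voxel)    [MBq/cnt/ml].

The object-specific scatter weighting factor is determined the way a
camera physicist would: acquire a single sphere of known activity in
non-radioactive water, reconstruct at each candidate SCF, and pick the
one whose reconstructed total sphere activity matches the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._util import round_half_away
from .phantom import (
    PhantomSpec,
    PhantomRealization,
    VoxelGrid,
    build_phantom,
    _sphere_mask,
)
from .acquisition import ProjectionSet
from .recon import ReconParams, ScatterParams, counts_to_ac, osem


@dataclass(frozen=True)
class CalibrationConstants:
    """S (per head and system mean), T, V_voxel and the derived QF."""

    s_det1: float
    s_det2: float
    t: float = 1200.0
    v_voxel: float = 0.01079

    def __post_init__(self):
        if min(self.s_det1, self.s_det2, self.t, self.v_voxel) <= 0:
            raise ValueError("all calibration constants must be positive")

    @property
    def s_system(self) -> float:
        """Mean head sensitivity, reported to 1 decimal (half away from zero)."""
        return mean_sensitivity(self.s_det1, self.s_det2)

    @property
    def qf(self) -> float:
        return compute_qf(self)


def planar_sensitivity(counts: float, duration_s: float, activity_mbq: float) -> float:
    """Planar sensitivity in cps/MBq: counts / (duration * activity)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if activity_mbq <= 0:
        raise ValueError("activity must be positive")
    if counts < 0:
        raise ValueError("counts must be non-negative")
    return counts / (duration_s * activity_mbq)


def mean_sensitivity(s1: float, s2: float) -> float:
    """System sensitivity: arithmetic head mean, 1 decimal, half away from zero."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sensitivities must be positive")
    return round_half_away((s1 + s2) / 2.0, 1)


def compute_qf(c: CalibrationConstants) -> float:
    """Quantitative factor QF = 1/(S_system * T * V_voxel) in MBq/cnt/ml."""
    return 1.0 / (c.s_system * c.t * c.v_voxel)


# ---------------------------------------------------------------------------
# Object-specific SCF determination


def make_calibration_phantom(
    grid: VoxelGrid,
    *,
    sphere_diameter: float = 37.0,
    sphere_ac: float = 100.0,
    body_width: float = 200.0,
    body_height: float = 200.0,
    body_length: float | None = None,
) -> PhantomRealization:
    """Hot sphere in cold water: the SCF-calibration geometry.

    A single known-activity sphere centered in a water-filled tank with no
    background activity and no lung insert.
    """
    if body_length is None:
        body_length = grid.shape[2] * grid.voxel_size * 0.9
    corner = min(body_width, body_height) / 2.0
    spec = PhantomSpec(
        sphere_diameters=(sphere_diameter,),
        sphere_ac=sphere_ac,
        background_ac=0.0,
        lung_insert_diameter=0.0,
        body_width=body_width,
        body_height=body_height,
        body_corner_radius=corner,
        body_length=body_length,
        sphere_ring_radius=0.0,
        background_voi_volume=None,
    )
    return build_phantom(spec, grid)


def calibrate_scf(
    calib_acq: ProjectionSet,
    mu: np.ndarray,
    true_activity_mbq: float,
    sphere_center: tuple[float, float, float],
    sphere_diameter: float,
    recon_params: ReconParams,
    scf_grid,
    s_system: float | None = None,
    *,
    voi_dilation: float = 2.0,
    return_curve: bool = False,
):
    """Grid-search the SCF that best recovers a known sphere activity.

    Reconstructs the calibration acquisition at each candidate SCF and
    returns the one minimizing |reconstructed total sphere activity - true
    activity|; ties break toward the smaller SCF.  The measurement VOI is
    the known sphere dilated by ``voi_dilation`` in diameter to capture
    resolution spill-out (the background is inactive, so the enlarged VOI
    adds no true counts).
    """
    scf_grid = np.asarray(list(scf_grid), dtype=float)
    if scf_grid.size == 0:
        raise ValueError("SCF grid must be non-empty")
    if np.any(np.diff(scf_grid) <= 0):
        raise ValueError("SCF grid must be strictly increasing")
    if true_activity_mbq <= 0:
        raise ValueError("true activity must be positive")
    grid = calib_acq.grid
    if s_system is None:
        s_system = calib_acq.physics.sensitivity
    # measurement VOI may clip at the grid edge: the background is inactive
    voi = _sphere_mask(sphere_center, sphere_diameter * voi_dilation, grid)
    qf = 1.0 / (s_system * calib_acq.protocol.total_time * grid.v_voxel)

    recovered = np.empty_like(scf_grid)
    for i, scf in enumerate(scf_grid):
        params = replace(recon_params, scatter=ScatterParams(scf=float(scf)))
        vol = counts_to_ac(osem(calib_acq, mu, params), qf)
        recovered[i] = vol.values[voi].sum() * grid.v_voxel * 1e-3  # kBq/ml -> MBq
    err = np.abs(recovered - true_activity_mbq)
    best = float(scf_grid[int(np.argmin(err))])  # argmin takes first = smaller SCF
    if return_curve:
        return best, scf_grid, recovered
    return best
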