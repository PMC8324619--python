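"""VOI statistics and image metrics: recovery coefficient, SNR, noise.

Per-VOI statistics are taken over every voxel carrying the VOI label
(population standard deviation, divisor n — the VOIs are exhaustively
enumerated, not sampled).  The three study metrics are

    HSRC = AC_rec.sphere / AC_real.sphere        (hot-spot recovery)
    SNR  = (AC_rec.sphere - AC_rec.BG) / SD_BG   (contrast-to-noise)
    N[%] = SD_BG / AC_rec.BG * 100               (background noise)

with AC in kBq/ml throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_away
from .phantom import BACKGROUND_LABEL, SPHERE_LABELS
from .recon import ReconVolume


@dataclass(frozen=True)
class VOIStats:
    """Mean, population SD and voxel count of one labeled VOI."""

    voi_id: int
    mean_ac: float
    sd: float
    n_voxels: int


@dataclass
class MetricsRecord:
    """All metrics of one reconstruction protocol, per sphere and background."""

    protocol_id: str
    sphere_hsrc: dict[int, float]
    sphere_snr: dict[int, float]
    sphere_delta_ac: dict[int, float]  # AC_rec - AC_real, kBq/ml
    sphere_mean_ac: dict[int, float]
    background_mean_ac: float
    background_sd: float
    noise_pct: float
    meta: dict = field(default_factory=dict)


def voi_stats(vol, labels: np.ndarray, voi_id: int) -> VOIStats:
    """Statistics of a labeled VOI on a reconstructed (kBq/ml) volume."""
    values = vol.values if isinstance(vol, ReconVolume) else np.asarray(vol)
    mask = np.asarray(labels) == voi_id
    n = int(mask.sum())
    if n == 0:
        raise KeyError(f"VOI label {voi_id} not present")
    v = values[mask]
    return VOIStats(voi_id=voi_id, mean_ac=float(v.mean()), sd=float(v.std(ddof=0)), n_voxels=n)


def hsrc(ac_rec_sphere: float, ac_real_sphere: float) -> float:
    """Hot-spot recovery coefficient: reconstructed over true concentration."""
    if ac_real_sphere <= 0:
        raise ValueError("true activity concentration must be positive")
    return ac_rec_sphere / ac_real_sphere


def snr(mean_sphere: float, mean_bg: float, sd_bg: float) -> float:
    """Signal-to-noise ratio: (sphere - background) / background SD."""
    if sd_bg <= 0:
        raise ZeroDivisionError("background SD must be positive for SNR")
    return (mean_sphere - mean_bg) / sd_bg


def noise_pct(sd_bg: float, mean_bg: float) -> float:
    """Background noise in percent: 100 * SD / mean."""
    if mean_bg <= 0:
        raise ValueError("background mean must be positive")
    return 100.0 * sd_bg / mean_bg


def percent_deviation(delta_ac: float, ac_real: float, ndigits: int = 1) -> float:
    """Deviation from truth as a percentage, rounded for reporting."""
    if ac_real <= 0:
        raise ValueError("true activity concentration must be positive")
    return round_half_away(100.0 * delta_ac / ac_real, ndigits)


def metrics_for_volume(
    ac_vol,
    labels: np.ndarray,
    ac_real_sphere: float,
    protocol_id: str = "",
    sphere_labels=SPHERE_LABELS,
    background_label: int = BACKGROUND_LABEL,
) -> MetricsRecord:
    """Evaluate HSRC/SNR per sphere and background noise for one volume."""
    if isinstance(ac_vol, ReconVolume) and ac_vol.units != "kBq/ml":
        raise ValueError("metrics require a volume in kBq/ml")
    bg = voi_stats(ac_vol, labels, background_label)
    out = MetricsRecord(
        protocol_id=protocol_id,
        sphere_hsrc={},
        sphere_snr={},
        sphere_delta_ac={},
        sphere_mean_ac={},
        background_mean_ac=bg.mean_ac,
        background_sd=bg.sd,
        noise_pct=noise_pct(bg.sd, bg.mean_ac),
    )
    for lab in sphere_labels:
        st = voi_stats(ac_vol, labels, lab)
        out.sphere_mean_ac[lab] = st.mean_ac
        out.sphere_hsrc[lab] = hsrc(st.mean_ac, ac_real_sphere)
        out.sphere_snr[lab] = snr(st.mean_ac, bg.mean_ac, bg.sd)
        out.sphere_delta_ac[lab] = st.mean_ac - ac_real_sphere
    return out
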