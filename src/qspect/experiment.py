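"""Orchestration of the full protocol-optimization study.

Expands the 16-cell protocol grid (2 acquisition protocols x 4 iteration
sets x 2 scatter weighting factors, with the Butterworth postfilter applied
exactly to the 2i/10s "diagnostic" cells), simulates one acquisition per
protocol, reconstructs every cell from the stored energy windows, converts
counts to activity concentration via the quantitative factor, and evaluates
HSRC, SNR and noise per VOI.  Effect summaries compare each single-parameter
variation against the clinical diagnostic reference (clinical acquisition,
2i/10s, SCF 1.10, postfiltered) with voxel-paired t tests, Holm-corrected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigurationError
from .acquisition import (
    CLINICAL_PROTOCOL,
    NEMA_PROTOCOL,
    AcquisitionProtocol,
    PhysicsModel,
    simulate_acquisition,
)
from .analysis import MetricsRecord, metrics_for_volume, voi_stats
from .calibration import CalibrationConstants
from .phantom import (
    BACKGROUND_LABEL,
    SPHERE_LABELS,
    PhantomSpec,
    VoxelGrid,
    build_phantom,
)
from .recon import ReconParams, ScatterParams, butterworth3d, counts_to_ac, osem
from .stats import holm_adjust

log = logging.getLogger("qspect")

#: The four examined iteration sets (iterations, subsets).
ITERATION_SETS: tuple[tuple[int, int], ...] = ((2, 10), (4, 10), (5, 15), (24, 10))
#: The two examined scatter weighting factors.
SCF_VALUES: tuple[float, float] = (0.41, 1.10)
#: Postfilter of the diagnostic reconstructions (cutoff cycles/cm, power).
DIAGNOSTIC_POSTFILTER: tuple[float, int] = (0.5, 10)
#: Iteration set that receives the postfilter (diagnostic cells).
DIAGNOSTIC_SET: tuple[int, int] = (2, 10)


@dataclass(frozen=True)
class ProtocolCell:
    """One cell of the study grid."""

    acquisition: str  # "clinical" or "nema"
    iterations: int
    subsets: int
    scf: float
    postfilter: bool

    @property
    def cell_id(self) -> str:
        pf = "pf" if self.postfilter else "nopf"
        return f"{self.acquisition}_{self.iterations}i{self.subsets}s_scf{self.scf:.2f}_{pf}"


def expand_grid(
    iteration_sets=ITERATION_SETS,
    scfs=SCF_VALUES,
    acquisitions=("clinical", "nema"),
    diagnostic_set=DIAGNOSTIC_SET,
) -> list[ProtocolCell]:
    """Exhaustive, duplicate-free expansion of the protocol grid.

    The postfilter rule is structural: a cell is postfiltered iff its
    iteration set is the diagnostic one (2i/10s), yielding 12 quantitative
    and 4 diagnostic cells in the default grid.
    """
    cells = [
        ProtocolCell(acq, it, sub, scf, postfilter=(it, sub) == tuple(diagnostic_set))
        for acq in acquisitions
        for (it, sub) in iteration_sets
        for scf in scfs
    ]
    if len({c.cell_id for c in cells}) != len(cells):
        raise ConfigurationError("duplicate cells in protocol grid")
    return cells


@dataclass
class StudyConfig:
    """Everything needed to run the study from a single seed."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    grid: VoxelGrid = field(default_factory=VoxelGrid)
    physics: PhysicsModel = field(default_factory=PhysicsModel)
    calibration: CalibrationConstants = field(
        default_factory=lambda: CalibrationConstants(s_det1=71.7, s_det2=72.8)
    )
    iteration_sets: tuple = ITERATION_SETS
    scfs: tuple = SCF_VALUES
    postfilter: tuple[float, int] = DIAGNOSTIC_POSTFILTER
    dtype: str = "float32"

    @classmethod
    def reduced(cls) -> "StudyConfig":
        """Desk-scale study: half-length grid and body (documented in docs)."""
        return cls(
            grid=VoxelGrid(shape=(144, 144, 32)),
            phantom=PhantomSpec(body_length=64.0),
        )


def load_study_config(path) -> StudyConfig:
    """Read a StudyConfig from YAML (nested mappings, missing keys default)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    if "phantom" in data:
        ph = dict(data["phantom"])
        if "sphere_diameters" in ph:
            ph["sphere_diameters"] = tuple(ph["sphere_diameters"])
        if "background_voi_center" in ph:
            ph["background_voi_center"] = tuple(ph["background_voi_center"])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "grid" in data:
        g = dict(data["grid"])
        if "shape" in g:
            g["shape"] = tuple(g["shape"])
        if "origin" in g and g["origin"] is not None:
            g["origin"] = tuple(g["origin"])
        kwargs["grid"] = VoxelGrid(**g)
    if "physics" in data:
        kwargs["physics"] = PhysicsModel(**data["physics"])
    if "calibration" in data:
        kwargs["calibration"] = CalibrationConstants(**data["calibration"])
    for key in ("iteration_sets", "scfs", "postfilter"):
        if key in data:
            kwargs[key] = tuple(tuple(x) if isinstance(x, list) else x for x in data[key]) if key == "iteration_sets" else tuple(data[key])
    if "dtype" in data:
        kwargs["dtype"] = data["dtype"]
    return StudyConfig(**kwargs)


@dataclass
class CellResult:
    """Metrics plus the VOI voxel values needed for paired statistics."""

    cell: ProtocolCell
    metrics: MetricsRecord | None
    voxels_largest_sphere: np.ndarray | None
    voxels_background: np.ndarray | None
    error: str | None = None


@dataclass
class StudyResult:
    cells: list[CellResult]
    metrics_df: pd.DataFrame
    config: StudyConfig
    seed: int

    @property
    def n_failed(self) -> int:
        return sum(1 for c in self.cells if c.error is not None)


def _protocol(name: str) -> AcquisitionProtocol:
    return {"clinical": CLINICAL_PROTOCOL, "nema": NEMA_PROTOCOL}[name]


def run_grid(config: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    """Run the full simulate -> reconstruct -> quantify -> analyze study.

    One noise realization is simulated per acquisition protocol and shared
    by all its reconstructions, matching the physical study (one scan, many
    reconstructions).  Fully deterministic given the seed.  A failing cell
    is recorded with its error and the run continues.
    """
    if config is None:
        config = StudyConfig()
    dtype = np.dtype(config.dtype)
    t0 = time.perf_counter()
    real = build_phantom(config.phantom, config.grid)
    log.info("phantom voxelized in %.1fs", time.perf_counter() - t0)

    cells = expand_grid(config.iteration_sets, config.scfs)
    acquisitions = {}
    ss = np.random.SeedSequence(seed)
    for name, child in zip(("clinical", "nema"), ss.spawn(2)):
        t0 = time.perf_counter()
        acq_seed = int(child.generate_state(1)[0] % (2**31))
        acquisitions[name] = simulate_acquisition(
            real, _protocol(name), config.physics, seed=acq_seed, dtype=dtype
        )
        log.info("acquisition %s simulated in %.1fs", name, time.perf_counter() - t0)

    qf = config.calibration.qf
    largest = SPHERE_LABELS[-1]
    results: list[CellResult] = []
    for cell in cells:
        t0 = time.perf_counter()
        try:
            params = ReconParams(
                iterations=cell.iterations,
                subsets=cell.subsets,
                scatter=ScatterParams(scf=cell.scf),
                postfilter=config.postfilter if cell.postfilter else None,
            )
            vol = osem(acquisitions[cell.acquisition], real.mu, params, dtype=dtype)
            ac = counts_to_ac(vol, qf)
            if cell.postfilter:
                ac.values = butterworth3d(
                    ac.values, config.postfilter[0], config.postfilter[1], config.grid.voxel_size
                )
            rec = metrics_for_volume(ac, real.voi_labels, config.phantom.sphere_ac, cell.cell_id)
            rec.meta = dataclasses.asdict(cell)
            results.append(
                CellResult(
                    cell=cell,
                    metrics=rec,
                    voxels_largest_sphere=ac.values[real.voi_labels == largest].copy(),
                    voxels_background=ac.values[real.voi_labels == BACKGROUND_LABEL].copy(),
                )
            )
            log.info("cell %s done in %.1fs", cell.cell_id, time.perf_counter() - t0)
        except Exception as exc:  # cell failure must not kill the study
            log.error("cell %s failed: %s", cell.cell_id, exc)
            results.append(CellResult(cell, None, None, None, error=str(exc)))

    return StudyResult(
        cells=results, metrics_df=_tidy(results, config), config=config, seed=seed
    )


def _tidy(results: list[CellResult], config: StudyConfig) -> pd.DataFrame:
    """One row per cell x VOI, in a stable order for byte-identical CSVs."""
    rows = []
    diam = dict(zip(SPHERE_LABELS, config.phantom.sphere_diameters))
    for res in results:
        c = res.cell
        base = {
            "cell_id": c.cell_id,
            "acquisition": c.acquisition,
            "iterations": c.iterations,
            "subsets": c.subsets,
            "total_updates": c.iterations * c.subsets,
            "scf": c.scf,
            "postfilter": c.postfilter,
            "failed": res.error is not None,
        }
        if res.metrics is None:
            rows.append({**base, "voi": "background"})
            continue
        m = res.metrics
        for lab in SPHERE_LABELS:
            rows.append(
                {
                    **base,
                    "voi": f"sphere_{diam[lab]:g}mm",
                    "diameter_mm": diam[lab],
                    "mean_ac_kbq_ml": m.sphere_mean_ac[lab],
                    "hsrc": m.sphere_hsrc[lab],
                    "snr": m.sphere_snr[lab],
                    "delta_ac_kbq_ml": m.sphere_delta_ac[lab],
                }
            )
        rows.append(
            {
                **base,
                "voi": "background",
                "mean_ac_kbq_ml": m.background_mean_ac,
                "sd_kbq_ml": m.background_sd,
                "noise_pct": m.noise_pct,
            }
        )
    return pd.DataFrame(rows)


REFERENCE_CELL = ProtocolCell("clinical", 2, 10, 1.10, postfilter=True)


def summarize_effects(result: StudyResult, reference: ProtocolCell = REFERENCE_CELL) -> pd.DataFrame:
    """Single-parameter effect table against the diagnostic reference cell.

    Each row changes exactly one parameter of the reference (SCF, iteration
    set, acquisition protocol) and reports the deltas in largest-sphere AC,
    HSRC and SNR and in background AC and noise, with voxel-paired t tests
    (Holm-corrected per metric family across rows).
    """
    by_cell = {r.cell: r for r in result.cells if r.error is None}
    if reference not in by_cell:
        raise KeyError(f"reference cell {reference.cell_id} missing or failed")
    ref = by_cell[reference]
    ac_real = result.config.phantom.sphere_ac
    largest = SPHERE_LABELS[-1]

    variations: list[tuple[str, ProtocolCell]] = []
    other_scf = [s for s in result.config.scfs if s != reference.scf]
    for s in other_scf:
        variations.append((f"SCF: {s:g}", replace(reference, scf=s)))
    for it, sub in result.config.iteration_sets:
        if (it, sub) == (reference.iterations, reference.subsets):
            continue
        variations.append(
            (
                f"Iteration set: {it}i/{sub}s",
                replace(reference, iterations=it, subsets=sub, postfilter=(it, sub) == DIAGNOSTIC_SET),
            )
        )
    other_acq = "nema" if reference.acquisition == "clinical" else "clinical"
    variations.append((f"Acquisition: {other_acq.upper()}", replace(reference, acquisition=other_acq)))

    from scipy import stats as sps

    rows = []
    for name, cell in variations:
        if cell not in by_cell:
            continue
        var = by_cell[cell]
        mr, mv = ref.metrics, var.metrics
        row = {
            "variation": name,
            "cell_id": cell.cell_id,
            "delta_ac_sphere": mv.sphere_mean_ac[largest] - mr.sphere_mean_ac[largest],
            "delta_hsrc": mv.sphere_hsrc[largest] - mr.sphere_hsrc[largest],
            "delta_snr": mv.sphere_snr[largest] - mr.sphere_snr[largest],
            "delta_ac_bg": mv.background_mean_ac - mr.background_mean_ac,
            "delta_noise_pct": mv.noise_pct - mr.noise_pct,
        }
        # voxel-paired contrasts (same acquisition only: voxels pair across
        # reconstructions of one scan; across scans use unpaired Welch)
        paired = cell.acquisition == reference.acquisition
        for key, a, b in (
            ("p_sphere", var.voxels_largest_sphere, ref.voxels_largest_sphere),
            ("p_bg", var.voxels_background, ref.voxels_background),
        ):
            if np.allclose(a, b):
                row[key] = 1.0
            elif paired:
                row[key] = float(sps.ttest_rel(a, b).pvalue)
            else:
                row[key] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("variation")
    for col in ("p_sphere", "p_bg"):
        table[f"{col}_holm"] = holm_adjust(table[col])
    return table


# ---------------------------------------------------------------------------
# Outputs


def write_outputs(result: StudyResult, outdir, *, plots: bool = False) -> dict:
    """Write metrics CSV, effect table, and a JSON run manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics_path = outdir / "metrics.csv"
    result.metrics_df.to_csv(metrics_path, index=False, float_format="%.6g")
    effects_path = outdir / "effects.csv"
    try:
        summarize_effects(result).to_csv(effects_path, float_format="%.6g")
    except KeyError:
        effects_path = None
    manifest = {
        "seed": result.seed,
        "n_cells": len(result.cells),
        "n_failed": result.n_failed,
        "grid": list(result.config.grid.shape),
        "voxel_size_mm": result.config.grid.voxel_size,
        "s_system_cps_per_mbq": result.config.calibration.s_system,
        "qf_mbq_per_cnt_ml": result.config.calibration.qf,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if plots:
        plot_hsrc_curves(result, outdir / "hsrc_curves.png")
    return manifest


def plot_hsrc_curves(result: StudyResult, path, normalize_to_fwhm: bool = True) -> None:
    """Recovery-vs-diameter curves per iteration set (clinical, SCF 1.10)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.metrics_df
    sel = df[(df.acquisition == "clinical") & (df.scf == SCF_VALUES[1]) & df.voi.str.startswith("sphere")]
    fwhm = result.config.physics.fwhm(100.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    for (it, sub), grp in sel.groupby(["iterations", "subsets"]):
        grp = grp.sort_values("diameter_mm")
        x = grp.diameter_mm / fwhm if normalize_to_fwhm else grp.diameter_mm
        ax.plot(x, grp.hsrc, marker="o", label=f"{it}i/{sub}s")
    ax.set_xlabel("sphere diameter / FWHM" if normalize_to_fwhm else "diameter (mm)")
    ax.set_ylabel("HSRC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
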