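# qspect

Simulation-based optimization of quantitative ⁹⁹ᵐTc SPECT/CT protocols on
the NEMA IEC body phantom.

Hybrid SPECT/CT can, like PET/CT, report tracer concentrations in
absolute units (kBq/ml) — if acquisition, reconstruction and calibration
are parametrized carefully. This package re-creates a complete
protocol-optimization study in software for physicists and method
developers: a voxelized NEMA IEC body phantom (six hot spheres of 10–37 mm
at 85.1 kBq/ml over a 10.6 kBq/ml background, cold lung insert) is imaged
by a simulated dual-head camera under two acquisition protocols
(60 proj × 20 s and 120 proj × 10 s over 360°, both 1200 s), reconstructed
with 2D OSEM under sixteen parametrizations, quantified, and compared.

The quantitative core, in the field's standard notation:

* **OSEM** with system model *y* = **A*x*** + *s*, where **A** contains
  attenuation (μ = 0.154 cm⁻¹ water at 140.5 keV) and a distance-dependent
  resolution model (FWHM = 3.8 + 0.036·d mm; 7.4 mm at 100 mm, LEHR), and
  iteration sets 2i/10s … 24i/10s (20–240 total updates);
* **Dual-energy-window scatter correction** *s* = *k*·(scatter-window
  counts), entered additively in the forward model, with
  *k* = SCF·W_sc/W_pk: the manufacturer default SCF 1.10 ↔ *k* = 0.470 and
  the object-specific SCF 0.41 ↔ *k* = 0.175 for the 140.5 keV ± 10% /
  120 keV ± 5% windows;
* **Quantitation** by QF = 1/(S·T·V_voxel) with planar system sensitivity
  S = 72.3 cps/MBq, scan time T = 1200 s and V_voxel = 0.01079 ml;
* **Metrics** per VOI: hot-spot recovery coefficient
  HSRC = AC_rec/AC_real, SNR = (AC_sphere − AC_bg)/SD_bg, noise
  N[%] = 100·SD_bg/AC_bg, compared across protocols with Friedman/Wilcoxon
  tests and Holm-corrected paired contrasts.

The acquisition simulator doubles as the ground-truth generator: its
scatter surrogate is constructed so that the object-specific weighting
factor (SCF = 0.41) is exactly recoverable, which turns calibration into a
testable parameter-recovery problem.

## Worked example

Run the sixteen-cell protocol grid at the desk-scale (half-length)
geometry and look at the best quantitative protocol and the effect table
against the clinical diagnostic reference:

```python
import qspect as q

result = q.run_grid(q.StudyConfig.reduced(), seed=1)
df = result.metrics_df
best = df[(df.cell_id == "clinical_24i10s_scf0.41_nopf") & (df.voi == "sphere_37mm")]
print(best[["hsrc", "snr", "delta_ac_kbq_ml"]].round(3).to_string(index=False))
effects = q.summarize_effects(result)
print(effects[["delta_ac_sphere", "delta_hsrc", "delta_snr", "delta_noise_pct"]].round(2).to_string())
```

prints (about five minutes):

```
 hsrc  snr  delta_ac_kbq_ml
0.883 4.52           -9.937
                        delta_ac_sphere  delta_hsrc  delta_snr  delta_noise_pct
variation
SCF: 0.41                         16.04        0.19      -7.72            -5.01
Iteration set: 4i/10s              8.57        0.10     -28.78            45.54
Iteration set: 5i/15s             12.25        0.14     -34.40            87.16
Iteration set: 24i/10s            13.81        0.16     -40.12           193.82
Acquisition: NEMA                 -1.99       -0.02      -9.49             0.77
```

Reading the numbers: the best quantitative cell (24 iterations /
10 subsets with the object-specific SCF 0.41, no postfilter) recovers the
largest sphere to HSRC = 0.883, still ≈ 10 kBq/ml below the known
85.1 kBq/ml — the partial-volume residual. In the effect table every row
changes one parameter of the diagnostic reference (clinical, 2i/10s,
SCF 1.10, Butterworth-postfiltered): switching to SCF 0.41 raises the
recovered concentration by 16 kBq/ml, adding iterations raises recovery
but costs SNR and background noise, and the acquisition protocol barely
matters — the study's central findings.

The same study runs from a shell:

```sh
qspect run --reduced --seed 1 --out results/ --plots
```

writing `metrics.csv` (one row per cell × VOI), `effects.csv`, a JSON run
manifest and optional recovery-curve plots.

## Layout

```
src/qspect/
  phantom.py       parametric NEMA IEC phantom -> voxel volumes
  acquisition.py   protocols, physics model, sinogram simulation
  projector.py     attenuated rotation projector with exact adjoint
  recon.py         OSEM, DEW scatter, Butterworth, counts -> kBq/ml
  calibration.py   planar sensitivity, QF, object-specific SCF search
  analysis.py      VOI statistics, HSRC / SNR / noise
  stats.py         Shapiro-Wilk/Levene, Friedman/Wilcoxon, Holm contrasts
  experiment.py    16-cell grid orchestration and effect tables
  cli.py           `qspect run`
docs/methods.md    models, defaults, numerical choices, limitations
```
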