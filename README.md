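# linescan

Simulation and analysis toolkit for **gradient-echo line-scanning
fMRI** — the acquisition that trades in-plane coverage for a single
line through cortex sampled at very high spatiotemporal resolution
(0.39 × 3.0 × 3.0 mm³ voxels, TR = 250 ms), so that BOLD time courses
can be resolved across cortical depth in, for example, the hand knob of
human primary motor cortex.

The package covers both halves of such an experiment:

* **Physics / simulation** — Shinnar–Le Roux (SLR) saturation-pulse
  design, Bloch simulation of the four-slab saturation scheme that
  carves the line out of the slice, line-profile quality metrics (FWHM
  and signal leakage), and a fully labeled synthetic generator for raw
  multi-coil multi-echo line-scan sessions (complex k-space, coil ×
  echo × readout × TR) with block-design laminar BOLD, motion events
  and thermal noise.
* **Analysis** — 1D/2D FFT reconstruction, root-sum-of-squares and
  SENSE-1 coil combination, T2*-matched multi-echo weighting
  (`w(TE) = TE·e^(−TE/T2*)`, target T2\* = 25 ms), integer-voxel
  alignment with motion rejection (brightest-voxel excursion > 3
  voxels), gray-matter segmentation from magnitude (bright pial CSF
  voxel) and unwrapped phase (GM/WM phase step), 24-bin cortical-depth
  resampling with layer assignment (surface/CSF, L2/3, L5, L6),
  percent-signal-change time courses, threshold timings
  (T10/T50/T90/T95) and constrained gamma-variate HRF onset fits

      h(t) = A (t−T0)^(a−1) b^a / Γ(a) · e^(−(t−T0) b),  t ≥ T0,

  with box constraints 0 < A < 40, 0.1 < T0 < 3.5, 2 < a < 4,
  0.5 < b < 3.

Every stage is testable without any external data: the generator knows
its own ground truth (borders, shifts, noiseless percent-change curves,
per-depth HRF parameters), and the pipeline is validated by recovering
it. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full synthetic pipeline (simulate → reconstruct → align/QC →
segment → laminar analysis) on a reduced 64 mm readout:

```python
from linescan import PipelineConfig, run_pipeline

cfg = PipelineConfig(fov_mm=64.0, n_coils=4, seed=7, noise_sd=0.02)
result = run_pipeline(cfg, outdir="demo_run")

print(f"alignment shift: {result.alignment.shift} voxels, rejected: {result.rejected}")
seg = result.segment
print(f"gray matter: voxels {seg.csf_border_index}..{seg.wm_border_index - 1} "
      f"({seg.n_gm_voxels} voxels, border method: {seg.method})")
for layer in ("Surface/CSF", "L2/3", "L5", "L6"):
    tm = result.layer_timings[layer]
    print(f"{layer:12s} T50 = {tm.t50:5.2f} s   T95 = {tm.t95:5.2f} s   "
          f"peak PSC = {result.laminar.layer_average(layer).max():4.2f} %")
```

prints

```
alignment shift: 0 voxels, rejected: False
gray matter: voxels 78..85 (8 voxels, border method: phase_jump)
Surface/CSF  T50 =  5.50 s   T95 = 11.75 s   peak PSC = 2.94 %
L2/3         T50 =  4.25 s   T95 =  9.50 s   peak PSC = 2.38 %
L5           T50 =  3.25 s   T95 =  8.75 s   peak PSC = 1.69 %
L6           T50 =  3.25 s   T95 =  9.25 s   peak PSC = 0.95 %
```

The run was not rejected for motion, the 3.3 mm cortical patch was
segmented to its true 8 voxels from the structural phase step, the
response amplitude falls from ~3 % near the pial surface toward the
white matter, and the deeper layers reach 95 % of their plateau several
seconds before the slowly rising superficial gray matter — the laminar
timing signature the method is designed to resolve.

Onset fitting recovers the generating parameters from noisy responses:

```python
import numpy as np
from linescan.laminar import fit_hrf
from linescan.synth import gamma_hrf

t = np.arange(0, 20, 0.25)
truth = gamma_hrf(t, amplitude=5.0, t0=1.0, a=3.0, b=1.0)
noisy = truth + np.random.default_rng(0).normal(scale=0.2 * truth.max(), size=t.size)
fit = fit_hrf(noisy, dt=0.25)
print(f"fitted onset T0 = {fit.t0:.2f} s (truth 1.00 s), R2 = {fit.r2:.3f}")
# fitted onset T0 = 1.00 s (truth 1.00 s), R2 = 0.643
```

A command-line interface mirrors the library
(`linescan profile | simulate | recon | qc | segment | analyze | run`);
for instance the saturation-scheme report:

```sh
$ linescan profile --scheme slr --gap 3.0
fwhm_mm=2.476
leakage_fraction=0.9686
...
```

The simulated linewidth of the idealized steady-state model is narrower
than scanner measurements, and area-ratio leakage on a flat object is
dominated by the T1-regrowth floor of the saturated bands —
`docs/methods.md` discusses both limits.

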