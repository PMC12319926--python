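# Methods

`linescan` simulates and analyzes gradient-echo line-scanning fMRI: an
acquisition that gives up in-plane coverage to record a single
0.39 mm-resolved line through cortex every 250 ms, so that BOLD time
courses can be resolved by cortical depth. The package has two halves
that meet in the middle: a physics side (saturation-pulse design and
line-profile simulation, plus a fully labeled synthetic session
generator) and an analysis side (reconstruction, alignment and motion
QC, gray-matter segmentation, depth-resolved percent-signal-change and
hemodynamic-onset analysis). This note records the models, the defaults
and the reasoning behind the design choices that were genuinely open.

## Saturation scheme and line profile

The line is selected by nulling longitudinal magnetization everywhere
except a narrow central gap, using four frequency-selective saturation
pulses per TR: two sharp inner pulses (256 samples, maximum phase, flip
110°, time-bandwidth 19, 7.8 ms, mapped onto 15 mm slabs; passband /
stopband ripple 0.01 % / 0.1 %) flanking a nominal 3 mm gap, and two
broad outer pulses (flip 120°, time-bandwidth 2.7, 3.8 ms, 120 mm
slabs) covering the rest of the slice, each nominally abutting an inner
slab.

Pulses are designed with the Shinnar–Le Roux transform implemented in
the package: the beta polynomial is an equiripple FIR filter
(Parks–McClellan); for maximum-phase pulses a linear-phase prototype of
the squared response is factorized by the cepstral method; the alpha
polynomial is the minimum-phase spectral complement; and the inverse
SLR recursion returns the RF samples. Two numerical caveats are
inherent to this standard construction and are asserted at their true
level by the tests rather than idealized away:

* the squared-response prototype must be lifted by its stopband ripple
  before the square root, which floors the achievable passband ripple
  of the longitudinal response near `max(d1, d2/2)` regardless of the
  requested `d1`;
* a time-domain Bloch integrator run on the piecewise-constant sampled
  envelope differs from the design response by a few 1e-3 (hard-pulse
  discretization); the design response itself is evaluated with the
  Cayley–Klein recursion.

The composed line profile uses a steady-state model of the sequence:
per TR the saturation train (product `s(x)` of the four regions' Mz
responses, each mapped from frequency to mm through its slab thickness
at constant gradient) immediately precedes the excitation
(`alpha = 15°`), and mono-exponential T1 recovery (default T1 = 1.9 s,
typical gray matter at 7 T) fills the remaining `TR − τ`, with `τ` the
summed pulse durations. The acquired profile is
`|sin α · s · M(s)| / M(1)` with
`M(s) = (1−E1)/(1−cos α · s · E1)`, normalized to the unsaturated
steady state. FWHM is measured on the profile bin-averaged to the
0.39 mm acquisition grid, with half-maximum crossings located by linear
interpolation nearest the peak; leakage is the magnitude sum outside a
band divided by the total.

Two hard limits of this idealized model are worth stating plainly,
because they bound what the simulation can claim about a scanner:

* **Linewidth.** Under per-TR steady state the half-maximum crossing
  sits where `s·M(s)` is half the center value, which the hyperbolic
  `M(s)` places only ~10 % into the saturation transition; with the
  printed pulse parameters the simulated FWHM is ≈ 2.5 mm for a 3 mm
  gap. Measured in-vivo linewidths are wider because B1+ deviations,
  vendor slab-gradient calibration and the imaging point-spread
  function broaden the effective transition; none of these scanner
  non-idealities is modeled here.
* **Leakage floor.** T1 regrowth over `TR − τ ≈ 227 ms` leaves the
  saturated bands a steady-state residual of a few percent of the line
  amplitude. Integrated over a flat 224 mm object against a ~4 mm
  line, an area-ratio leakage is therefore dominated by the residual
  floor (tens of percent) for any plausible T1; single-digit leakage
  percentages are only obtainable on masked or windowed profiles.

The outer pulses deserve a note: a time-bandwidth of 2.7 spread over
120 mm implies transition zones of roughly 46 mm per edge, so wherever
the outer slabs are placed, a flat object keeps broad partially
saturated shoulders. The default scheme keeps the nominal adjacency
arrangement (outer slab edge at the inner slab's outer edge).

## Synthetic sessions

The generator produces raw k-space (coil × echo × readout × TR) for a
1D tissue profile: CSF (proton density 1.0, T2* 45 ms), gray matter
(0.8, 25 ms, default thickness 3.3 mm ≈ 8.5 voxels at 0.39 mm), white
matter (0.65, 18 ms), zero background. The CSF voxel at the pial
surface is brightened by 20 % (partial-volume/vein brightening), which
is the feature the CSF-border search keys on; the white matter phase
differs from gray by 0.3 rad (susceptibility-driven phase step at
7 T), which is what the WM-border search keys on. Phase is otherwise
compartment-wise constant by default (an optional linear background
ramp exists as a stressor).

The functional modulation is a block design (20 s tapping / 20 s rest,
8 trials, 20 s lead-in baseline, TR 250 ms) scaled by a depth-dependent
gamma-variate response

    h(t) = A (t−T0)^(a−1) b^a / Γ(a) · exp(−(t−T0) b),  t ≥ T0.

Two response constructions are available. `"convolved"` (default)
convolves the stimulus boxcar with h as a unit-area kernel, giving
sustained responses that plateau at the amplitude parameter —
appropriate for plateau/timing analyses. `"direct"` places a
peak-normalized copy of h at each trial onset, so the trial-averaged
response is h itself — appropriate for onset-recovery studies, where
the fitted model and the generating model coincide. The default depth
profile has amplitude falling from 3 % at the surface to 0.5 % at the
WM border, onsets of 1.1 / 0.7 / 1.0 / 2.3 s at the surface / L2/3 /
L5 / L6 layer centers, and a rate parameter rising with depth
(0.55 → 2.5 s⁻¹) so deep responses plateau early while superficial
ones are still rising at stimulus offset.

Coil sensitivities are smooth Gaussian lobes on a constant floor with
coil-specific phase ramps (root-sum-of-squares strictly positive, ratio
of extremes > 0.2 over tissue). Motion is modeled as integer-voxel
displacements that persist from a given TR onward. Thermal noise is
i.i.d. complex Gaussian per k-space sample; the default
`noise_sd = 0.02` yields a raw voxel tSNR of ~60 in gray matter on the
reduced test grid — deliberately comfortable, since the line-scan voxel
is large. Physiological noise, drift and sub-voxel motion are *not*
modeled; green pipeline tests therefore demonstrate algorithmic
correctness under the stated noise model, not robustness to structured
in-vivo noise.

The structural pair (FLASH with and without saturation) is generated
in 2D by extending the line profile along phase-encode with a smooth
envelope whose center row equals the 1D phantom exactly.

## Reconstruction

Centered, unitary FFTs throughout (fftshift convention, fixed for bit
reproducibility). The functional path is 1D inverse FFT →
root-sum-of-squares over coils → echo combination with
`w(TE) = TE·exp(−TE/T2*)` at target T2* = 25 ms, normalized to unit
sum (percent signal change downstream is scale-invariant, so the
normalization only fixes units). The structural path keeps complex
data: SENSE-1 (conjugate-weighted least squares per voxel) preserves
the object phase for segmentation. For synthetic sessions the
pipeline uses the generator's true coil sensitivities; for data
without known maps a smoothed-ratio estimate (coil image / RSS,
Gaussian-smoothed) is provided — its phase retains a high-passed copy
of the object phase near sharp phase features, a known limitation of
ratio calibration, which is why known maps are preferred whenever they
exist. Phase lines are unwrapped by accumulating wrapped differences.

## Alignment and motion QC

Each run's temporal-mean line is aligned to the collapsed saturated
structural profile by the integer shift (searched exhaustively over
±15 voxels) maximizing zero-mean cross-correlation inside a 30-voxel
window centered on the reference maximum; ties break toward the
smaller displacement, and shifts are applied by pure indexing — no
interpolation. Motion is detected, not corrected: the brightest
in-brain voxel of the first echo (3-TR median-smoothed to ignore
single-TR glitches) is tracked per TR, and a run is rejected when the
track's excursion exceeds three voxels ("more than three", so exactly
three passes). Rejection percentages round half up.

## Segmentation

The CSF/GM border is the gray-matter label edge adjacent to the
brightest voxel within ±3 voxels of either edge of an initial rough
segmentation (ties prefer the lower-index edge; CSF is at lower index
by convention). The GM/WM border is located on the unwrapped
structural phase as a least-squares change point: every candidate
depth splits the cortical segment (plus 6 tail voxels) into two
constants, the candidate minimizing the residual wins, and the step is
accepted only if it exceeds 4× its own standard error — otherwise the
segmenter falls back to a configured thickness (3.3 mm / voxel size =
8 voxels). The change-point formulation was chosen over a simple
first-difference threshold because it localizes the border exactly in
≈ 97 % of trials when the step is 3× the phase-difference noise,
where a single-difference rule succeeds only ~60 % of the time.
Depth fractions assign voxel centers to (i + 0.5)/n_gm, mapping the
segment onto [0, 1].

## Laminar analysis

Gray-matter time courses are box-smoothed (7 TRs), converted to
percent signal change against the mean of the final 10 s of each rest
period (the baseline definition is a package choice, exposed as
config), trial-averaged over 40 s peristimulus windows, linearly
resampled to 24 depth bins, and assigned to layers by the human-M1
scheme 0–20 % surface/CSF, 20–49 % L2/3, 49–67 % L5, 67–100 % L6
(half-open intervals; 0.49 and 0.50 both fall in L5's neighborhood
unambiguously, and the deepest interval is closed at 1).

Threshold timings (T10/T50/T90/T95: first times reaching that fraction
of the peak) are measured after a strong Gaussian temporal filter with
width parameter 3 s — the filter identity behind a "strong" smooth is
ambiguous in general, so kernel and width are exposed as config.
The HRF onset fit uses the *unfiltered* trial average over the 20 s
stimulus interval: the box filter alone biases fitted onsets early by
~0.4 s, which is why the pipeline keeps both a smoothed and a raw
trial average. The fit is constrained least squares under the box
bounds 0 < A < 40, 0.1 < T0 < 3.5, 2 < a < 4, 0.5 < b < 3, with a
deterministic multi-start (4 onsets × 2 rates in the box interior,
shape started at 3) and best-residual selection; solutions ending
within 1e-4 of a bound are flagged. GLM betas regress voxel PSC on a
boxcar convolved with a canonical unit-area kernel (T0 = 1 s, a = 3,
b = 1 s⁻¹) plus intercept. Layer timing comparisons are paired
two-sided t-tests with Bonferroni correction (p × number of
comparisons, capped at 1).

On sustained (convolved) responses the gamma-variate model cannot
represent a rising plateau within its shape bounds, so fit quality
degrades toward the surface layers — mirroring the low published R²
for deep-layer fits; onset-recovery validation therefore uses
direct-mode sessions where the fitted and generating models coincide.

## Problem sizes and reproducibility

End-to-end property sweeps (motion-shift recovery, border recovery,
onset recovery at 20 % amplitude noise, deep-before-superficial T95
ordering in ≥ 95 of 100 seeds) run full-length sessions (1360 TRs, 4
echoes) on a 48 mm readout with 4 coils — the laminar content is
identical to the full 224 mm grid, which is used for single smoke runs
and the saturation-profile simulation (0.05 mm grid, 4480 samples).
All randomness flows from explicit integer seeds; identical
configuration and seed reproduce bit-identical k-space, reports and
NIfTI payloads. Run directories store the configuration JSON, its
hash and per-stage wall time.

## Known limitations

* The line-profile simulation is an idealized steady-state model; it
  underestimates measured linewidths and cannot reproduce single-digit
  leakage percentages on flat objects (see the two limits above).
* ME-ICA denoising is exposed only as an optional pass-through hook;
  no denoising beyond echo weighting and box smoothing is performed.
* The generator omits physiological noise, B0 drift and sub-voxel
  motion; the motion model matches exactly what the pipeline can
  correct (integer shifts), plus uncorrectable jumps for the rejection
  rule.
* Vendor raw-file ingestion is out of scope; real data enter as
  complex arrays in the documented (coil, echo, readout, TR) layout.
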