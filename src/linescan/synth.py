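"""Synthetic multi-coil multi-echo line-scan sessions with ground truth.

The generator emulates the statistical structure a line-scanning pipeline
has to cope with, on a fully labeled footing:

* a 1D tissue profile along the readout line (CSF / gray matter / white
  matter) with per-compartment proton density, T2* and phase, including
  the bright pial-surface voxel at the CSF/GM border and the small phase
  step at the GM/WM border that the segmenter exploits;
* smooth complex coil sensitivities;
* a block-design laminar BOLD modulation (20 s on / 20 s off, 8 trials,
  TR 250 ms) built from a gamma-variate hemodynamic response with
  depth-dependent amplitude and onset;
* integer-voxel motion events;
* complex Gaussian thermal noise added in k-space.

Everything the pipeline is later asked to recover is stored as ground
truth alongside the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import GeometryError
from .recon import fft_centered

__all__ = [
    "TissueProfile",
    "SessionDesign",
    "LaminarHRFModel",
    "GroundTruth",
    "RawLineScanSession",
    "StructuralScans",
    "make_phantom_1d",
    "make_coil_sensitivities",
    "gamma_hrf",
    "block_response",
    "simulate_session",
    "simulate_structural",
    "default_laminar_model",
    "shift_profile",
]

COMPARTMENTS = ("background", "csf", "gm", "wm")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TissueProfile:
    """1D tissue model along the readout line.

    ``gm_depth`` is the relative cortical depth of each GM voxel center
    (0 at the CSF border, 1 at the WM border) and NaN elsewhere.
    """

    positions: np.ndarray  # mm
    compartment: np.ndarray  # str per voxel
    proton_density: np.ndarray
    t2star_ms: np.ndarray
    phase_rad: np.ndarray
    gm_depth: np.ndarray
    csf_border_index: int  # first GM voxel
    wm_border_index: int  # first WM voxel (one past the last GM voxel)
    gm_thickness_mm: float
    voxel_mm: float

    @property
    def n_voxels(self) -> int:
        return self.positions.size

    @property
    def gm_slice(self) -> slice:
        return slice(self.csf_border_index, self.wm_border_index)

    @property
    def n_gm_voxels(self) -> int:
        return self.wm_border_index - self.csf_border_index

    @property
    def gm_fractional_voxels(self) -> float:
        """GM thickness expressed in voxels, including the fractional part."""
        return self.gm_thickness_mm / self.voxel_mm


@dataclass(frozen=True)
class SessionDesign:
    """Acquisition and paradigm parameters of one functional run."""

    tr: float = 0.25  # s
    n_trials: int = 8
    on_duration: float = 20.0  # s tapping
    off_duration: float = 20.0  # s rest
    baseline_duration: float = 20.0  # s leading rest
    echo_times_ms: tuple[float, ...] = (14.0, 25.0, 36.0, 47.0)
    n_coils: int = 8
    noise_sd: float = 0.02
    motion_events: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    @property
    def n_trs(self) -> int:
        total = self.baseline_duration + self.n_trials * (
            self.on_duration + self.off_duration
        )
        return int(round(total / self.tr))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_trs) * self.tr

    @property
    def trial_onsets(self) -> np.ndarray:
        """Tapping onsets in seconds."""
        return self.baseline_duration + np.arange(self.n_trials) * (
            self.on_duration + self.off_duration
        )

    def stimulus_boxcar(self) -> np.ndarray:
        """1 during tapping, 0 during rest, sampled at the TR grid."""
        t = self.frame_times
        box = np.zeros(self.n_trs)
        for onset in self.trial_onsets:
            box[(t >= onset) & (t < onset + self.on_duration)] = 1.0
        return box

    def baseline_mask(self, window_s: float = 10.0) -> np.ndarray:
        """TRs in the final ``window_s`` seconds of each rest period."""
        t = self.frame_times
        mask = np.zeros(self.n_trs, bool)
        rest_ends = np.concatenate(
            [[self.baseline_duration], self.trial_onsets[1:], [t[-1] + self.tr]]
        )
        for end in rest_ends:
            mask |= (t >= end - window_s) & (t < end)
        return mask


@dataclass(frozen=True)
class LaminarHRFModel:
    """Depth-resolved hemodynamic response parameters.

    Parameters are given on a depth grid in [0, 1] and linearly
    interpolated.  ``amplitude`` is the plateau (convolved mode) or peak
    (direct mode) percent signal change.  ``response_model`` selects how
    the per-TR modulation is built from the gamma-variate response h(t):
    ``"convolved"`` convolves the stimulus boxcar with h as a unit-area
    kernel (sustained responses that plateau at ``amplitude``), whereas
    ``"direct"`` places a peak-normalized copy of h at each trial onset
    (transient responses whose shape is h itself).
    """

    depth_grid: tuple[float, ...] = (0.0, 1.0)
    amplitude: tuple[float, ...] = (3.0, 0.5)  # percent
    t0: tuple[float, ...] = (1.1, 2.3)  # s onset
    a: tuple[float, ...] = (3.0, 3.0)  # shape
    b: tuple[float, ...] = (0.55, 2.5)  # 1/s rate
    response_model: str = "convolved"

    def params_at(self, depth: np.ndarray) -> dict[str, np.ndarray]:
        d = np.clip(np.asarray(depth, float), 0, 1)
        g = np.asarray(self.depth_grid)
        return {
            name: np.interp(d, g, np.asarray(vals))
            for name, vals in (
                ("amplitude", self.amplitude),
                ("t0", self.t0),
                ("a", self.a),
                ("b", self.b),
            )
        }


def default_laminar_model(response_model: str = "convolved") -> LaminarHRFModel:
    """Depth profile emulating motor-cortex finger-tapping responses.

    Amplitude decays from ~3 % at the pial surface toward ~0.5 % at the WM
    border; onsets follow the layer-resolved fits (surface 1.1 s, L2/3
    0.7 s, L5 1.0 s, L6 2.3 s); the rate parameter rises with depth so
    deep responses plateau early while superficial ones keep rising.
    """
    return LaminarHRFModel(
        depth_grid=(0.0, 0.1, 0.345, 0.58, 0.835, 1.0),
        amplitude=(3.0, 2.8, 2.2, 1.4, 0.7, 0.5),
        t0=(1.1, 1.1, 0.7, 1.0, 2.3, 2.3),
        a=(3.0, 3.0, 3.0, 3.0, 3.0, 3.0),
        b=(0.55, 0.55, 0.8, 1.4, 2.5, 2.5),
        response_model=response_model,
    )


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    csf_border_index: int
    wm_border_index: int
    gm_depth: np.ndarray  # depth per GM voxel
    hrf_params: dict[str, np.ndarray]  # per GM voxel: amplitude, t0, a, b
    shifts: np.ndarray  # applied integer shift per TR
    psc: np.ndarray  # noiseless percent-change (GM voxel x TR)
    phantom: TissueProfile
    design: SessionDesign


@dataclass
class RawLineScanSession:
    """Raw functional k-space: (coil, echo, readout sample, TR)."""

    kspace: np.ndarray
    coil_sensitivities: np.ndarray  # (coil, readout voxel)
    design: SessionDesign
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        n_c, n_e, n_x, n_t = self.kspace.shape
        if n_c != self.coil_sensitivities.shape[0]:
            raise ValueError("coil count mismatch between kspace and sensitivities")
        if n_e != len(self.design.echo_times_ms):
            raise ValueError("echo count mismatch between kspace and design")
        if n_t != self.design.n_trs:
            raise ValueError("TR count mismatch between kspace and design")


@dataclass
class StructuralScans:
    """2D multi-echo structural acquisitions, with and without saturation.

    k-space layout: (coil, echo, readout, phase-encode).  The center
    phase-encode row of the object equals the 1D phantom, so collapsing
    the saturated scan along phase-encode yields the alignment reference.
    """

    kspace_saturated: np.ndarray
    kspace_unsaturated: np.ndarray
    coil_sensitivities: np.ndarray  # (coil, readout voxel)
    phase_positions_mm: np.ndarray
    phantom: TissueProfile
    echo_times_ms: tuple[float, ...]
    reference_magnitude: np.ndarray  # noiseless (readout, phase) magnitude
    reference_phase: np.ndarray


# ---------------------------------------------------------------------------
# phantom and sensitivities
# ---------------------------------------------------------------------------


def make_phantom_1d(
    fov_mm: float = 224.0,
    voxel_mm: float = 0.39,
    gm_thickness_mm: float = 3.3,
    phase_step_rad: float = 0.3,
    csf_thickness_mm: float = 6.0,
    wm_thickness_mm: float = 12.0,
    pial_brightening: float = 1.2,
    phase_ramp_rad_per_voxel: float = 0.0,
) -> TissueProfile:
    """Build the 1D tissue profile along the readout line.

    The cortical patch sits at the center of the field of view, CSF on the
    lower-index side.  CSF is brighter than GM (long T2*, high proton
    density, plus a pial-surface brightening of the CSF voxel adjacent to
    GM), and the WM phase differs from GM by ``phase_step_rad``.
    """
    if min(fov_mm, voxel_mm, gm_thickness_mm, csf_thickness_mm, wm_thickness_mm) <= 0:
        raise ValueError("sizes must be positive")
    if gm_thickness_mm >= fov_mm / 4:
        raise ValueError("gm_thickness_mm must be < fov_mm / 4")

    n = int(round(fov_mm / voxel_mm))
    x = (np.arange(n) - (n - 1) / 2) * voxel_mm
    center = 0.0
    gm_lo = center - gm_thickness_mm / 2
    gm_hi = center + gm_thickness_mm / 2

    comp = np.full(n, "background", dtype=object)
    comp[(x >= gm_lo - csf_thickness_mm) & (x < gm_lo)] = "csf"
    comp[(x >= gm_lo) & (x < gm_hi)] = "gm"
    comp[(x >= gm_hi) & (x < gm_hi + wm_thickness_mm)] = "wm"
    comp = comp.astype(str)

    pd_map = {"background": 0.0, "csf": 1.0, "gm": 0.8, "wm": 0.65}
    t2_map = {"background": 100.0, "csf": 45.0, "gm": 25.0, "wm": 18.0}
    pd = np.array([pd_map[c] for c in comp])
    t2 = np.array([t2_map[c] for c in comp])

    gm_idx = np.flatnonzero(comp == "gm")
    csf_border = int(gm_idx[0])
    wm_border = int(gm_idx[-1]) + 1
    pd[csf_border - 1] *= pial_brightening  # bright pial-surface voxel

    phase = phase_ramp_rad_per_voxel * np.arange(n)
    phase[comp == "wm"] += phase_step_rad

    depth = np.full(n, np.nan)
    depth[gm_idx] = (x[gm_idx] - gm_lo) / gm_thickness_mm

    return TissueProfile(
        positions=x,
        compartment=comp,
        proton_density=pd,
        t2star_ms=t2,
        phase_rad=phase,
        gm_depth=depth,
        csf_border_index=csf_border,
        wm_border_index=wm_border,
        gm_thickness_mm=gm_thickness_mm,
        voxel_mm=voxel_mm,
    )


def make_coil_sensitivities(
    n_coils: int, positions: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Smooth complex coil sensitivities, (coil, position).

    Gaussian magnitude lobes spread over the field of view on a constant
    floor, with coil-specific smooth phase ramps; the root-sum-of-squares
    over coils is strictly positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    x = np.asarray(positions, float)
    if n_coils == 1:
        return np.ones((1, x.size), complex)
    rng = np.random.default_rng(seed)
    span = x[-1] - x[0]
    centers = x[0] + span * (np.arange(n_coils) + 0.5) / n_coils
    width = span / n_coils * 1.5
    sens = np.empty((n_coils, x.size), complex)
    for c in range(n_coils):
        mag = 0.35 + np.exp(-0.5 * ((x - centers[c]) / width) ** 2)
        slope = rng.uniform(-0.5, 0.5) / span
        phase = 2 * np.pi * slope * (x - x[0]) + rng.uniform(0, 2 * np.pi)
        sens[c] = mag * np.exp(1j * phase)
    return sens


# ---------------------------------------------------------------------------
# hemodynamic responses
# ---------------------------------------------------------------------------


def gamma_hrf(
    t: np.ndarray, amplitude: float, t0: float, a: float, b: float
) -> np.ndarray:
    """Gamma-variate hemodynamic response.

    h(t) = A * (t-T0)^(a-1) * b^a / Gamma(a) * exp(-(t-T0)*b) for t >= T0,
    0 before the onset T0.  With this normalization the response integrates
    to A; its peak sits at T0 + (a-1)/b.
    """
    t = np.asarray(t, float)
    h = np.zeros_like(t)
    m = t >= t0
    h[m] = amplitude * stats.gamma.pdf(t[m] - t0, a, scale=1.0 / b)
    return h


def gamma_hrf_peak(a: float, b: float) -> float:
    """Peak value of the unit-amplitude gamma-variate response."""
    return float(stats.gamma.pdf((a - 1) / b, a, scale=1.0 / b))


def block_response(
    design: SessionDesign, t0: float, a: float, b: float, response_model: str
) -> np.ndarray:
    """Unit-amplitude response time course on the TR grid.

    ``"convolved"``: stimulus boxcar convolved with the unit-area response
    kernel (plateaus at 1 for long blocks).  ``"direct"``: peak-normalized
    response inserted at each trial onset.
    """
    t = design.frame_times
    if response_model == "convolved":
        kernel = gamma_hrf(t - t[0], 1.0, t0, a, b)
        box = design.stimulus_boxcar()
        return np.convolve(box, kernel)[: t.size] * design.tr
    if response_model == "direct":
        resp = np.zeros(t.size)
        peak = gamma_hrf_peak(a, b)
        for onset in design.trial_onsets:
            resp += gamma_hrf(t - onset, 1.0, t0, a, b) / peak
        return resp
    raise ValueError("response_model must be 'convolved' or 'direct'")


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


def shift_profile(arr: np.ndarray, shift: int, axis: int = 0) -> np.ndarray:
    """Integer shift with zero fill (no wrap-around)."""
    if shift == 0:
        return arr
    n = arr.shape[axis]
    if abs(shift) >= n:
        raise GeometryError(f"shift {shift} exceeds grid of {n} voxels")
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if shift > 0:
        dst[axis] = slice(shift, None)
        src[axis] = slice(None, n - shift)
    else:
        dst[axis] = slice(None, n + shift)
        src[axis] = slice(-shift, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shifts_per_tr(design: SessionDesign) -> np.ndarray:
    shifts = np.zeros(design.n_trs, int)
    for tr_index, shift in sorted(design.motion_events):
        if not 0 <= tr_index < design.n_trs:
            raise GeometryError(f"motion event at TR {tr_index} outside the run")
        shifts[tr_index:] = shift
    return shifts


def simulate_session(
    phantom: TissueProfile,
    design: SessionDesign,
    laminar_model: LaminarHRFModel | None = None,
    coil_sensitivities: np.ndarray | None = None,
) -> RawLineScanSession:
    """Generate one raw functional line-scan session.

    The noiseless signal of coil c, echo e, voxel x, TR t is

        sens[c,x] * pd[x] * exp(-TE_e / T2*[x]) * exp(i phase[x])
        * (1 + delta[x,t]),

    shifted by the motion event active at t and transformed to k-space,
    plus i.i.d. complex Gaussian noise of standard deviation
    ``design.noise_sd`` per k-space sample.  ``delta`` is the laminar
    block-design response (fractional units) on GM voxels, zero elsewhere.
    """
    if laminar_model is None:
        laminar_model = default_laminar_model()
    x = phantom.positions
    n = x.size
    rng = np.random.default_rng(design.seed)
    if coil_sensitivities is None:
        coil_sensitivities = make_coil_sensitivities(
            design.n_coils, x, seed=design.seed
        )
    sens = np.asarray(coil_sensitivities, complex)

    gm = phantom.gm_slice
    depths = phantom.gm_depth[gm]
    params = laminar_model.params_at(depths)
    n_t = design.n_trs
    delta_gm = np.zeros((depths.size, n_t))
    for i in range(depths.size):
        resp = block_response(
            design,
            params["t0"][i],
            params["a"][i],
            params["b"][i],
            laminar_model.response_model,
        )
        delta_gm[i] = params["amplitude"][i] / 100.0 * resp

    modulation = np.ones((n, n_t))
    modulation[gm] += delta_gm

    shifts = _shifts_per_tr(design)
    echo_decay = np.exp(
        -np.asarray(design.echo_times_ms)[:, None] / phantom.t2star_ms[None, :]
    )
    static = phantom.proton_density * np.exp(1j * phantom.phase_rad)

    n_c, n_e = sens.shape[0], len(design.echo_times_ms)
    kspace = np.empty((n_c, n_e, n, n_t), complex)
    # group TRs by shift so each group is one vectorized FFT call
    for shift in np.unique(shifts):
        cols = shifts == shift
        mod = modulation[:, cols]
        for c in range(n_c):
            for e in range(n_e):
                img = (sens[c] * static * echo_decay[e])[:, None] * mod
                img = shift_profile(img, int(shift), axis=0)
                kspace[c, e][:, cols] = fft_centered(img, axis=0)
    if design.noise_sd > 0:
        noise = rng.normal(scale=design.noise_sd, size=(2, n_c, n_e, n, n_t))
        kspace += noise[0] + 1j * noise[1]

    truth = GroundTruth(
        csf_border_index=phantom.csf_border_index,
        wm_border_index=phantom.wm_border_index,
        gm_depth=depths,
        hrf_params=params,
        shifts=shifts,
        psc=100.0 * delta_gm,
        phantom=phantom,
        design=design,
    )
    return RawLineScanSession(kspace, sens, design, truth)


def simulate_structural(
    phantom: TissueProfile,
    n_coils: int = 8,
    echo_times_ms: Sequence[float] = (14.0, 25.0, 36.0, 47.0),
    saturation_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    n_phase: int = 33,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StructuralScans:
    """Generate the 2D structural FLASH pair (with / without saturation).

    The 2D object extends the 1D phantom along the phase-encode axis with
    a smooth envelope whose center row equals the phantom exactly.
    Saturation multiplies the object along phase-encode by
    ``saturation_profile(y_mm)`` (default: an idealized line profile with
    a 3 mm unsaturated gap over a 3 % steady-state residual floor).
    """
    x = phantom.positions
    n_x = x.size
    if n_phase % 2 == 0:
        n_phase += 1  # keep an exact center row
    y = (np.arange(n_phase) - n_phase // 2) * phantom.voxel_mm
    envelope = np.exp(-0.5 * (y / (0.8 * y.max() + 1e-9)) ** 2)
    envelope /= envelope[n_phase // 2]

    if saturation_profile is None:
        sat = np.where(np.abs(y) < 1.5, 1.0, 0.03)
    else:
        sat = np.asarray(saturation_profile(y), float)

    rng = np.random.default_rng(seed)
    sens = make_coil_sensitivities(n_coils, x, seed=seed)
    static = phantom.proton_density * np.exp(1j * phantom.phase_rad)
    echo_decay = np.exp(
        -np.asarray(echo_times_ms)[:, None] / phantom.t2star_ms[None, :]
    )

    n_e = len(echo_times_ms)
    k_sat = np.empty((n_coils, n_e, n_x, n_phase), complex)
    k_nosat = np.empty_like(k_sat)
    for c in range(n_coils):
        for e in range(n_e):
            plane = (sens[c] * static * echo_decay[e])[:, None] * envelope[None, :]
            k_nosat[c, e] = fft_centered(fft_centered(plane, axis=0), axis=1)
            k_sat[c, e] = fft_centered(
                fft_centered(plane * sat[None, :], axis=0), axis=1
            )
    if noise_sd > 0:
        for k in (k_sat, k_nosat):
            noise = rng.normal(scale=noise_sd, size=(2,) + k.shape)
            k += noise[0] + 1j * noise[1]

    ref = static[:, None] * envelope[None, :]
    return StructuralScans(
        kspace_saturated=k_sat,
        kspace_unsaturated=k_nosat,
        coil_sensitivities=sens,
        phase_positions_mm=y,
        phantom=phantom,
        echo_times_ms=tuple(echo_times_ms),
        reference_magnitude=np.abs(ref),
        reference_phase=np.angle(ref),
    )
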