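"""Depth-resolved percent-signal-change analysis and HRF onset fitting.

Aligned gray-matter time courses are converted to percent signal change,
lightly smoothed, trial-averaged, resampled to 24 cortical-depth bins and
assigned to layers (surface/CSF, L2/3, L5, L6, following human M1
histology).  Timing is characterized by the first crossings of 10/50/90/95 %
of the peak amplitude and by a constrained gamma-variate fit of the
hemodynamic response

    h(t) = A (t-T0)^(a-1) b^a / Gamma(a) exp(-(t-T0) b),  t >= T0

over the stimulus interval, whose onset parameter T0 carries the laminar
timing information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d

from .synth import SessionDesign, gamma_hrf

__all__ = [
    "LayerScheme",
    "DEFAULT_LAYER_SCHEME",
    "HRFParams",
    "TimingMetrics",
    "LaminarTimecourse",
    "to_percent_change",
    "smooth_box",
    "epoch_and_average",
    "resample_depth",
    "assign_layers",
    "timing_metrics",
    "fit_hrf",
    "glm_betas",
    "compare_layer_timings",
    "N_DEPTH_BINS",
]

N_DEPTH_BINS = 24

#: Depth intervals per layer (half-open; the last is closed at 1.0).
DEFAULT_LAYER_SCHEME: tuple[tuple[str, float, float], ...] = (
    ("Surface/CSF", 0.0, 0.20),
    ("L2/3", 0.20, 0.49),
    ("L5", 0.49, 0.67),
    ("L6", 0.67, 1.0),
)

LayerScheme = tuple[tuple[str, float, float], ...]


@dataclass(frozen=True)
class HRFParams:
    """Gamma-variate HRF parameters with fit quality."""

    amplitude: float  # A, percent scale
    t0: float  # onset, s
    a: float  # shape
    b: float  # rate, 1/s
    r2: float = np.nan
    at_bound: bool = False

    #: box constraints of the fit: 0 < A < 40; 0.1 < T0 < 3.5; 2 < a < 4;
    #: 0.5 < b < 3
    BOUNDS = ((0.0, 40.0), (0.1, 3.5), (2.0, 4.0), (0.5, 3.0))


@dataclass(frozen=True)
class TimingMetrics:
    """First times the response exceeds fractions of its peak amplitude."""

    t_peak: float
    t10: float
    t50: float
    t90: float
    t95: float
    valid: bool = True


@dataclass
class LaminarTimecourse:
    """Percent-signal-change time courses on the 24-bin depth grid."""

    depth_bins: np.ndarray  # bin-center depth fractions
    layer: list[str]  # layer label per bin
    psc: np.ndarray  # (bin, TR), box-smoothed
    trial_average: np.ndarray  # (bin, peristimulus sample), box-smoothed
    peristimulus_times: np.ndarray  # s, 0..40
    trial_average_raw: np.ndarray | None = None  # unfiltered, for HRF fits

    def layer_average(self, layer: str, raw: bool = False) -> np.ndarray:
        """Trial-averaged time course averaged over the bins of a layer.

        ``raw=True`` returns the unfiltered version (onset fits use the
        unfiltered trial averages; the box filter biases onsets early).
        """
        sel = [i for i, lab in enumerate(self.layer) if lab == layer]
        if not sel:
            raise ValueError(f"no depth bins in layer {layer!r}")
        src = self.trial_average_raw if raw else self.trial_average
        if src is None:
            raise ValueError("raw trial averages were not stored")
        return src[sel].mean(axis=0)


def to_percent_change(
    timeseries: np.ndarray, baseline_mask: np.ndarray
) -> np.ndarray:
    """Percent signal change: 100 (s(t) - B) / B with B the baseline mean.

    Works on (TR,) or (voxel, TR) arrays; the mask selects baseline TRs.
    """
    ts = np.asarray(timeseries, float)
    mask = np.asarray(baseline_mask, bool)
    if mask.shape != ts.shape[-1:]:
        raise ValueError("baseline mask must match the TR axis")
    if not mask.any():
        raise ValueError("empty baseline")
    b = ts[..., mask].mean(axis=-1, keepdims=True)
    if np.any(b <= 0):
        raise ValueError("baseline mean must be positive")
    return 100.0 * (ts - b) / b


def smooth_box(timeseries: np.ndarray, kernel_trs: int = 7) -> np.ndarray:
    """Centered running average along the last axis; edges shrink the window."""
    if kernel_trs % 2 != 1:
        raise ValueError("kernel size must be odd")
    ts = np.asarray(timeseries, float)
    n = ts.shape[-1]
    if kernel_trs > n:
        raise ValueError("kernel longer than the series")
    kernel = np.ones(kernel_trs)
    summed = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, ts
    )
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return summed / counts


def epoch_and_average(
    psc: np.ndarray, design: SessionDesign, window_s: float = 40.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average peristimulus windows locked to the tapping onsets.

    Returns ``(trial_average, times)`` where the window covers
    ``[0, window_s)`` seconds from each onset.  Trials whose window would
    run past the end of the run are dropped with a warning.
    """
    ts = np.asarray(psc, float)
    n_t = ts.shape[-1]
    if n_t != design.n_trs:
        raise ValueError("time series length does not match the design")
    n_win = int(round(window_s / design.tr))
    onsets_tr = np.round(design.trial_onsets / design.tr).astype(int)
    complete = onsets_tr[onsets_tr + n_win <= n_t]
    if complete.size < onsets_tr.size:
        warnings.warn(
            f"dropping {onsets_tr.size - complete.size} incomplete trial(s)",
            stacklevel=2,
        )
    if complete.size == 0:
        raise ValueError("no complete trials in the run")
    epochs = np.stack([ts[..., o : o + n_win] for o in complete], axis=0)
    return epochs.mean(axis=0), np.arange(n_win) * design.tr


def resample_depth(
    gm_psc: np.ndarray, depth_fractions: np.ndarray, n_bins: int = N_DEPTH_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate voxel time courses onto equally spaced depth bins.

    ``gm_psc`` is (GM voxel, TR); ``depth_fractions`` gives each voxel
    center's relative cortical depth.  Returns ``(binned, bin_centers)``
    with ``binned`` of shape (n_bins, TR); beyond the outermost voxel
    centers the profile is clamped (constant extrapolation).
    """
    psc = np.atleast_2d(np.asarray(gm_psc, float))
    depths = np.asarray(depth_fractions, float)
    if psc.shape[0] != depths.size:
        raise ValueError("one depth per GM voxel required")
    if depths.size < 2:
        raise ValueError("need at least two gray-matter voxels")
    order = np.argsort(depths)
    depths = depths[order]
    psc = psc[order]
    bins = np.linspace(0.0, 1.0, n_bins)
    out = np.empty((n_bins, psc.shape[1]))
    for t in range(psc.shape[1]):
        out[:, t] = np.interp(bins, depths, psc[:, t])
    return out, bins


def assign_layers(
    depth_bins: np.ndarray, scheme: LayerScheme = DEFAULT_LAYER_SCHEME
) -> list[str]:
    """Assign depth fractions to cortical layers.

    Intervals are half-open ([lo, hi)), except the deepest layer which is
    closed at depth 1.0, so the scheme partitions [0, 1] totally.
    """
    depths = np.asarray(depth_bins, float)
    if np.any((depths < 0) | (depths > 1)):
        raise ValueError("depth fractions must lie in [0, 1]")
    labels = []
    last = len(scheme) - 1
    for d in depths:
        for i, (name, lo, hi) in enumerate(scheme):
            if lo <= d < hi or (i == last and d == hi):
                labels.append(name)
                break
    return labels


def timing_metrics(
    trial_average: np.ndarray,
    dt: float,
    strong_filter_width_s: float = 3.0,
) -> TimingMetrics:
    """Threshold-crossing times of a trial-averaged response.

    The response is smoothed with a Gaussian temporal filter (width
    parameter ``strong_filter_width_s`` as the standard deviation), the
    peak located, and the first samples at or above 10/50/90/95 % of the
    peak amplitude reported at TR resolution.  A non-positive peak leaves
    the metrics undefined (``valid=False``).
    """
    y = np.asarray(trial_average, float)
    if strong_filter_width_s > 0:
        y = gaussian_filter1d(y, strong_filter_width_s / dt, mode="nearest")
    i_peak = int(np.argmax(y))
    peak = y[i_peak]
    if peak <= 0:
        return TimingMetrics(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
    times = {}
    for frac, name in ((0.10, "t10"), (0.50, "t50"), (0.90, "t90"), (0.95, "t95")):
        above = np.flatnonzero(y >= frac * peak)
        times[name] = float(above[0] * dt)
    return TimingMetrics(t_peak=float(i_peak * dt), valid=True, **times)


def _fit_residual(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    return gamma_hrf(t, *params) - y


def fit_hrf(
    trial_average: np.ndarray,
    dt: float,
    segment_s: float = 20.0,
    n_starts_t0: int = 4,
    n_starts_b: int = 2,
) -> HRFParams:
    """Constrained least-squares gamma-variate fit over the stimulus interval.

    Fits ``h(t)`` to the first ``segment_s`` seconds of the trial average
    under the box constraints 0 < A < 40, 0.1 < T0 < 3.5, 2 < a < 4,
    0.5 < b < 3, using a deterministic multi-start over a coarse grid of
    (T0, b) in the box interior and keeping the best-r2 solution.  A fit
    ending on a box bound is flagged.
    """
    y = np.asarray(trial_average, float)
    n_seg = int(round(segment_s / dt))
    y = y[:n_seg]
    t = np.arange(y.size) * dt
    lo = np.array([b[0] for b in HRFParams.BOUNDS])
    hi = np.array([b[1] for b in HRFParams.BOUNDS])

    a0_amp = float(np.clip(np.max(y) * 2.0, 0.5, 39.0))
    t0_grid = np.linspace(0.3, 3.2, n_starts_t0)
    b_grid = np.linspace(0.7, 2.5, n_starts_b)
    best = None
    for t0_start in t0_grid:
        for b_start in b_grid:
            x0 = np.array([a0_amp, t0_start, 3.0, b_start])
            res = optimize.least_squares(
                _fit_residual,
                x0,
                bounds=(lo, hi),
                args=(t, y),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
            )
            if best is None or res.cost < best.cost:
                best = res

    params = best.x
    ss_res = float(np.sum(best.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    eps = 1e-4 * (hi - lo)
    at_bound = bool(np.any(params - lo < eps) or np.any(hi - params < eps))
    return HRFParams(
        amplitude=float(params[0]),
        t0=float(params[1]),
        a=float(params[2]),
        b=float(params[3]),
        r2=r2,
        at_bound=at_bound,
    )


def glm_betas(
    psc: np.ndarray,
    design: SessionDesign,
    hrf: HRFParams | None = None,
) -> np.ndarray:
    """Ordinary least squares of voxel time courses on an HRF regressor.

    The regressor is the stimulus boxcar convolved with a unit-area
    gamma-variate kernel (canonical parameters T0=1 s, a=3, b=1 by
    default) plus an intercept; betas are in percent units.
    """
    from .synth import block_response  # local import to avoid cycle at import

    ts = np.atleast_2d(np.asarray(psc, float))
    if hrf is None:
        hrf = HRFParams(amplitude=1.0, t0=1.0, a=3.0, b=1.0)
    reg = block_response(design, hrf.t0, hrf.a, hrf.b, "convolved")
    x = np.column_stack([reg, np.ones_like(reg)])
    if np.linalg.matrix_rank(x) < 2:
        raise ValueError("rank-deficient design (constant regressor)")
    beta, *_ = np.linalg.lstsq(x, ts.T, rcond=None)
    out = beta[0]
    return out if np.asarray(psc).ndim > 1 else float(out[0])


def compare_layer_timings(
    metrics_by_layer: dict[str, np.ndarray],
) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted paired t-tests between layer pairs.

    ``metrics_by_layer`` maps layer name to a per-subject vector of one
    timing metric; subjects must be paired (equal length, same order).
    Each raw two-sided p-value is multiplied by the number of comparisons
    and capped at 1.
    """
    layers = list(metrics_by_layer)
    if len(layers) < 2:
        raise ValueError("need at least two layers to compare")
    lengths = {len(v) for v in metrics_by_layer.values()}
    if len(lengths) != 1:
        raise ValueError("paired comparisons require equal subject counts")
    if lengths.pop() < 2:
        raise ValueError("need at least two subjects per layer")
    pairs = list(combinations(layers, 2))
    n_comp = len(pairs)
    out = {}
    for la, lb in pairs:
        va = np.asarray(metrics_by_layer[la], float)
        vb = np.asarray(metrics_by_layer[lb], float)
        if np.allclose(va, vb):
            p = 1.0
        else:
            p = float(stats.ttest_rel(va, vb).pvalue)
        out[(la, lb)] = min(p * n_comp, 1.0)
    return out
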