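"""Run-to-reference alignment and motion quality control.

Each functional run is aligned to the collapsed saturated structural
profile by a pure integer-voxel shift (sub-voxel interpolation would blur
the laminar signal).  The shift maximizes the zero-mean cross-correlation
inside a 30-voxel window around the target gray matter, searched
exhaustively.  Motion is detected, not corrected: if the brightest
first-echo voxel inside the brain wanders by more than three voxels over
a run, the run is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .errors import AlignmentError, GeometryError

__all__ = [
    "AlignmentResult",
    "find_shift",
    "apply_shift",
    "detect_motion",
    "session_rejection_report",
]


@dataclass
class AlignmentResult:
    shift: int
    cross_correlation_peak: float
    brightest_voxel_track: np.ndarray | None = None
    rejected: bool = False
    reason: str = ""


def find_shift(
    run_mean_line: np.ndarray,
    reference_line: np.ndarray,
    window_voxels: int = 30,
    center_index: int | None = None,
    max_shift: int = 15,
) -> AlignmentResult:
    """Integer shift aligning a run to the reference line.

    The zero-mean cross-correlation is evaluated inside a ``window_voxels``
    window centered on ``center_index`` (default: the reference maximum,
    i.e. the bright CSF voxel next to the target gray matter) for every
    integer shift in ``[-max_shift, max_shift]``; ties break toward the
    smaller absolute shift.  Shifting the run by the returned amount
    aligns it with the reference.
    """
    run = np.asarray(run_mean_line, float)
    ref = np.asarray(reference_line, float)
    if run.shape != ref.shape:
        raise ValueError("run and reference must share one grid")
    n = ref.size
    if center_index is None:
        center_index = int(np.argmax(ref))
    half = window_voxels // 2
    lo = max(center_index - half, 0)
    hi = min(lo + window_voxels, n)
    lo = max(hi - window_voxels, 0)
    ref_win = ref[lo:hi] - ref[lo:hi].mean()
    if np.allclose(ref_win, 0):
        raise AlignmentError("reference window has zero variance")

    best_shift, best_cc = 0, -np.inf
    for shift in range(-max_shift, max_shift + 1):
        src_lo, src_hi = lo - shift, hi - shift
        if src_lo < 0 or src_hi > n:
            continue
        seg = run[src_lo:src_hi] - run[src_lo:src_hi].mean()
        cc = float(np.dot(seg, ref_win))
        if cc > best_cc or (cc == best_cc and abs(shift) < abs(best_shift)):
            best_cc, best_shift = cc, shift
    if abs(best_shift) == max_shift:
        warnings.warn(
            f"best shift {best_shift} lies at the search-window edge",
            stacklevel=2,
        )
    return AlignmentResult(shift=best_shift, cross_correlation_peak=best_cc)


def apply_shift(run: np.ndarray, shift: int, axis: int = 0) -> np.ndarray:
    """Shift a run by an integer number of voxels without interpolation.

    Voxels shifted in from outside the grid are marked invalid (NaN for
    float data, 0 otherwise).
    """
    run = np.asarray(run)
    if int(shift) != shift:
        raise ValueError("only integer shifts are applied (no interpolation)")
    shift = int(shift)
    n = run.shape[axis]
    if abs(shift) >= n:
        raise GeometryError(f"shift {shift} exceeds the line length {n}")
    if shift == 0:
        return run.copy()
    fill = np.nan if np.issubdtype(run.dtype, np.floating) else 0
    out = np.full_like(run, fill)
    src = [slice(None)] * run.ndim
    dst = [slice(None)] * run.ndim
    if shift > 0:
        dst[axis] = slice(shift, None)
        src[axis] = slice(None, n - shift)
    else:
        dst[axis] = slice(None, n + shift)
        src[axis] = slice(-shift, None)
    out[tuple(dst)] = run[tuple(src)]
    return out


def detect_motion(
    first_echo_magnitude: np.ndarray,
    brain_mask: np.ndarray,
    max_excursion_voxels: int = 3,
    smooth_trs: int = 3,
) -> AlignmentResult:
    """Reject a run whose brightest in-brain voxel wanders too far.

    The brightest voxel of the (temporally median-smoothed) first-echo
    magnitude is tracked per TR inside the brain mask; the run is rejected
    when the track's excursion exceeds ``max_excursion_voxels`` (the rule
    is "more than three voxels", so an excursion of exactly three passes).
    """
    mag = np.asarray(first_echo_magnitude, float)
    mask = np.asarray(brain_mask, bool)
    if mag.ndim != 2:
        raise ValueError("expected (voxel, TR) magnitude")
    if not mask.any():
        raise ValueError("empty brain mask")
    if smooth_trs > 1:
        mag = median_filter(mag, size=(1, smooth_trs), mode="nearest")
    idx = np.flatnonzero(mask)
    track = idx[np.argmax(mag[idx], axis=0)]
    excursion = int(track.max() - track.min())
    rejected = excursion > max_excursion_voxels
    reason = (
        f"brightest-voxel excursion {excursion} voxels exceeds "
        f"{max_excursion_voxels}"
        if rejected
        else ""
    )
    return AlignmentResult(
        shift=0,
        cross_correlation_peak=np.nan,
        brightest_voxel_track=track,
        rejected=rejected,
        reason=reason,
    )


def session_rejection_report(results: list[AlignmentResult]) -> dict:
    """Counts and percentage of rejected runs (percentage rounds half up)."""
    if not results:
        raise ValueError("need at least one run")
    n_rejected = sum(r.rejected for r in results)
    n_total = len(results)
    percentage = int(np.floor(100.0 * n_rejected / n_total + 0.5))
    return {
        "n_rejected": n_rejected,
        "n_total": n_total,
        "percentage": percentage,
    }
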