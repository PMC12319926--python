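"""Gray-matter segmentation on the line from magnitude and phase.

The cortical segment is located in two steps.  The CSF/GM border is the
gray-matter label edge adjacent to the brightest voxel near an edge of a
rough initial segmentation: CSF is bright on the echo-combined magnitude
line, and the pial surface is the brightest voxel next to cortex.  The
GM/WM border is found on the unwrapped structural phase line, where the
different tissue susceptibility produces a small phase step; the step is
located as a least-squares change point and accepted only when clearly
above the noise, otherwise the segmenter falls back to a configured
cortical thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SegmentationError

__all__ = [
    "GmSegment",
    "collapse_segmentation",
    "find_csf_border",
    "find_wm_border",
    "segment_line",
]


@dataclass(frozen=True)
class GmSegment:
    """The gray-matter segment on the line (0-based voxel indices).

    ``csf_border_index`` is the first gray-matter voxel (CSF side, lower
    index by convention); ``wm_border_index`` is the first white-matter
    voxel, one past the last gray-matter voxel.
    """

    csf_border_index: int
    wm_border_index: int
    method: str  # "phase_jump" or "thickness_fallback"

    def __post_init__(self) -> None:
        if self.csf_border_index >= self.wm_border_index:
            raise ValueError("csf_border_index must be < wm_border_index")

    @property
    def n_gm_voxels(self) -> int:
        return self.wm_border_index - self.csf_border_index

    @property
    def gm_slice(self) -> slice:
        return slice(self.csf_border_index, self.wm_border_index)

    def depth_fractions(self) -> np.ndarray:
        """Relative cortical depth of each GM voxel center in [0, 1]."""
        i = np.arange(self.n_gm_voxels)
        return (i + 0.5) / self.n_gm_voxels


def collapse_segmentation(mask_2d: np.ndarray, axis: int = 1) -> np.ndarray:
    """Collapse a 2D segmentation to its center line along ``axis``."""
    mask_2d = np.asarray(mask_2d)
    if mask_2d.ndim != 2:
        raise ValueError("expected a 2D mask")
    center = mask_2d.shape[axis] // 2
    line = np.take(mask_2d, center, axis=axis)
    if not np.any(line):
        raise SegmentationError("center row of the segmentation is empty")
    return line


def find_csf_border(
    magnitude: np.ndarray,
    initial_labels: np.ndarray,
    search_voxels: int = 3,
) -> int:
    """CSF/GM border index from the bright pial voxel near a label edge.

    Searches within ``search_voxels`` of both edges of the initial
    gray-matter label run for the local magnitude maximum; the border is
    placed just inside that bright CSF voxel, on the side facing the
    labeled run.  Ties between equally bright candidates at both edges
    break toward the lower-index edge.
    """
    mag = np.asarray(magnitude, float)
    labels = np.asarray(initial_labels, bool)
    if mag.shape != labels.shape:
        raise ValueError("magnitude and labels must share one grid")
    run = np.flatnonzero(labels)
    if run.size == 0:
        raise SegmentationError("initial labels contain no gray matter")
    lo_edge, hi_edge = int(run[0]), int(run[-1])

    n = mag.size
    best = None  # (peak magnitude, edge order, border index)
    for order, (edge, inward) in enumerate([(lo_edge, +1), (hi_edge, -1)]):
        sl = slice(max(edge - search_voxels, 0), min(edge + search_voxels + 1, n))
        idx = np.arange(sl.start, sl.stop)
        peak_pos = idx[np.argmax(mag[sl])]
        border = peak_pos + 1 if inward > 0 else peak_pos - 1
        if not 0 <= border < n:
            continue
        cand = (float(mag[peak_pos]), -order, border)
        if best is None or cand > best:
            best = cand
    if best is None:
        raise SegmentationError("no magnitude peak near either label edge")
    return int(best[2])


def find_wm_border(
    unwrapped_phase: np.ndarray,
    csf_index: int,
    max_depth_voxels: int = 16,
    voxel_mm: float = 0.39,
    fallback_thickness_mm: float = 3.3,
    jump_factor: float = 4.0,
    tail_voxels: int = 6,
) -> tuple[int, str]:
    """GM/WM border from the phase step, with a thickness fallback.

    The border is located as a least-squares change point: for every
    candidate depth the phase over the cortical segment (plus
    ``tail_voxels`` of presumptive white matter) is modeled as two
    constants separated by a step, and the candidate minimizing the
    residual wins.  The step is accepted only when its magnitude exceeds
    ``jump_factor`` times its own standard error (so pure noise, or a
    phantom without a phase step, falls through); otherwise the border
    falls back to ``csf_index + round(fallback_thickness_mm / voxel_mm)``.

    Returns ``(wm_border_index, method)``.
    """
    phase = np.asarray(unwrapped_phase, float)
    n = phase.size
    if not 0 <= csf_index < n - 1:
        raise SegmentationError("csf_index outside the line")
    hi = min(csf_index + max_depth_voxels + tail_voxels, n)
    seg = phase[csf_index:hi]
    m = seg.size
    if m < 5:
        fallback = min(max(csf_index + 1, csf_index + 1), n - 1)
        return fallback, "thickness_fallback"
    i = np.arange(m)
    best = None
    for j in range(2, min(max_depth_voxels, m - 2)):
        x = np.column_stack([np.ones(m), (i >= j).astype(float)])
        beta, *_ = np.linalg.lstsq(x, seg, rcond=None)
        rss = float(np.sum((seg - x @ beta) ** 2))
        if best is None or rss < best[0]:
            cov = np.linalg.inv(x.T @ x)
            se = np.sqrt(max(rss / max(m - 2, 1) * cov[-1, -1], 1e-300))
            best = (rss, j, float(beta[-1]), se)
    _, j, step, se = best
    if abs(step) / se > jump_factor:
        return csf_index + j, "phase_jump"
    fallback = csf_index + int(round(fallback_thickness_mm / voxel_mm))
    fallback = min(max(fallback, csf_index + 1), n - 1)
    return fallback, "thickness_fallback"


def segment_line(
    magnitude: np.ndarray,
    unwrapped_phase: np.ndarray,
    initial_labels: np.ndarray,
    voxel_mm: float = 0.39,
    fallback_thickness_mm: float = 3.3,
    max_depth_voxels: int = 16,
    jump_factor: float = 4.0,
) -> GmSegment:
    """Full segmentation: CSF border from magnitude, WM border from phase."""
    try:
        csf = find_csf_border(magnitude, initial_labels)
    except SegmentationError:
        csf = int(np.flatnonzero(np.asarray(initial_labels, bool))[0])
    wm, method = find_wm_border(
        unwrapped_phase,
        csf,
        max_depth_voxels=max_depth_voxels,
        voxel_mm=voxel_mm,
        fallback_thickness_mm=fallback_thickness_mm,
        jump_factor=jump_factor,
    )
    return GmSegment(csf_border_index=csf, wm_border_index=wm, method=method)
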