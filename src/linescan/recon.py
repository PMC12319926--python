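"""Reconstruction: FFT, coil combination, echo weighting, phase unwrapping.

The functional (1D) path transforms each readout line to image space,
combines coils by root-sum-of-squares (RSS) and combines echoes with
T2*-matched weights.  The structural (2D) path keeps the complex signal:
coils are combined with an unaccelerated SENSE (SENSE-1) combination that
preserves the object phase needed for gray/white matter segmentation.

FFT convention: centered k-space and centered image (fftshift style),
unitary scaling, inverse transform for reconstruction.  The convention is
fixed so reconstructions are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "fft_centered",
    "ifft_centered",
    "recon_1d",
    "recon_2d",
    "rss_combine",
    "sense1_combine",
    "estimate_sensitivities",
    "EchoWeighting",
    "echo_combine",
    "unwrap_phase_1d",
    "ReconLine",
    "reconstruct_functional",
]


def fft_centered(img: np.ndarray, axis: int = 0) -> np.ndarray:
    """Forward transform, centered image -> centered k-space (unitary)."""
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(img, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def ifft_centered(ksp: np.ndarray, axis: int = 0) -> np.ndarray:
    """Inverse transform, centered k-space -> centered image (unitary)."""
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(ksp, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def recon_1d(kspace: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reconstruct a readout line (or stack of lines) from k-space."""
    kspace = np.asarray(kspace)
    if kspace.shape[axis] == 0:
        raise ValueError("empty readout dimension")
    return ifft_centered(kspace, axis=axis)


def recon_2d(kspace: np.ndarray, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Reconstruct a 2D image: inverse transform along read and phase axes."""
    out = np.asarray(kspace)
    for ax in axes:
        if out.shape[ax] == 0:
            raise ValueError("empty k-space dimension")
        out = ifft_centered(out, axis=ax)
    return out


def rss_combine(coil_data: np.ndarray, axis: int = 0) -> np.ndarray:
    """Root-sum-of-squares magnitude combination across the coil axis."""
    coil_data = np.asarray(coil_data)
    if coil_data.shape[axis] < 1:
        raise ValueError("need at least one coil")
    return np.sqrt(np.sum(np.abs(coil_data) ** 2, axis=axis))


def sense1_combine(
    coil_images: np.ndarray, sensitivities: np.ndarray
) -> np.ndarray:
    """Unaccelerated SENSE combination preserving the object phase.

    Per voxel the least-squares estimate sum(conj(S_c) I_c) / sum(|S_c|^2).
    Voxels where every sensitivity is zero produce 0 with a warning.
    """
    coil_images = np.asarray(coil_images, complex)
    sens = np.asarray(sensitivities, complex)
    if coil_images.shape[0] != sens.shape[0]:
        raise ValueError("coil count mismatch")
    num = np.sum(np.conj(sens) * coil_images, axis=0)
    den = np.sum(np.abs(sens) ** 2, axis=0)
    zero = den == 0
    if np.any(zero):
        warnings.warn("all-zero sensitivity voxels set to 0", stacklevel=2)
        den = np.where(zero, 1.0, den)
        num = np.where(zero, 0.0, num)
    return num / den


def estimate_sensitivities(
    calibration_images: np.ndarray,
    mask: np.ndarray | None = None,
    smooth_voxels: float = 3.0,
) -> np.ndarray:
    """Ratio-based coil sensitivity estimate from an unsaturated scan.

    Each coil image is divided by the RSS across coils and spatially
    smoothed; background voxels (below 5 % of the peak RSS, unless an
    explicit mask is given) are masked out.  The RSS of the result is ~1
    over tissue.  This replaces eigenvalue-based calibration, which is not
    the point of this toolkit.
    """
    imgs = np.asarray(calibration_images, complex)
    if imgs.ndim != 2:
        raise ValueError("expected (coil, voxel) calibration images")
    rss = rss_combine(imgs, axis=0)
    if not np.any(rss > 0):
        raise ValueError("calibration image carries no signal")
    if mask is None:
        mask = rss > 0.05 * rss.max()
    raw = np.where(mask, imgs / np.where(rss == 0, 1.0, rss), 0.0)
    smoothed = gaussian_filter1d(raw.real, smooth_voxels, axis=1) + 1j * (
        gaussian_filter1d(raw.imag, smooth_voxels, axis=1)
    )
    # renormalize so RSS over tissue is ~1 despite smoothing into background
    rss_s = rss_combine(smoothed, axis=0)
    out = np.where(mask, smoothed / np.where(rss_s == 0, 1.0, rss_s), 0.0)
    return out


@dataclass(frozen=True)
class EchoWeighting:
    """T2*-matched echo weights w(TE) = TE * exp(-TE / T2*), unit sum."""

    echo_times_ms: tuple[float, ...]
    target_t2star_ms: float = 25.0

    @property
    def weights(self) -> np.ndarray:
        te = np.asarray(self.echo_times_ms, float)
        w = te * np.exp(-te / self.target_t2star_ms)
        return w / w.sum()


def echo_combine(echo_lines: np.ndarray, weighting: EchoWeighting) -> np.ndarray:
    """Weighted sum across the echo axis (first axis)."""
    lines = np.asarray(echo_lines)
    w = weighting.weights
    if lines.shape[0] != w.size:
        raise ValueError(
            f"{lines.shape[0]} echoes but {w.size} echo times in the weighting"
        )
    return np.tensordot(w, lines, axes=(0, 0))


def unwrap_phase_1d(phase: np.ndarray) -> np.ndarray:
    """Unwrap a 1D phase line: successive differences within (-pi, pi].

    Output differs from the input by integer multiples of 2 pi per voxel.
    """
    from skimage.restoration import unwrap_phase

    phase = np.asarray(phase, float)
    out = np.asarray(unwrap_phase(phase), float)
    # pin the first sample to the input (the unwrapper fixes only the
    # phase differences, not the global 2-pi branch)
    out = out - 2 * np.pi * np.round((out[0] - phase[0]) / (2 * np.pi))
    return out


@dataclass
class ReconLine:
    """Reconstructed functional line: magnitude per (readout voxel, TR)."""

    magnitude: np.ndarray  # echo-combined RSS magnitude, (voxel, TR)
    first_echo_magnitude: np.ndarray  # RSS of the first echo, (voxel, TR)
    echo_magnitudes: np.ndarray  # (echo, voxel, TR)
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


def reconstruct_functional(
    kspace: np.ndarray, weighting: EchoWeighting
) -> ReconLine:
    """Full functional path: 1D FFT -> RSS over coils -> echo combination.

    ``kspace`` has layout (coil, echo, readout sample, TR).
    """
    imgs = recon_1d(kspace, axis=2)
    per_echo = rss_combine(imgs, axis=0)  # (echo, voxel, TR)
    combined = echo_combine(per_echo, weighting)
    return ReconLine(
        magnitude=combined,
        first_echo_magnitude=per_echo[0],
        echo_magnitudes=per_echo,
        provenance=("ifft_readout", "rss_coils", "echo_weighted"),
    )
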