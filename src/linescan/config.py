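"""Pipeline configuration with acquisition-protocol defaults.

Defaults mirror the functional line-scan protocol: 224 mm readout FOV at
0.39 mm, TR 250 ms, echoes 14/25/36/47 ms, a 20 s-on/20 s-off tapping
block design with 8 trials, echo combination targeted at T2* = 25 ms, a
30-voxel alignment window, the >3-voxel motion-rejection rule, 24 depth
bins and the M1 layer scheme.  The configuration serializes to/from JSON
so a run directory can be re-executed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # grid
    fov_mm: float = 224.0
    voxel_mm: float = 0.39
    # phantom
    gm_thickness_mm: float = 3.3
    phase_step_rad: float = 0.3
    # acquisition / paradigm
    tr_s: float = 0.25
    echo_times_ms: tuple[float, ...] = (14.0, 25.0, 36.0, 47.0)
    n_trials: int = 8
    on_duration_s: float = 20.0
    off_duration_s: float = 20.0
    baseline_duration_s: float = 20.0
    n_coils: int = 8
    noise_sd: float = 0.02
    # recon
    target_t2star_ms: float = 25.0
    # alignment / QC
    alignment_window_voxels: int = 30
    max_shift_voxels: int = 15
    motion_rejection_voxels: int = 3
    # segmentation
    csf_search_voxels: int = 3
    phase_jump_factor: float = 4.0
    fallback_thickness_mm: float = 3.3
    # analysis
    box_kernel_trs: int = 7
    baseline_window_s: float = 10.0
    n_depth_bins: int = 24
    strong_filter_width_s: float = 3.0
    hrf_segment_s: float = 20.0
    # reproducibility
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        lists_to_tuples = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**lists_to_tuples)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
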