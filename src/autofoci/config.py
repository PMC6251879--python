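"""Run configuration: the small set of user-defined parameters.

Defaults match the acquisition regime the pipeline was designed for:
120 x 120 px single-cell crops of 8-bit images, a local-maximum radius of
3 px, a minimum object area of 3 px, a minimum per-pixel intensity of 1.1x
the nucleus mean, and a 10 px structuring-element diameter for the top-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    local_max_radius_px: float = 3.0
    min_object_area_px: int = 3
    pixel_intensity_factor: float = 1.1
    tophat_diameter_px: float = 10.0
    crop_size_px: int = 120
    bit_depth: int = 8
    histogram_bins: int = 60
    histogram_smooth_bins: float = 2.0
    step_decay: float = 0.8
    max_iterations: int = 60
    convergence_sd_fraction: float = 0.05
    convergence_window: int = 6
    pearson_min: float = 0.4
    valley_prominence: float = 0.10
    g1_gate_k_mad: float = 2.5
    rng_seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
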