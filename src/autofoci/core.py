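"""Core data containers shared across the pipeline stages.

The pipeline operates on three levels of granularity: a microscope *field*
(one DAPI plane plus two five-plane marker z-stacks), a *single-cell image*
(a fixed-size crop around one nucleus with one selected best plane per
marker channel), and a *detected object* (a candidate focus or background
signal inside one cell).

Conventions: pixel coordinates are 0-based ``(row, col)``; crop windows are
half-open; raw images are 8-bit grey values 0-255 unless a float pathway is
requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Number of z-planes acquired per damage-marker channel.
N_PLANES = 5


@dataclass
class FieldImage:
    """One microscope field: DAPI plane and two marker z-stacks.

    Attributes
    ----------
    dapi : ndarray, shape (H, W)
        DNA-stain plane used for nucleus segmentation.
    red_stack : ndarray, shape (5, H, W)
        53BP1 marker z-stack.
    green_stack : ndarray, shape (5, H, W)
        gammaH2AX marker z-stack.
    name : str
        Identifier used in output tables and file names.
    """

    dapi: np.ndarray
    red_stack: np.ndarray
    green_stack: np.ndarray
    name: str = "field"

    def __post_init__(self) -> None:
        if self.red_stack.shape[0] != N_PLANES or self.green_stack.shape[0] != N_PLANES:
            raise ValueError(
                f"marker stacks must have exactly {N_PLANES} planes, got "
                f"{self.red_stack.shape[0]} / {self.green_stack.shape[0]}"
            )
        if not (self.dapi.shape == self.red_stack.shape[1:] == self.green_stack.shape[1:]):
            raise ValueError("all planes of a field must share the same 2-D shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape


@dataclass
class SingleCellImage:
    """Per-nucleus crop with one selected best plane per marker channel.

    ``mask`` is a boolean array over the crop window; the nucleus statistics
    (mean intensity ``I_nucl`` and intensity standard deviation per channel)
    are computed over mask pixels of the best planes and feed the per-object
    score and the channel weighting factor.
    """

    cell_id: str
    mask: np.ndarray
    dapi: np.ndarray
    red: np.ndarray
    green: np.ndarray
    origin: tuple[int, int]
    red_plane_index: int
    green_plane_index: int
    i_nucl_red: float
    i_nucl_green: float
    i_std_red: float
    i_std_green: float
    dapi_sum: float
    gate_verdict: str = "ungated"

    @property
    def n_mask_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DetectedObject:
    """A candidate signal: local-maximum seed plus the grown pixel set.

    Objects are delimited on the red (53BP1) best plane; features are later
    extracted on both channels at the same pixel coordinates.
    """

    object_id: int
    seed: tuple[int, int]
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    cell_id: str = ""
    features: dict = field(default_factory=dict)

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class OEPRecord:
    """Per-object evaluation scores.

    ``oep_red`` / ``oep_green`` are the single-channel scores, ``w`` the
    per-cell channel weight (red-to-green intensity-spread ratio), ``oep``
    the combined score, and ``log_oep`` / ``inv_log_oep`` the histogram
    representations (base-10 logarithm and its reciprocal).
    """

    cell_id: str
    object_id: int
    oep_red: float
    oep_green: float
    w: float
    oep: float
    log_oep: Optional[float] = None
    inv_log_oep: Optional[float] = None
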