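"""Object evaluation parameter (OEP): per-object scoring.

Each detected object receives one score per marker channel,

    OEP_channel = (I_TH / I_nucl) * I_LC * C,

where ``I_TH`` is the mean of the object's three brightest pixels in the
top-hat image, ``I_LC`` the mean of its three brightest pixels in the
local-curvature image, ``I_nucl`` the mean nucleus intensity of that
channel, and ``C`` the object's compactness — the inverse of its
intensity-weighted moment of inertia,

    C = 1 / sum_i r_i^2 I_i,

with ``r_i`` the distance of pixel ``i`` from the intensity-weighted
centroid.  The two channel scores are combined with a per-cell weighting
factor ``w`` (the ratio of the intensity standard deviations of the two
channels within the nucleus, typically 0.9-1.2),

    OEP = OEP_red**w * OEP_green**(1/w),

so the channel with the crisper staining carries more weight.  Because
background speckles are channel-independent while genuine foci co-localize,
the product collapses the score of single-channel signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DetectedObject, OEPRecord, SingleCellImage
from . import transforms

#: Compactness assigned to degenerate objects (single pixel or zero second
#: moment) when no >= 2-pixel object exists in the same cell to cap against.
DEGENERATE_C_CAP = 1e3


class DegenerateChannelError(ValueError):
    """Raised when a channel has zero intensity spread within the nucleus."""


@dataclass
class ChannelFeatures:
    """Raw ingredients of one channel's OEP for one object."""

    i_th: float
    i_lc: float
    i_nucl: float
    c: float


def compactness(pixels: np.ndarray, channel_image: np.ndarray) -> float:
    """Inverse intensity-weighted second moment about the object centroid.

    Returns ``inf`` for the degenerate case (all mass at the centroid);
    callers cap it, see :func:`score_objects`.
    """
    if pixels.shape[0] == 0:
        raise ValueError("object has no pixels")
    intens = np.asarray(channel_image, dtype=float)[pixels[:, 0], pixels[:, 1]]
    total = intens.sum()
    if total <= 0:
        return math.inf
    centre = (intens[:, None] * pixels).sum(axis=0) / total
    r2 = ((pixels - centre) ** 2).sum(axis=1)
    denom = float((r2 * intens).sum())
    if denom == 0.0:
        return math.inf
    return 1.0 / denom


def _top3_mean(pixels: np.ndarray, image: np.ndarray) -> float:
    vals = np.asarray(image, dtype=float)[pixels[:, 0], pixels[:, 1]]
    k = min(3, vals.size)
    return float(np.sort(vals)[-k:].mean())


def channel_oep(features: ChannelFeatures) -> float:
    """Single-channel score; a negative local-curvature response (an
    anti-blob) is clamped to zero so such objects rank below every focus."""
    if features.i_nucl <= 0:
        raise ValueError("nucleus mean intensity must be positive")
    i_lc = max(features.i_lc, 0.0)
    return (features.i_th / features.i_nucl) * i_lc * features.c


def weight_factor(cell: SingleCellImage) -> float:
    """Per-cell channel weight w = I_STDred / I_STDgreen."""
    if cell.i_std_green == 0:
        raise DegenerateChannelError(f"cell {cell.cell_id}: constant green channel")
    if cell.i_std_red == 0:
        raise DegenerateChannelError(f"cell {cell.cell_id}: constant red channel")
    return cell.i_std_red / cell.i_std_green


def combined_oep(oep_red: float, oep_green: float, w: float) -> float:
    """Weighted geometric combination OEP_red**w * OEP_green**(1/w)."""
    if w <= 0:
        raise ValueError("weight factor must be positive")
    if oep_red < 0 or oep_green < 0:
        raise ValueError("channel OEPs must be non-negative")
    return oep_red**w * oep_green ** (1.0 / w)


def score_objects(
    cell: SingleCellImage,
    objects: list[DetectedObject],
    tophat_diameter: float = 10.0,
) -> list[OEPRecord]:
    """Compute channel and combined OEPs for every object of one cell.

    Compactness uses the raw best-plane intensities of each channel; the
    degenerate single-pixel case is capped at the largest compactness seen
    among >= 2-pixel objects of the same cell (fixed fallback cap when there
    is none).  Intermediate per-channel features are stashed on each
    object's ``features`` dict for benchmarking.
    """
    if not objects:
        return []
    w = weight_factor(cell)
    planes = {"red": np.asarray(cell.red, float), "green": np.asarray(cell.green, float)}
    th = {ch: transforms.top_hat(img, tophat_diameter) for ch, img in planes.items()}
    lc = {ch: transforms.local_curvature(img) for ch, img in planes.items()}
    i_nucl = {"red": cell.i_nucl_red, "green": cell.i_nucl_green}

    raw_c: dict[str, list[float]] = {"red": [], "green": []}
    for obj in objects:
        for ch in ("red", "green"):
            raw_c[ch].append(compactness(obj.pixels, planes[ch]))
    # cap degenerate compactness at the per-cell maximum finite value
    cap: dict[str, float] = {}
    for ch in ("red", "green"):
        finite = [c for c in raw_c[ch] if math.isfinite(c)]
        cap[ch] = max(finite) if finite else DEGENERATE_C_CAP

    records: list[OEPRecord] = []
    for k, obj in enumerate(objects):
        per_channel: dict[str, float] = {}
        for ch in ("red", "green"):
            c = raw_c[ch][k]
            if not math.isfinite(c):
                c = cap[ch]
            feats = ChannelFeatures(
                i_th=_top3_mean(obj.pixels, th[ch]),
                i_lc=_top3_mean(obj.pixels, lc[ch]),
                i_nucl=i_nucl[ch],
                c=c,
            )
            per_channel[ch] = channel_oep(feats)
            obj.features[f"i_th_{ch}"] = feats.i_th
            obj.features[f"i_lc_{ch}"] = feats.i_lc
            obj.features[f"c_{ch}"] = feats.c
            obj.features[f"mean_raw_{ch}"] = float(
                planes[ch][obj.pixels[:, 0], obj.pixels[:, 1]].mean()
            )
        oep = combined_oep(per_channel["red"], per_channel["green"], w)
        records.append(
            OEPRecord(
                cell_id=cell.cell_id,
                object_id=obj.object_id,
                oep_red=per_channel["red"],
                oep_green=per_channel["green"],
                w=w,
                oep=oep,
            )
        )
    return records


def attach_log_scores(records: list[OEPRecord]) -> None:
    """Fill ``log_oep`` (base 10) and ``inv_log_oep`` in place.

    Zero or negative combined scores are floored at the smallest positive
    OEP in the sample before taking the logarithm, so every object stays in
    the histogram pipeline.  The reciprocal representation ``1 / log10`` is
    defined only for OEP > 1; other objects get ``inv_log_oep = None`` and
    are simply excluded from that histogram.
    """
    positives = [r.oep for r in records if r.oep > 0]
    if not positives:
        for r in records:
            r.log_oep = None
            r.inv_log_oep = None
        return
    floor = min(positives)
    for r in records:
        val = r.oep if r.oep > 0 else floor
        r.log_oep = math.log10(val)
        r.inv_log_oep = 1.0 / r.log_oep if val > 1.0 and r.log_oep != 0 else None
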