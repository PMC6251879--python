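"""Field preprocessing: nucleus segmentation, single-cell cropping, best
z-plane selection and G0/G1 gating.

Nuclei are located on the DAPI plane (Gaussian smoothing, Otsu threshold,
hole filling, distance-transform watershed to split touching nuclei, area
gate).  Each nucleus is cropped in all channels with a fixed window centred
on the mask centroid; nuclei whose window would leave the field are dropped.
For each marker channel the best of the five z-planes is the one maximising
the ratio of total Sobel gradient magnitude to total raw intensity within
the nucleus mask — an edge-contrast measure that peaks at the focal plane.
Finally, cells with abnormal DNA content (S/G2 doubling, dying-cell
signatures) or pan-nuclear gammaH2AX signal are excluded from analysis.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .core import FieldImage, SingleCellImage
from .transforms import sobel_magnitude

__all__ = ["segment_nuclei", "crop_cells", "select_best_plane", "filter_g1"]


class InvalidCellError(ValueError):
    """Raised when no valid best plane exists for a cell."""


def segment_nuclei(
    dapi: np.ndarray,
    min_area: int = 60,
    max_area: int | None = None,
    smoothing_sigma: float = 2.0,
) -> list[np.ndarray]:
    """Segment nuclei on the DAPI plane; returns a list of boolean masks.

    Touching nuclei are split by a watershed on the distance transform
    seeded at its regional maxima.  Masks outside ``[min_area, max_area]``
    are discarded.  Deterministic; an all-zero image yields an empty list.
    """
    img = np.asarray(dapi, dtype=float)
    if img.max() <= 0:
        return []
    smoothed = gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    try:
        thr = threshold_otsu(smoothed)
    except ValueError:  # constant image
        return []
    binary = smoothed > thr
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return []
    distance = ndi.distance_transform_edt(binary)
    # seeds: regional maxima of the smoothed distance map, one per nucleus
    dsmooth = gaussian(distance, sigma=2.0, preserve_range=True)
    seeds_mask = (dsmooth == ndi.maximum_filter(dsmooth, size=9)) & binary & (dsmooth > 2)
    markers, n_seeds = ndi.label(seeds_mask)
    if n_seeds == 0:
        labels = label(binary)
    else:
        # collapse seed plateaus to single markers before the watershed
        labels = watershed(-dsmooth, markers=markers, mask=binary)
    masks = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        if max_area is not None and region.area > max_area:
            continue
        masks.append(labels == region.label)
    # stable order: by centroid (row, col)
    masks.sort(key=lambda m: tuple(np.argwhere(m).mean(axis=0).tolist()))
    return masks


def _crop_window(centroid: tuple[float, float], size: int) -> tuple[int, int]:
    r0 = int(round(centroid[0])) - size // 2
    c0 = int(round(centroid[1])) - size // 2
    return r0, c0


def select_best_plane(stack: np.ndarray, mask: np.ndarray) -> int:
    """Index of the sharpest plane: argmax over planes of (Sobel-magnitude
    sum within the mask) / (raw-intensity sum within the mask).

    Planes with zero raw intensity inside the mask are excluded; if all are,
    an :class:`InvalidCellError` is raised.  Ties break to the lowest index,
    and the ratio construction makes the choice invariant under a positive
    rescaling of the whole stack.
    """
    if not mask.any():
        raise InvalidCellError("empty nucleus mask")
    best_idx, best_ratio = None, -np.inf
    for idx in range(stack.shape[0]):
        plane = np.asarray(stack[idx], dtype=float)
        raw_sum = plane[mask].sum()
        if raw_sum <= 0:
            continue
        ratio = sobel_magnitude(plane)[mask].sum() / raw_sum
        if ratio > best_ratio:
            best_idx, best_ratio = idx, ratio
    if best_idx is None:
        raise InvalidCellError("no plane with positive intensity within the mask")
    return best_idx


def crop_cells(
    field: FieldImage, masks: list[np.ndarray], crop_size: int = 120
) -> list[SingleCellImage]:
    """Cut one fixed-size single-cell image per nucleus mask.

    The window is centred on the mask centroid; masks whose window would be
    clipped at the field border are dropped.  Raw pixels are copied
    bit-exactly from the field.  Nucleus statistics (per-channel mean and
    standard deviation over mask pixels of the selected best planes, and the
    DAPI integrated intensity) are filled in here.
    """
    h, w = field.shape
    cells: list[SingleCellImage] = []
    for k, mask in enumerate(masks):
        coords = np.argwhere(mask)
        centroid = coords.mean(axis=0)
        r0, c0 = _crop_window((centroid[0], centroid[1]), crop_size)
        if r0 < 0 or c0 < 0 or r0 + crop_size > h or c0 + crop_size > w:
            continue  # border cell
        bbox_h = int(np.ptp(coords[:, 0])) + 1
        bbox_w = int(np.ptp(coords[:, 1])) + 1
        if bbox_h > crop_size or bbox_w > crop_size:
            raise ValueError(
                f"crop size {crop_size} smaller than mask bounding box "
                f"({bbox_h}x{bbox_w})"
            )
        win = (slice(r0, r0 + crop_size), slice(c0, c0 + crop_size))
        mask_crop = mask[win]
        dapi_crop = field.dapi[win].copy()
        red_stack = field.red_stack[(slice(None),) + win]
        green_stack = field.green_stack[(slice(None),) + win]
        try:
            red_idx = select_best_plane(red_stack, mask_crop)
            green_idx = select_best_plane(green_stack, mask_crop)
        except InvalidCellError:
            continue
        red = red_stack[red_idx].copy()
        green = green_stack[green_idx].copy()
        red_vals = red[mask_crop].astype(float)
        green_vals = green[mask_crop].astype(float)
        cells.append(
            SingleCellImage(
                cell_id=f"{field.name}_c{k:03d}",
                mask=mask_crop.copy(),
                dapi=dapi_crop,
                red=red,
                green=green,
                origin=(r0, c0),
                red_plane_index=red_idx,
                green_plane_index=green_idx,
                i_nucl_red=float(red_vals.mean()),
                i_nucl_green=float(green_vals.mean()),
                i_std_red=float(red_vals.std()),
                i_std_green=float(green_vals.std()),
                dapi_sum=float(dapi_crop[mask_crop].astype(float).sum()),
            )
        )
    return cells


def filter_g1(
    cells: list[SingleCellImage],
    k_mad: float = 2.5,
    min_cells: int = 10,
) -> list[SingleCellImage]:
    """Retain the G0/G1 population; exclude S/G2 and dying cells.

    The gate mirrors the manual DAPI-vs-gammaH2AX histogram selection: the
    G1 mode of log DAPI integrated intensity is estimated robustly (kernel
    density argmax) and cells outside mode +/- ``k_mad`` * MAD are removed,
    as are cells whose gammaH2AX nucleus mean exceeds the population median
    by more than ``k_mad`` MADs (pan-nuclear signal of dying cells).  With
    fewer than ``min_cells`` cells the gate is refused and every cell is
    flagged ``ungated``.
    """
    if not cells:
        return []
    if len(cells) < min_cells:
        for cell in cells:
            cell.gate_verdict = "ungated"
        return list(cells)
    log_dapi = np.log10(np.asarray([c.dapi_sum for c in cells], dtype=float))
    from scipy.stats import gaussian_kde

    grid = np.linspace(log_dapi.min(), log_dapi.max(), 512)
    if np.ptp(log_dapi) == 0:
        mode = log_dapi[0]
    else:
        kde = gaussian_kde(log_dapi)
        mode = grid[int(np.argmax(kde(grid)))]
    mad_d = np.median(np.abs(log_dapi - np.median(log_dapi)))
    mad_d = max(mad_d, 1e-6)
    green_mean = np.asarray([c.i_nucl_green for c in cells], dtype=float)
    med_g = np.median(green_mean)
    mad_g = max(np.median(np.abs(green_mean - med_g)), 1e-6)

    retained = []
    for cell, ld, gm in zip(cells, log_dapi, green_mean):
        if abs(ld - mode) > k_mad * mad_d:
            cell.gate_verdict = "excluded_dapi"
        elif gm > med_g + k_mad * mad_g:
            cell.gate_verdict = "excluded_gamma"
        else:
            cell.gate_verdict = "g1"
            retained.append(cell)
    return retained
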