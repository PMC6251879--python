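"""Candidate-object detection on the 53BP1 (red) best plane.

Objects — repair foci as well as unspecific background signals — are found
as local intensity maxima inside the nucleus mask and delimited by an area
growing step that connects each maximum with every adjacent pixel holding at
least half the maximum's intensity.  Two cheap filters (minimum object area,
minimum pixel intensity relative to the nucleus mean) prune the dimmest
background signals without touching genuine foci.
"""

from __future__ import annotations

import numpy as np

from .core import DetectedObject, SingleCellImage

__all__ = ["find_local_maxima", "grow_object", "detect_objects"]


def _disc_offsets(radius: float) -> np.ndarray:
    """Offsets (dr, dc) within Euclidean distance ``radius``, excluding (0, 0)."""
    n = int(np.floor(radius))
    offs = []
    for dr in range(-n, n + 1):
        for dc in range(-n, n + 1):
            if dr == 0 and dc == 0:
                continue
            if dr * dr + dc * dc <= radius * radius:
                offs.append((dr, dc))
    return np.asarray(offs, dtype=int)


def find_local_maxima(
    image: np.ndarray, mask: np.ndarray | None = None, radius: float = 3.0
) -> list[tuple[int, int]]:
    """Pixels strictly brighter than every other pixel within ``radius``.

    The neighbourhood is Euclidean.  Plateaus (a maximum whose neighbourhood
    contains equal-valued pixels) are kept only at the lexicographically
    smallest (row, col) member of the plateau, so 8-bit quantization cannot
    silently drop flat-topped peaks.  Pixels outside ``mask`` are ignored
    both as candidates and as competitors.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 px")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if mask is None:
        mask = np.ones_like(img, dtype=bool)
    offsets = _disc_offsets(radius)

    values = np.where(mask, img, -np.inf)
    # pass 1: pixels with no strictly greater neighbour within the radius
    candidates: set[tuple[int, int]] = set()
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows.tolist(), cols.tolist()):
        v = values[r, c]
        is_max = True
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and values[rr, cc] > v:
                is_max = False
                break
        if is_max:
            candidates.add((r, c))
    # pass 2: of equal-valued candidates within one radius (a plateau), keep
    # only the lexicographically smallest
    seeds: list[tuple[int, int]] = []
    for r, c in sorted(candidates):
        v = values[r, c]
        suppressed = False
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if (rr, cc) < (r, c) and (rr, cc) in candidates and values[rr, cc] == v:
                suppressed = True
                break
        if not suppressed:
            seeds.append((r, c))
    return seeds


def grow_object(
    image: np.ndarray,
    seed: tuple[int, int],
    mask: np.ndarray | None = None,
    intensity_floor: float = 0.0,
) -> np.ndarray:
    """Area growing: maximal 8-connected set around ``seed`` in which every
    pixel holds at least half the seed intensity ("at least half" is
    inclusive) and at least ``intensity_floor``.

    Growth never leaves the nucleus mask.  Returns an (n, 2) int array of
    (row, col) positions sorted lexicographically.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if mask is None:
        mask = np.ones_like(img, dtype=bool)
    threshold = max(0.5 * img[seed], intensity_floor)
    visited = np.zeros_like(mask, dtype=bool)
    stack = [seed]
    visited[seed] = True
    out = []
    while stack:
        r, c = stack.pop()
        out.append((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                if visited[rr, cc] or not mask[rr, cc]:
                    continue
                if img[rr, cc] >= threshold:
                    visited[rr, cc] = True
                    stack.append((rr, cc))
    out.sort()
    return np.asarray(out, dtype=int)


def detect_objects(
    cell: SingleCellImage,
    radius: float = 3.0,
    min_area: int = 3,
    intensity_factor: float = 1.1,
) -> list[DetectedObject]:
    """Detect candidate objects on the red best plane of one cell.

    Local maxima inside the nucleus mask seed an area-growing step; the
    ``intensity_factor`` times the red nucleus mean acts as a floor during
    growth (pixels below it are not connectable), and objects smaller than
    ``min_area`` pixels are discarded.  When the grown regions of two seeds
    overlap, each contested pixel goes to the seed with the higher intensity
    (ties to the smaller (row, col) seed), so object pixel sets are disjoint.
    """
    img = np.asarray(cell.red, dtype=float)
    floor = intensity_factor * cell.i_nucl_red
    seeds = find_local_maxima(img, cell.mask, radius)
    # seeds below the pixel floor can never grow a valid object
    seeds = [s for s in seeds if img[s] >= floor]
    # assign contested pixels to the brighter seed; ties to smaller (row, col)
    order = sorted(seeds, key=lambda s: (-img[s], s))
    claimed = np.zeros(img.shape, dtype=bool)
    objects: list[DetectedObject] = []
    obj_id = 0
    for seed in order:
        if claimed[seed]:
            continue
        pixels = grow_object(img, seed, cell.mask, intensity_floor=floor)
        keep = [(r, c) for r, c in pixels if not claimed[r, c]]
        if not keep:
            continue
        pix = np.asarray(keep, dtype=int)
        claimed[pix[:, 0], pix[:, 1]] = True
        if pix.shape[0] < min_area:
            continue
        objects.append(
            DetectedObject(object_id=obj_id, seed=seed, pixels=pix, cell_id=cell.cell_id)
        )
        obj_id += 1
    # stable output order: by seed position
    objects.sort(key=lambda o: o.seed)
    for i, obj in enumerate(objects):
        obj.object_id = i
    return objects
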