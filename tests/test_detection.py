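"""Oracle tests for local-maxima detection and area growing."""

from __future__ import annotations

import numpy as np
import pytest

from autofoci import detection
from tests.conftest import make_cell

N_SEEDS = 120


def _brute_maxima(img, mask, radius):
    """Exhaustive reference: strict maxima within the Euclidean radius, with
    plateau representatives at the lexicographically smallest candidate."""
    h, w = img.shape
    offs = [
        (dr, dc)
        for dr in range(-int(radius), int(radius) + 1)
        for dc in range(-int(radius), int(radius) + 1)
        if (dr, dc) != (0, 0) and dr * dr + dc * dc <= radius * radius
    ]
    vals = np.where(mask, img.astype(float), -np.inf)
    cands = set()
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            if all(
                not (0 <= r + dr < h and 0 <= c + dc < w)
                or vals[r + dr, c + dc] <= vals[r, c]
                for dr, dc in offs
            ):
                cands.add((r, c))
    keep = []
    for r, c in sorted(cands):
        if not any(
            (r + dr, c + dc) in cands
            and (r + dr, c + dc) < (r, c)
            and vals[r + dr, c + dc] == vals[r, c]
            for dr, dc in offs
        ):
            keep.append((r, c))
    return keep


def _brute_grow(img, seed, mask, floor):
    """Reference flood fill: 8-connected component of pixels >= max(half the
    seed, floor), containing the seed, within the mask."""
    img = img.astype(float)
    thr = max(0.5 * img[seed], floor)
    h, w = img.shape
    seen = {seed}
    frontier = [seed]
    while frontier:
        r, c = frontier.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                p = (r + dr, c + dc)
                if (
                    p != (r, c)
                    and 0 <= p[0] < h
                    and 0 <= p[1] < w
                    and p not in seen
                    and mask[p]
                    and img[p] >= thr
                ):
                    seen.add(p)
                    frontier.append(p)
    return sorted(seen)


@pytest.mark.parametrize("seed", range(N_SEEDS))
def test_find_local_maxima_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 40, size=(14, 14)).astype(float)  # many plateaus
    mask = rng.uniform(size=img.shape) > 0.2
    got = detection.find_local_maxima(img, mask, radius=3.0)
    assert got == _brute_maxima(img, mask, 3.0)


@pytest.mark.parametrize("seed", range(N_SEEDS))
def test_grow_object_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(12, 12)).astype(float)
    mask = rng.uniform(size=img.shape) > 0.1
    r, c = rng.integers(0, 12, size=2)
    mask[r, c] = True
    floor = float(rng.uniform(0, 100))
    got = detection.grow_object(img, (int(r), int(c)), mask, intensity_floor=floor)
    assert [tuple(p) for p in got] == _brute_grow(img, (int(r), int(c)), mask, floor)


def test_plateau_keeps_single_representative():
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 1, size=(9, 9))  # rough background, no plateaus
    img[4, 4] = img[4, 5] = 10.0  # two-pixel plateau on top
    seeds = detection.find_local_maxima(img, radius=3.0)
    assert (4, 4) in seeds  # lexicographically smallest member kept
    assert (4, 5) not in seeds


def test_half_maximum_growth_is_inclusive():
    img = np.zeros((7, 7))
    img[3, 3] = 100.0
    img[3, 4] = 50.0  # exactly half: included
    img[3, 5] = 49.9  # just below: excluded
    pix = {tuple(p) for p in detection.grow_object(img, (3, 3))}
    assert (3, 4) in pix and (3, 5) not in pix


def test_detect_objects_disjoint_and_floored():
    rng = np.random.default_rng(3)
    img = rng.uniform(8, 12, size=(40, 40))
    for r, c in [(10, 10), (10, 24), (28, 30)]:
        rr, cc = np.mgrid[0:40, 0:40]
        img += 120 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.5**2))
    cell = make_cell(img)
    objs = detection.detect_objects(cell, radius=3.0, min_area=3, intensity_factor=1.1)
    assert len(objs) == 3
    seen = set()
    floor = 1.1 * cell.i_nucl_red
    for o in objs:
        pix = {tuple(p) for p in o.pixels}
        assert not (pix & seen)  # pixel sets are disjoint
        seen |= pix
        assert img[o.seed] >= floor
        assert (img[o.pixels[:, 0], o.pixels[:, 1]] >= floor).all()
        assert o.area >= 3


def test_detect_objects_min_area_filters_specks():
    img = np.full((20, 20), 10.0)
    img[5, 5] = 100.0  # bright single pixel surrounded by nothing growable
    cell = make_cell(img)
    assert detection.detect_objects(cell, min_area=3) == []
    assert len(detection.detect_objects(cell, min_area=1)) == 1


def test_detect_objects_respects_intensity_factor():
    img = np.full((20, 20), 100.0)
    rr, cc = np.mgrid[0:20, 0:20]
    img += 8 * np.exp(-((rr - 9) ** 2 + (cc - 9) ** 2) / (2 * 1.5**2))
    cell = make_cell(img)  # peak ~108 < 1.1 * ~100
    assert detection.detect_objects(cell, intensity_factor=1.1) == []
    assert len(detection.detect_objects(cell, intensity_factor=1.0)) == 1


def test_radius_validation():
    with pytest.raises(ValueError):
        detection.find_local_maxima(np.zeros((5, 5)), radius=0.5)
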