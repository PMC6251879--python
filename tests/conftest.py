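"""Shared fixtures and ground-truth helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from autofoci.config import RunConfig
from autofoci.core import SingleCellImage
from autofoci.synthetic import SyntheticSpec, generate_field
from autofoci import pipeline


def make_cell(
    red: np.ndarray,
    green: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    cell_id: str = "test_c000",
) -> SingleCellImage:
    """Build a SingleCellImage directly from arrays, bypassing segmentation."""
    red = np.asarray(red, dtype=float)
    green = red.copy() if green is None else np.asarray(green, dtype=float)
    if mask is None:
        mask = np.ones(red.shape, dtype=bool)
    rv, gv = red[mask], green[mask]
    return SingleCellImage(
        cell_id=cell_id,
        mask=mask,
        dapi=np.full(red.shape, 100.0),
        red=red,
        green=green,
        origin=(0, 0),
        red_plane_index=0,
        green_plane_index=0,
        i_nucl_red=float(rv.mean()),
        i_nucl_green=float(gv.mean()),
        i_std_red=float(rv.std()),
        i_std_green=float(gv.std()),
        dapi_sum=float(mask.sum() * 100.0),
    )


def build_sample(n_fields: int, seed0: int = 0, **spec_kw):
    """Generate fields, run segmentation/cropping/gating/detection/scoring.

    Returns (fields, truths, g1_cells, objects, records).
    """
    fields, truths = [], []
    for i in range(n_fields):
        spec = SyntheticSpec(rng_seed=seed0 + i, **spec_kw)
        f, gt = generate_field(spec)
        fields.append(f)
        truths.append(gt)
    cfg = RunConfig()
    _, g1 = pipeline.process_fields(fields, cfg)
    objects, records, _ = pipeline.score_sample(g1, cfg)
    return fields, truths, g1, objects, records


def label_objects(fields, truths, g1, objects, match_px: float = 3.0):
    """Ground-truth binary labels: an object is a focus iff its seed lies
    within ``match_px`` of a planted focus centre.  Returns a dict keyed by
    (cell_id, object_id)."""
    truth_foci = [
        (f.name, fr, fc)
        for f, gt in zip(fields, truths)
        for n in gt.nuclei
        for fr, fc, _a, _ch in n.foci
    ]
    cellmap = {c.cell_id: c for c in g1}
    out = {}
    for obj in objects:
        c = cellmap[obj.cell_id]
        fname = obj.cell_id.rsplit("_c", 1)[0]
        r = obj.seed[0] + c.origin[0]
        col = obj.seed[1] + c.origin[1]
        out[(obj.cell_id, obj.object_id)] = any(
            fn == fname and (fr - r) ** 2 + (fc - col) ** 2 < match_px**2
            for fn, fr, fc in truth_foci
        )
    return out


def planted_foci_per_cell(fields, truths, g1, crop_size: int = 120) -> float:
    """Planted foci per analyzed cell: foci whose centre falls inside the
    nucleus mask of a retained (G1-gated, non-border) cell."""
    n = 0
    for f, gt in zip(fields, truths):
        cells = [c for c in g1 if c.cell_id.rsplit("_c", 1)[0] == f.name]
        for nu in gt.nuclei:
            for fr, fc, _a, _ch in nu.foci:
                if any(
                    c.origin[0] <= fr < c.origin[0] + crop_size
                    and c.origin[1] <= fc < c.origin[1] + crop_size
                    and c.mask[int(fr) - c.origin[0], int(fc) - c.origin[1]]
                    for c in cells
                ):
                    n += 1
    return n / len(g1)


@pytest.fixture(scope="session")
def small_sample():
    """One modest sample reused by pipeline-level tests (kept small)."""
    return build_sample(4, seed0=7, foci_per_cell=1.0, speckle_rate=15.0)
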