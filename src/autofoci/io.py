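"""Reading and writing the pipeline's file formats.

Fields travel as multi-page TIFF (default page order: DAPI, red z1-z5,
green z1-z5 — 11 pages); tables as headed CSV with '.' decimal separator;
nested session and quality records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import FieldImage, N_PLANES, OEPRecord, SingleCellImage


class FormatError(ValueError):
    """Malformed input file (wrong page count, missing columns, ...)."""


def read_field(path: str | Path, page_order: str = "dapi,red,green") -> FieldImage:
    """Read one field from a multi-page TIFF.

    ``page_order`` names the channel blocks in page order; the DAPI block is
    one page, marker blocks five pages each.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    expected = 1 + 2 * N_PLANES
    if pages.shape[0] != expected:
        raise FormatError(
            f"{path.name}: expected {expected} pages (DAPI + 2x{N_PLANES}), got {pages.shape[0]}"
        )
    blocks: dict[str, np.ndarray] = {}
    idx = 0
    for name in page_order.split(","):
        n = 1 if name == "dapi" else N_PLANES
        block = pages[idx : idx + n]
        blocks[name] = block[0] if name == "dapi" else block
        idx += n
    return FieldImage(
        dapi=blocks["dapi"],
        red_stack=blocks["red"],
        green_stack=blocks["green"],
        name=path.stem,
    )


def cells_table(cells: list[SingleCellImage]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": c.cell_id,
            "origin_row": c.origin[0],
            "origin_col": c.origin[1],
            "red_plane": c.red_plane_index,
            "green_plane": c.green_plane_index,
            "i_nucl_red": c.i_nucl_red,
            "i_nucl_green": c.i_nucl_green,
            "i_std_red": c.i_std_red,
            "i_std_green": c.i_std_green,
            "dapi_sum": c.dapi_sum,
            "gate_verdict": c.gate_verdict,
        }
        for c in cells
    ]
    return pd.DataFrame(rows)


def records_table(records: list[OEPRecord], objects=None) -> pd.DataFrame:
    feature_map = {}
    if objects:
        for obj in objects:
            feature_map[(obj.cell_id, obj.object_id)] = obj
    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "object_id": r.object_id,
            "oep_red": r.oep_red,
            "oep_green": r.oep_green,
            "w": r.w,
            "oep": r.oep,
            "log_oep": r.log_oep,
            "inv_log_oep": r.inv_log_oep,
        }
        obj = feature_map.get((r.cell_id, r.object_id))
        if obj is not None:
            row["seed_row"], row["seed_col"] = obj.seed
            row["area"] = obj.area
            row.update(obj.features)
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
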