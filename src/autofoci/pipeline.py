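"""End-to-end pipeline runner: fields -> cells -> objects -> scores ->
threshold -> foci per cell + quality verdict."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import detection, oep, preprocess, quality, thresholding
from .config import RunConfig
from .core import DetectedObject, FieldImage, OEPRecord, SingleCellImage

log = logging.getLogger("autofoci")


@dataclass
class SampleResult:
    """Everything the pipeline produces for one sample (a set of fields)."""

    cells: list[SingleCellImage]
    g1_cells: list[SingleCellImage]
    objects: list[DetectedObject]
    records: list[OEPRecord]
    start_threshold: float | None
    threshold_parts: dict = field(default_factory=dict)
    session: thresholding.ThresholdSession | None = None
    foci_per_cell: float | None = None
    quality_metrics: quality.QualityMetrics | None = None
    quality_verdict: quality.QualityVerdict | None = None
    dropped: list[dict] = field(default_factory=list)


def process_fields(
    fields: list[FieldImage], config: RunConfig | None = None
) -> tuple[list[SingleCellImage], list[SingleCellImage]]:
    """Segment, crop and gate every field; returns (all cells, G1 cells)."""
    config = config or RunConfig()
    cells: list[SingleCellImage] = []
    for f in fields:
        masks = preprocess.segment_nuclei(f.dapi)
        cells.extend(preprocess.crop_cells(f, masks, crop_size=config.crop_size_px))
    g1 = preprocess.filter_g1(cells, k_mad=config.g1_gate_k_mad)
    return cells, g1


def score_sample(
    cells: list[SingleCellImage], config: RunConfig | None = None
) -> tuple[list[DetectedObject], list[OEPRecord], list[dict]]:
    """Detect and score objects in every cell; degenerate cells are dropped
    with a machine-readable reason."""
    config = config or RunConfig()
    objects: list[DetectedObject] = []
    records: list[OEPRecord] = []
    dropped: list[dict] = []
    for cell in cells:
        objs = detection.detect_objects(
            cell,
            radius=config.local_max_radius_px,
            min_area=config.min_object_area_px,
            intensity_factor=config.pixel_intensity_factor,
        )
        try:
            recs = oep.score_objects(cell, objs, tophat_diameter=config.tophat_diameter_px)
        except oep.DegenerateChannelError as exc:
            dropped.append({"cell_id": cell.cell_id, "reason": "degenerate_channel", "detail": str(exc)})
            continue
        objects.extend(objs)
        records.extend(recs)
    oep.attach_log_scores(records)
    return objects, records, dropped


def run_pipeline(
    fields: list[FieldImage],
    config: RunConfig | None = None,
    oracle: thresholding.RaterOracle | None = None,
) -> SampleResult:
    """Full chain on a list of fields.

    Without an ``oracle`` the automated starting threshold is used as the
    final threshold; with one, the iterative adjustment loop refines it.
    Deterministic for a fixed config and input.
    """
    config = config or RunConfig()
    cells, g1 = process_fields(fields, config)
    objects, records, dropped = score_sample(g1, config)
    result = SampleResult(
        cells=cells, g1_cells=g1, objects=objects, records=records, start_threshold=None,
        dropped=dropped,
    )
    n_cells = len([c for c in g1 if not any(d["cell_id"] == c.cell_id for d in dropped)])
    if not records or n_cells == 0:
        log.warning("no scored objects or no cells; empty result")
        return result

    metrics = quality.sample_pearson(g1)
    log_scores = np.asarray([r.log_oep for r in records if r.log_oep is not None])
    result.quality_metrics = metrics
    result.quality_verdict = quality.sample_quality(
        metrics, log_scores, pearson_min=config.pearson_min,
        min_valley_depth=config.valley_prominence,
    )

    try:
        thr, parts = thresholding.estimate_start_threshold(
            [r.oep for r in records], return_parts=True
        )
    except thresholding.NoThresholdError as exc:
        log.warning("no starting threshold: %s", exc)
        return result
    result.start_threshold = thr
    result.threshold_parts = parts

    if oracle is not None:
        session = thresholding.ThresholdSession(records=records, n_cells=n_cells, threshold=thr)
        session = thresholding.adjust_threshold(
            session,
            oracle,
            decay=config.step_decay,
            sd_fraction=config.convergence_sd_fraction,
            window=config.convergence_window,
            max_iter=config.max_iterations,
        )
        result.session = session
        result.foci_per_cell = session.final_foci_per_cell
    else:
        result.foci_per_cell = thresholding.count_foci(records, thr, n_cells)
    return result
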