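"""End-to-end orchestration: field images -> object/clump/well tables.

This is thin glue over the analysis modules; each stage remains usable on
its own.  ``process_field`` runs flatfield correction, nucleus and cell
segmentation, the selection cascade and clump tagging for a single field;
``run_study`` streams a whole (real or simulated) plate into well summaries
and the condition-level PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .aggregate import aggregate_plate
from .analysis import (
    ConditionReport,
    PCAResult,
    build_feature_matrix,
    compare_conditions,
    group_ellipse,
    run_pca,
)
from .clumps import annotate_clump_size, detect_clumps
from .filters import CascadeResult, FilterThresholds, run_cascade
from .plate_io import FieldImage, PlateLayout
from .segmentation import (
    SegmentationParams,
    flatfield_correct,
    segment_cells,
    segment_nuclei,
)

logger = logging.getLogger(__name__)


@dataclass
class FieldResult:
    """Per-field outcome: tagged object rows, clump rows, stage counts."""

    table: pd.DataFrame
    clumps: pd.DataFrame
    counts: dict[str, int]
    cascade: CascadeResult


def process_field(
    image: FieldImage,
    seg_params: SegmentationParams | None = None,
    thresholds: FilterThresholds | None = None,
    plate: str = "plate",
) -> FieldResult:
    """Segment one field and produce its final tagged object table."""
    seg_params = seg_params or SegmentationParams()
    thresholds = thresholds or FilterThresholds()
    channels = {
        name: flatfield_correct(arr) for name, arr in image.channels.items()
    }
    nuclei = segment_nuclei(channels["dapi"], seg_params, image.pixel_size_um)
    cells = segment_cells(channels["cellmask647"], nuclei, seg_params,
                          image.pixel_size_um)
    metadata = {"plate": plate, "well": image.well, "field": image.field}
    cascade = run_cascade(nuclei, cells, channels, thresholds, metadata,
                          image.pixel_size_um)
    clump_table = detect_clumps(cascade.cells_mask, image.well, image.field)
    table = annotate_clump_size(cascade.table, clump_table)
    return FieldResult(table=table, clumps=clump_table, counts=cascade.counts,
                       cascade=cascade)


@dataclass
class StudyResult:
    """Whole-plate outcome through aggregation and condition analysis."""

    objects: pd.DataFrame
    clumps: pd.DataFrame
    nuclei_objects: pd.DataFrame          # pre-filter detections (QC)
    summaries: pd.DataFrame
    counts: dict[str, int]
    pca: PCAResult | None = None
    ellipses: dict = field(default_factory=dict)
    report: ConditionReport | None = None


def process_fields(
    images: Iterable[FieldImage],
    seg_params: SegmentationParams | None = None,
    thresholds: FilterThresholds | None = None,
    plate: str = "plate",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Run the per-field pipeline over an image stream; concatenate tables."""
    object_frames, clump_frames, nuclei_frames = [], [], []
    totals = {"nuclei": 0, "nuclei2": 0, "cell_unselected": 0, "cell": 0}
    for image in images:
        result = process_field(image, seg_params, thresholds, plate=plate)
        object_frames.append(result.table)
        clump_frames.append(result.clumps)
        nuclei_frames.append(result.cascade.nuclei_table)
        for k in totals:
            totals[k] += result.counts[k]
    objects = (pd.concat(object_frames, ignore_index=True)
               if object_frames else pd.DataFrame())
    clumps = (pd.concat(clump_frames, ignore_index=True)
              if clump_frames else pd.DataFrame())
    nuclei = (pd.concat(nuclei_frames, ignore_index=True)
              if nuclei_frames else pd.DataFrame())
    return objects, clumps, nuclei, totals


def run_study(
    images: Iterable[FieldImage],
    layout: PlateLayout,
    seg_params: SegmentationParams | None = None,
    thresholds: FilterThresholds | None = None,
    plate: str = "plate",
    with_pca: bool = True,
) -> StudyResult:
    """Images -> objects -> well summaries -> condition report and PCA."""
    objects, clumps, nuclei, counts = process_fields(
        images, seg_params, thresholds, plate=plate)
    summaries = aggregate_plate(objects, clumps, layout=layout, plate=plate)
    result = StudyResult(objects=objects, clumps=clumps, nuclei_objects=nuclei,
                         summaries=summaries, counts=counts)
    if len(summaries):
        result.report = compare_conditions(summaries, objects=objects,
                                           layout=layout)
    if with_pca and len(summaries) >= 3 and len(summaries["condition"].unique()) >= 2:
        matrix, _ = build_feature_matrix(summaries)
        if len(matrix) >= 3:
            result.pca = run_pca(matrix)
            labels = [layout.condition_of(w) for w in result.pca.well_ids]
            result.ellipses = group_ellipse(result.pca.scores, labels)
    return result
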