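"""The object-selection cascade: Nuclei -> Nuclei 2 -> Cell unselected -> Cell.

Artefacts and contaminants are discarded by morphology and intensity
thresholds.  Boundary semantics follow the protocol wording: "between a and
b" is the closed interval [a, b]; "below x" and "over x" are strict.  The
cell-area ceiling removes the rare oversized feeder-cell contaminants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import build_object_table
from .segmentation import LabelMask, border_labels, subset_labels

logger = logging.getLogger(__name__)

STAGES = ("nuclei", "nuclei2", "cell_unselected", "cell")


@dataclass(frozen=True)
class FilterThresholds:
    """Object-selection thresholds (areas um^2, intensities in AU)."""

    nucleus_area_min: float = 60.0
    nucleus_area_max: float = 600.0
    edu_median_max: float = 10_000.0
    dapi_median_min: float = 500.0
    dapi_median_max: float = 10_000.0
    brightfield_min: float = 0.0   # exclusive
    cell_area_max: float = 6_000.0

    #: flip to make "below"/"over" non-strict and "between" open
    strict_bounds: bool = True

    def __post_init__(self) -> None:
        if not self.nucleus_area_min < self.nucleus_area_max:
            raise ValueError("nucleus area: min must be < max")
        if not self.dapi_median_min < self.dapi_median_max:
            raise ValueError("DAPI median: min must be < max")
        for name in ("edu_median_max", "cell_area_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _require_stage(table: pd.DataFrame, stage: str) -> None:
    if len(table) and not (table["qc_stage"] == stage).all():
        found = sorted(table["qc_stage"].unique())
        raise ValueError(f"expected rows at qc_stage {stage!r}, found {found}")


def nuclei2_reasons(table: pd.DataFrame, t: FilterThresholds) -> pd.DataFrame:
    """Per-row boolean removal reasons for the Nuclei -> Nuclei 2 selection."""
    if t.strict_bounds:
        area_ok = table["nucleus_area_um2"].between(
            t.nucleus_area_min, t.nucleus_area_max, inclusive="both")
        edu_ok = table["edu488_median"] < t.edu_median_max
        dapi_ok = table["dapi_median"].between(
            t.dapi_median_min, t.dapi_median_max, inclusive="both")
        bf_ok = table["brightfield_median"] > t.brightfield_min
    else:
        area_ok = table["nucleus_area_um2"].between(
            t.nucleus_area_min, t.nucleus_area_max, inclusive="neither")
        edu_ok = table["edu488_median"] <= t.edu_median_max
        dapi_ok = table["dapi_median"].between(
            t.dapi_median_min, t.dapi_median_max, inclusive="neither")
        bf_ok = table["brightfield_median"] >= t.brightfield_min
    return pd.DataFrame({
        "nucleus_area": ~area_ok,
        "edu_median": ~edu_ok,
        "dapi_median": ~dapi_ok,
        "brightfield": ~bf_ok,
    }, index=table.index)


def cell_reasons(table: pd.DataFrame, t: FilterThresholds) -> pd.DataFrame:
    """Per-row boolean removal reasons for the cell-area selection."""
    if t.strict_bounds:
        ok = table["cell_area_um2"] < t.cell_area_max
    else:
        ok = table["cell_area_um2"] <= t.cell_area_max
    return pd.DataFrame({"cell_area": ~ok}, index=table.index)


def _log_removals(reasons: pd.DataFrame, table: pd.DataFrame, stage: str) -> None:
    removed = reasons.any(axis=1)
    if removed.any():
        by = {c: int(reasons.loc[removed, c].sum()) for c in reasons.columns}
        logger.info("%s: removed %d objects (%s)", stage, int(removed.sum()), by)


def select_nuclei2(table: pd.DataFrame, t: FilterThresholds) -> pd.DataFrame:
    """Keep nuclei passing area/EdU/DAPI/brightfield; advance to 'nuclei2'."""
    _require_stage(table, "nuclei")
    if not len(table):
        return table.copy()
    reasons = nuclei2_reasons(table, t)
    _log_removals(reasons, table, "nuclei2")
    kept = table.loc[~reasons.any(axis=1)].copy()
    kept["qc_stage"] = "nuclei2"
    return kept


def select_cells(table: pd.DataFrame, t: FilterThresholds) -> pd.DataFrame:
    """Keep cells below the area ceiling (feeder exclusion); advance to 'cell'."""
    _require_stage(table, "cell_unselected")
    if not len(table):
        return table.copy()
    reasons = cell_reasons(table, t)
    _log_removals(reasons, table, "cell")
    n_feederlike = int(reasons["cell_area"].sum())
    if n_feederlike:
        logger.info("cell-area filter removed %d oversized (feeder-like) objects",
                    n_feederlike)
    kept = table.loc[~reasons.any(axis=1)].copy()
    kept["qc_stage"] = "cell"
    return kept


@dataclass
class CascadeResult:
    """Final object table plus per-stage bookkeeping."""

    table: pd.DataFrame            # rows at qc_stage "cell", relabelled ids
    counts: dict[str, int]         # objects surviving each stage
    nuclei_table: pd.DataFrame     # initial table at stage "nuclei"
    removal_log: pd.DataFrame      # object_id, stage, reason
    nuclei_mask: LabelMask         # restricted to the final population
    cells_mask: LabelMask


def _removals(table: pd.DataFrame, reasons: pd.DataFrame, stage: str) -> pd.DataFrame:
    removed = reasons.any(axis=1)
    if not removed.any():
        return pd.DataFrame(columns=["well", "field", "object_id", "stage", "reason"])
    recs = []
    sub = reasons.loc[removed]
    for idx, row in sub.iterrows():
        why = ";".join(c for c in reasons.columns if row[c])
        recs.append((table.at[idx, "well"], table.at[idx, "field"],
                     table.at[idx, "object_id"], stage, why))
    return pd.DataFrame(recs, columns=["well", "field", "object_id", "stage", "reason"])


def run_cascade(
    nuclei: LabelMask,
    cells: LabelMask,
    channels,
    thresholds: FilterThresholds,
    metadata: dict,
    pixel_size_um: float,
) -> CascadeResult:
    """Object table build + full selection cascade for one field.

    Stages: build (``nuclei``) -> intensity/area selection (``nuclei2``) ->
    border-object removal on the cell region (``cell_unselected``) ->
    cell-area ceiling (``cell``).  Stage counts are monotone non-increasing.
    The returned masks are restricted to the final population and relabelled
    consecutively; ``table.object_id`` matches the new labels and the original
    segmentation label is kept in ``segmentation_label``.
    """
    table = build_object_table(nuclei, cells, channels, metadata, pixel_size_um)
    counts = {"nuclei": len(table)}
    logs = []

    reasons = nuclei2_reasons(table, thresholds) if len(table) else None
    nuclei2 = select_nuclei2(table, thresholds)
    if reasons is not None:
        logs.append(_removals(table, reasons, "nuclei2"))
    counts["nuclei2"] = len(nuclei2)

    on_border = set(map(int, border_labels(cells)))
    keep = ~nuclei2["object_id"].astype(int).isin(on_border)
    if len(nuclei2) and not keep.all():
        removed = nuclei2.loc[~keep]
        logs.append(pd.DataFrame({
            "well": removed["well"], "field": removed["field"],
            "object_id": removed["object_id"], "stage": "cell_unselected",
            "reason": "border_object",
        }))
    unselected = nuclei2.loc[keep].copy()
    unselected["qc_stage"] = "cell_unselected"
    counts["cell_unselected"] = len(unselected)

    if len(unselected):
        logs.append(_removals(unselected, cell_reasons(unselected, thresholds),
                              "cell"))
    final = select_cells(unselected, thresholds)
    counts["cell"] = len(final)

    keep_ids = final["object_id"].astype(int).tolist()
    nuclei_final, mapping = subset_labels(nuclei, keep_ids)
    cells_final, _ = subset_labels(cells, keep_ids)
    final = final.copy()
    final["segmentation_label"] = final["object_id"].astype(int)
    final["object_id"] = final["segmentation_label"].map(mapping)
    final = final.sort_values("object_id").reset_index(drop=True)

    removal_log = (pd.concat(logs, ignore_index=True) if logs
                   else pd.DataFrame(columns=["well", "field", "object_id",
                                              "stage", "reason"]))
    return CascadeResult(
        table=final, counts=counts, nuclei_table=table,
        removal_log=removal_log, nuclei_mask=nuclei_final,
        cells_mask=cells_final,
    )
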