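"""Per-object morphology and intensity measurements; object-table assembly.

Nine phenotypic features are exported per retained cell: six morphology
(nucleus/cell area, roundness, width-to-length), two intensity (DAPI and EdU
median), and one context feature (cells per clump, filled later by the clump
module).  The brightfield median is carried as a QC column only.

Definitions:

* area = pixel count x pixel_size_um^2;
* roundness = 4 pi A / P^2 (isoperimetric quotient), clipped to (0, 1]
  because discretisation can exceed the bound; perimeter is the weighted
  boundary-chain estimate (diagonal steps weighted sqrt(2));
* width_to_length = minor / major axis of the second-central-moment
  equivalent ellipse, in (0, 1].

The three intensity medians are measured on the nucleus region (DAPI and EdU
are nuclear signals and precede cytoplasm detection in the cascade); the
region choice is configurable via ``measure_intensity``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .plate_io import TABLE_SCHEMAS
from .segmentation import LabelMask

logger = logging.getLogger(__name__)

OBJECT_COLUMNS = TABLE_SCHEMAS["object"]


class IntegrityError(ValueError):
    """Nucleus and cell label populations do not correspond one-to-one."""


def measure_morphology(mask: LabelMask, pixel_size_um: float) -> pd.DataFrame:
    """Area (um^2), roundness and width-to-length for every label.

    Single-pixel (or otherwise degenerate) objects get roundness and
    width_to_length 1 and are flagged.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    rows = []
    for prop in regionprops(mask.labels):
        area_px = float(prop.area)
        perimeter = float(prop.perimeter)
        flagged = False
        if perimeter <= 0:
            roundness = 1.0
            flagged = True
        else:
            roundness = 4.0 * math.pi * area_px / perimeter**2
        major, minor = float(prop.axis_major_length), float(prop.axis_minor_length)
        if major <= 0:
            w2l = 1.0
            flagged = True
        else:
            w2l = minor / major
        cr, cc = prop.centroid
        rows.append((
            int(prop.label),
            area_px * pixel_size_um**2,
            float(np.clip(roundness, 1e-6, 1.0)),
            float(np.clip(w2l, 1e-6, 1.0)),
            float(cr), float(cc),
            flagged,
        ))
    return pd.DataFrame(
        rows,
        columns=["object_id", "area_um2", "roundness", "width_to_length",
                 "centroid_row", "centroid_col", "flagged"],
    )


def measure_intensity(mask: LabelMask, channel: np.ndarray) -> pd.Series:
    """Median intensity over each label's region, indexed by label."""
    channel = np.asarray(channel)
    if channel.shape != mask.labels.shape:
        raise ValueError("channel image and mask shapes differ")
    ids = mask.label_ids()
    if ids.size == 0:
        return pd.Series(dtype=float, name="median")
    medians = ndi.labeled_comprehension(
        channel, mask.labels, ids, np.median, float, np.nan)
    return pd.Series(medians, index=pd.Index(ids, name="object_id"),
                     name="median")


def build_object_table(
    nuclei: LabelMask,
    cells: LabelMask,
    channels,
    metadata: dict,
    pixel_size_um: float,
) -> pd.DataFrame:
    """One row per object joining nucleus+cell morphology and the medians.

    ``channels`` maps channel names to aligned intensity arrays; the medians
    of dapi/edu488/brightfield are measured on the nucleus region.  Nucleus
    and cell labels must correspond one-to-one.  ``qc_stage`` starts at
    "nuclei".
    """
    nuc_ids = set(map(int, nuclei.label_ids()))
    cell_ids = set(map(int, cells.label_ids()))
    if nuc_ids != cell_ids:
        raise IntegrityError(
            f"nucleus/cell label mismatch: {sorted(nuc_ids ^ cell_ids)[:10]} ..."
        )
    if not nuc_ids:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in OBJECT_COLUMNS})
        return df

    nuc = measure_morphology(nuclei, pixel_size_um).set_index("object_id")
    cell = measure_morphology(cells, pixel_size_um).set_index("object_id")
    table = pd.DataFrame(index=nuc.index)
    table["plate"] = metadata.get("plate", "plate")
    table["well"] = metadata["well"]
    table["field"] = int(metadata["field"])
    table["object_id"] = table.index
    table["centroid_row"] = nuc["centroid_row"]
    table["centroid_col"] = nuc["centroid_col"]
    table["nucleus_area_um2"] = nuc["area_um2"]
    table["nucleus_roundness"] = nuc["roundness"]
    table["nucleus_width_to_length"] = nuc["width_to_length"]
    table["cell_area_um2"] = cell["area_um2"]
    table["cell_roundness"] = cell["roundness"]
    table["cell_width_to_length"] = cell["width_to_length"]
    table["dapi_median"] = measure_intensity(nuclei, channels["dapi"])
    table["edu488_median"] = measure_intensity(nuclei, channels["edu488"])
    table["brightfield_median"] = measure_intensity(nuclei, channels["brightfield"])
    table["n_per_clump"] = np.nan
    table["qc_stage"] = "nuclei"
    bad = table["cell_area_um2"] < table["nucleus_area_um2"]
    if bad.any():
        raise IntegrityError(
            f"{int(bad.sum())} objects have cell area below nucleus area; "
            "cell regions must contain their nuclei"
        )
    return table.reset_index(drop=True)[list(OBJECT_COLUMNS)]
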