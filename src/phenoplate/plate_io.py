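"""Plate layout parsing, image discovery and tabular input/output.

A 96-well plate is addressed as letter row (A-H) plus zero-padded column
(01-12), e.g. ``"B02"``.  Border wells (row A, row H, column 01, column 12)
are reserved for the "unused" marker: assays avoid them to reduce edge
effects, leaving the 60 interior wells assignable to substrate conditions.

All tabular results (object, clump, well-summary and ground-truth tables)
are flat CSV files with versioned headers; :func:`write_table` /
:func:`read_table` provide validated round-trip I/O.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

ROWS = "ABCDEFGH"
COLUMNS = tuple(f"{c:02d}" for c in range(1, 13))
WELL_RE = re.compile(r"^([A-H])(0[1-9]|1[0-2])$")

#: The four acquisition channels, in canonical order.
CHANNELS = ("dapi", "edu488", "cellmask647", "brightfield")

#: Default filename convention: ``{well}_f{field}_{channel}.tif``.
DEFAULT_IMAGE_PATTERN = (
    r"^(?P<well>[A-H]\d{2})_f(?P<field>\d+)_"
    r"(?P<channel>dapi|edu488|cellmask647|brightfield)\.tif{1,2}$"
)

UNUSED = "unused"

ALL_WELLS = tuple(f"{r}{c}" for r in ROWS for c in COLUMNS)
INTERIOR_WELLS = tuple(
    w for w in ALL_WELLS if w[0] not in "AH" and w[1:] not in ("01", "12")
)

TABLE_SCHEMA_VERSION = 1

#: Required columns per table kind.  Extra columns survive round trips.
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "object": (
        "plate", "well", "field", "object_id",
        "centroid_row", "centroid_col",
        "nucleus_area_um2", "nucleus_roundness", "nucleus_width_to_length",
        "cell_area_um2", "cell_roundness", "cell_width_to_length",
        "dapi_median", "edu488_median", "brightfield_median",
        "n_per_clump", "qc_stage",
    ),
    "clump": ("well", "field", "clump_id", "clump_size", "members"),
    "well_summary": (
        "plate", "well", "condition", "cell_count",
        "edu_positive_fraction", "fraction_single",
        "inverse_mean_clump_size", "n_clumps",
    ),
    "ground_truth": (
        "object_id", "well", "field", "centroid_row", "centroid_col",
        "nucleus_area_um2", "cell_area_um2", "clump_id", "clump_size",
        "edu_label", "is_feeder",
    ),
}

_STRING_COLUMNS = {"plate", "well", "qc_stage", "condition", "members"}


class LayoutError(ValueError):
    """A plate-layout file violates the 96-well conventions."""


class SchemaError(ValueError):
    """A table file does not match the declared schema."""

    def __init__(self, kind: str, missing: Sequence[str]):
        self.kind = kind
        self.missing = tuple(missing)
        super().__init__(
            f"table is not a valid {kind!r} table: missing columns {list(missing)}"
        )


def is_border_well(well: str) -> bool:
    """True for row A/H or column 01/12 wells (edge-effect exclusion zone)."""
    if not WELL_RE.match(well):
        raise LayoutError(f"malformed well name: {well!r}")
    return well[0] in "AH" or well[1:] in ("01", "12")


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of a 96-well plate's wells to substrate condition labels."""

    plate_id: str
    wells: Mapping[str, str]
    replicate_pattern: tuple[tuple[str, ...], ...] | None = None

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for c in self.wells.values() if c != UNUSED}))

    @property
    def assay_wells(self) -> tuple[str, ...]:
        return tuple(sorted(w for w, c in self.wells.items() if c != UNUSED))

    def wells_for(self, condition: str) -> tuple[str, ...]:
        return tuple(sorted(w for w, c in self.wells.items() if c == condition))

    def condition_of(self, well: str) -> str:
        return self.wells[well]


def _validate_layout(wells: Mapping[str, str], source: str = "<layout>",
                     require_triplicates: bool = False) -> None:
    for i, (well, condition) in enumerate(wells.items()):
        if not WELL_RE.match(str(well)):
            raise LayoutError(
                f"{source}: row {i}: malformed well name {well!r} "
                "(expected letter A-H + zero-padded column 01-12, e.g. 'B02')"
            )
        if is_border_well(well) and condition != UNUSED:
            raise LayoutError(
                f"{source}: border well {well} assigned condition {condition!r}; "
                "border wells (row A/H, column 01/12) must be 'unused' to avoid "
                "edge effects"
            )
    counts: dict[str, int] = {}
    for condition in wells.values():
        if condition != UNUSED:
            counts[condition] = counts.get(condition, 0) + 1
    for condition, n in counts.items():
        if n < 3:
            message = (
                f"{source}: condition {condition!r} present in only {n} wells; "
                "a technical triplicate (>= 3 wells) is expected"
            )
            if require_triplicates:
                raise LayoutError(message)
            logger.warning(message)


def load_plate_layout(path: str | Path, plate_id: str | None = None,
                      require_triplicates: bool = False) -> PlateLayout:
    """Read and validate a ``well,condition`` CSV as a :class:`PlateLayout`.

    Wells absent from the file are treated as ``unused``.  An empty table is
    a valid (vacuous) layout with zero assay wells.  Conditions present in
    fewer than 3 wells draw a warning (an error with
    ``require_triplicates=True``).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"well", "condition"}
    if not required.issubset(df.columns):
        raise LayoutError(f"{path}: layout file must have columns 'well,condition'")
    wells = dict.fromkeys(ALL_WELLS, UNUSED)
    listed = {str(r.well): str(r.condition) for r in df.itertuples()}
    _validate_layout(listed, source=str(path),
                     require_triplicates=require_triplicates)
    wells.update(listed)
    if not any(c != UNUSED for c in wells.values()):
        logger.warning("%s: layout has zero assay wells", path)
    return PlateLayout(plate_id=plate_id or path.stem, wells=wells)


def write_plate_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    rows = [(w, c) for w, c in sorted(layout.wells.items()) if c != UNUSED]
    pd.DataFrame(rows, columns=["well", "condition"]).to_csv(path, index=False)
    return path


def make_column_layout(
    conditions: Sequence[str] = ("Fn1", "Fn5", "Fn25"),
    n_blocks: int = 1,
    rows: str = "BCDEFG",
    start_column: int = 2,
    seed: int | None = None,
    plate_id: str = "plate01",
) -> PlateLayout:
    """Build a column-randomised technical-replicate layout.

    Conditions are assigned per interior column in blocks: within each block
    of ``len(conditions)`` consecutive columns the condition order is a random
    permutation (e.g. Fn1-Fn5-Fn25, Fn5-Fn25-Fn1, ...), and every well in
    ``rows`` of a column carries that column's condition.  One block of three
    conditions over rows B-G yields 6 replicate wells per condition.
    """
    rng = np.random.default_rng(seed)
    wells = dict.fromkeys(ALL_WELLS, UNUSED)
    patterns = []
    col = start_column
    for _ in range(n_blocks):
        order = list(rng.permutation(list(conditions)))
        patterns.append(tuple(order))
        for condition in order:
            name = f"{col:02d}"
            if col > 11:
                raise LayoutError("layout blocks exceed interior columns 02-11")
            for row in rows:
                well = f"{row}{name}"
                if is_border_well(well):
                    raise LayoutError(f"row {row!r} is a border row")
                wells[well] = condition
            col += 1
    layout = PlateLayout(plate_id=plate_id, wells=wells,
                         replicate_pattern=tuple(patterns))
    _validate_layout({w: c for w, c in wells.items() if c != UNUSED})
    return layout


@dataclass(frozen=True)
class FieldImage:
    """One field of view: four co-registered 2-D intensity arrays."""

    well: str
    field: int
    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"field image missing channels: {missing}")
        shapes = {c: np.asarray(a).shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel arrays differ in shape: {shapes}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        for name, arr in self.channels.items():
            if np.min(arr) < 0:
                raise ValueError(f"channel {name!r} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.channels["dapi"]).shape


@dataclass(frozen=True)
class FieldImageRef:
    """Lazy reference to the four channel files of one (well, field)."""

    well: str
    field: int
    paths: Mapping[str, Path]

    def load(self, pixel_size_um: float) -> FieldImage:
        channels = {
            name: np.asarray(tifffile.imread(path))
            for name, path in self.paths.items()
        }
        return FieldImage(well=self.well, field=self.field,
                          channels=channels, pixel_size_um=pixel_size_um)


@dataclass
class DiscoveryResult:
    fields: list[FieldImageRef] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)


def discover_images(
    root: str | Path, naming: str = DEFAULT_IMAGE_PATTERN
) -> DiscoveryResult:
    """Scan ``root`` for channel TIFFs and group them into field references.

    The ``naming`` regex must expose ``well``, ``field`` and ``channel``
    capture groups.  Fields missing one or more channels are reported in the
    diagnostics list and excluded; unparseable filenames are skipped with a
    warning.
    """
    pattern = re.compile(naming)
    for group in ("well", "field", "channel"):
        if group not in pattern.groupindex:
            raise ValueError(f"naming pattern lacks capture group {group!r}")
    found: dict[tuple[str, int], dict[str, Path]] = {}
    result = DiscoveryResult()
    for path in sorted(Path(root).iterdir()):
        if not path.is_file():
            continue
        m = pattern.match(path.name)
        if m is None:
            if path.suffix.lower() in (".tif", ".tiff"):
                msg = f"unparseable image filename skipped: {path.name}"
                logger.warning(msg)
                result.diagnostics.append(msg)
            continue
        key = (m.group("well"), int(m.group("field")))
        found.setdefault(key, {})[m.group("channel")] = path
    for (well, fld), paths in sorted(found.items()):
        missing = [c for c in CHANNELS if c not in paths]
        if missing:
            result.diagnostics.append(
                f"field {well}/f{fld} missing channels {missing}; excluded"
            )
            continue
        result.fields.append(FieldImageRef(well=well, field=fld, paths=paths))
    return result


def write_field_image(image: FieldImage, root: str | Path) -> list[Path]:
    """Write a field's channels as 16-bit grayscale TIFFs (default naming)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for channel in CHANNELS:
        arr = np.clip(np.asarray(image.channels[channel]), 0, 65535)
        path = root / f"{image.well}_f{image.field}_{channel}.tif"
        tifffile.imwrite(path, arr.astype(np.uint16))
        written.append(path)
    return written


def empty_table(kind: str) -> pd.DataFrame:
    """An empty table with the full schema for ``kind``."""
    columns = TABLE_SCHEMAS[kind]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    return df


def validate_table(table: pd.DataFrame, kind: str) -> None:
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in table.columns]
    if missing:
        raise SchemaError(kind, missing)


def write_table(table: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Write a typed table as CSV; the schema is validated first."""
    validate_table(table, kind)
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a typed table back; missing required columns raise SchemaError."""
    df = pd.read_csv(path, dtype={c: str for c in _STRING_COLUMNS})
    validate_table(df, kind)
    return df
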