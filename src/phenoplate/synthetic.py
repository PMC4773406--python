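"""Ground-truthed synthetic plates for pipeline validation.

The simulator emulates the statistical structure a dissociated-iPSC adhesion
assay produces on a fibronectin concentration gradient:

* per-well attached cell numbers ordered with substrate adhesiveness
  (Fn25 > Fn5 > Fn1 under the default presets);
* clump sizes (cells in mutual contact) i.i.d. geometric on {1, 2, ...} — a
  single cell is a clump of size 1 — so high-adhesion conditions with a small
  geometric parameter produce exponentially fewer clumps of bigger sizes;
* a two-population EdU intensity mixture: log-normal negative (background
  incorporation) and positive (S-phase) components, Gaussian in log10 space;
* rare oversized feeder-cell contaminants exercising the cell-area filter.

Cells are rendered as filled ellipses into the four acquisition channels
(dapi, edu488, cellmask647, brightfield); members of one clump are placed in
mutual contact on a hexagonal spiral while distinct clumps are separated by a
stated clearance, so distance-0 clump detection has an unambiguous truth.
Everything is a pure function of (params, layout, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from skimage.draw import ellipse as draw_ellipse

from .plate_io import (
    FieldImage,
    PlateLayout,
    write_field_image,
    write_plate_layout,
    write_table,
)

logger = logging.getLogger(__name__)


class PackingError(RuntimeError):
    """Raised when a field cannot hold the requested cell density."""


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel background and signal intensity model (16-bit AU).

    EdU signal is a two-component mixture, Gaussian in log10 intensity; the
    positive log-mean must exceed the negative log-mean so the components are
    separable.
    """

    dapi_background: tuple[float, float] = (100.0, 10.0)
    edu_background: tuple[float, float] = (80.0, 8.0)
    cellmask_background: tuple[float, float] = (100.0, 10.0)
    brightfield_background: tuple[float, float] = (500.0, 20.0)
    dapi_scale: float = 3000.0
    dapi_log_sd: float = 0.12
    edu_negative_log_mean: float = 2.5
    edu_negative_log_sd: float = 0.12
    edu_positive_log_mean: float = 3.6
    edu_positive_log_sd: float = 0.15
    cellmask_scale: float = 1500.0
    cellmask_log_sd: float = 0.10

    def __post_init__(self) -> None:
        if not self.edu_positive_log_mean > self.edu_negative_log_mean:
            raise ValueError(
                "EdU positive log-mean must exceed the negative log-mean "
                "(separable mixture)"
            )


@dataclass(frozen=True)
class ConditionParams:
    """Generative block for one substrate condition."""

    expected_attached_cells: float = 200.0   # per well, over the imaged fields
    clump_geometric_p: float = 0.55          # geometric clump-size parameter
    edu_positive_fraction: float = 0.30
    nucleus_area_median_um2: float = 150.0   # log-normal median
    nucleus_area_log_sd: float = 0.22        # sd of ln(area)
    cell_area_median_um2: float = 480.0
    cell_area_log_sd: float = 0.30
    elongation_alpha: float = 5.0            # beta params for width-to-length
    elongation_beta: float = 3.0
    nucleus_elongation_alpha: float = 8.0
    nucleus_elongation_beta: float = 2.0
    feeder_rate: float = 0.1                 # expected contaminants per well
    feeder_cell_area_um2: float = 8000.0
    feeder_nucleus_area_um2: float = 400.0

    def __post_init__(self) -> None:
        if self.expected_attached_cells < 0:
            raise ValueError("expected_attached_cells must be non-negative")
        if not 0 < self.clump_geometric_p <= 1:
            raise ValueError("clump_geometric_p must lie in (0, 1]")
        for name in ("edu_positive_fraction", "feeder_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Full generative description of a synthetic plate."""

    conditions: Mapping[str, ConditionParams]
    intensity: IntensityModel = field(default_factory=IntensityModel)
    pixel_size_um: float = 0.65
    image_shape: tuple[int, int] = (960, 960)
    n_fields: int = 9
    clump_clearance_px: float = 8.0
    contact_factor: float = 0.95  # hex spacing as fraction of touching distance
    border_margin_px: float = 4.0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")


def default_params() -> SimulationParams:
    """Default presets for the three fibronectin concentrations.

    Attached cell numbers are ordered Fn25 > Fn5 > Fn1 and the clump-size
    geometric parameter decreases with fibronectin concentration (stronger
    clumping on high Fn); the EdU-positive fraction is shared.
    """
    return SimulationParams(
        conditions={
            "Fn1": ConditionParams(
                expected_attached_cells=110.0, clump_geometric_p=0.70,
                cell_area_median_um2=380.0, cell_area_log_sd=0.28,
                elongation_alpha=8.0, elongation_beta=2.0,
            ),
            "Fn5": ConditionParams(
                expected_attached_cells=200.0, clump_geometric_p=0.55,
                cell_area_median_um2=480.0, cell_area_log_sd=0.32,
                elongation_alpha=6.0, elongation_beta=3.0,
            ),
            "Fn25": ConditionParams(
                expected_attached_cells=320.0, clump_geometric_p=0.40,
                cell_area_median_um2=600.0, cell_area_log_sd=0.36,
                elongation_alpha=5.0, elongation_beta=4.0,
            ),
        }
    )


def params_to_yaml(params: SimulationParams, path: str | Path) -> Path:
    payload = asdict(params)
    payload["conditions"] = {k: asdict(v) for k, v in params.conditions.items()}
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def params_from_yaml(path: str | Path) -> SimulationParams:
    payload = yaml.safe_load(Path(path).read_text())
    conditions = {
        k: ConditionParams(**v) for k, v in payload.pop("conditions").items()
    }
    intensity = IntensityModel(
        **{k: tuple(v) if isinstance(v, list) else v
           for k, v in payload.pop("intensity").items()}
    )
    payload["image_shape"] = tuple(payload["image_shape"])
    return SimulationParams(conditions=conditions, intensity=intensity, **payload)


GROUND_TRUTH_COLUMNS = (
    "object_id", "well", "field", "centroid_row", "centroid_col",
    "nucleus_area_um2", "cell_area_um2", "clump_id", "clump_size",
    "edu_label", "is_feeder",
    # rendering geometry (pixels / radians), kept for reproducible drawing
    "cell_a_px", "cell_b_px", "nucleus_a_px", "nucleus_b_px", "orientation",
)


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in GROUND_TRUTH_COLUMNS})


def _hex_spiral(n: int) -> np.ndarray:
    """First ``n`` points of a unit hexagonal spiral (centre first)."""
    pts = [(0.0, 0.0)]
    ring = 1
    while len(pts) < n:
        # walk the hexagonal ring of radius `ring`
        corner = [(ring * math.cos(np.pi / 3 * k), ring * math.sin(np.pi / 3 * k))
                  for k in range(6)]
        for k in range(6):
            x0, y0 = corner[k]
            x1, y1 = corner[(k + 1) % 6]
            for step in range(ring):
                t = step / ring
                pts.append((x0 + (x1 - x0) * t, y0 + (y1 - y0) * t))
                if len(pts) >= n:
                    return np.asarray(pts[:n])
        ring += 1
    return np.asarray(pts[:n])


def _ellipse_axes(area_px2: float, width_to_length: float) -> tuple[float, float]:
    """Semi-axes (major a, minor b) of an ellipse with given area and b/a."""
    a = math.sqrt(area_px2 / (math.pi * width_to_length))
    return a, a * width_to_length


def _sample_cell_shapes(
    rng: np.random.Generator, cp: ConditionParams, n: int, pixel_size_um: float,
    feeder: bool = False,
) -> pd.DataFrame:
    """Draw per-cell morphology: areas (log-normal), elongation (beta)."""
    px2 = pixel_size_um ** 2
    if feeder:
        cell_area = np.full(n, cp.feeder_cell_area_um2) * np.exp(
            rng.normal(0, 0.1, n))
        nuc_area = np.full(n, cp.feeder_nucleus_area_um2) * np.exp(
            rng.normal(0, 0.1, n))
    else:
        cell_area = cp.cell_area_median_um2 * np.exp(
            rng.normal(0, cp.cell_area_log_sd, n))
        nuc_area = cp.nucleus_area_median_um2 * np.exp(
            rng.normal(0, cp.nucleus_area_log_sd, n))
    w2l = np.clip(rng.beta(cp.elongation_alpha, cp.elongation_beta, n), 0.35, 1.0)
    nw2l = np.clip(
        rng.beta(cp.nucleus_elongation_alpha, cp.nucleus_elongation_beta, n),
        0.3, 1.0)
    theta = rng.uniform(0, np.pi, n)
    rows = []
    for i in range(n):
        ca, cb = _ellipse_axes(cell_area[i] / px2, w2l[i])
        na, nb = _ellipse_axes(nuc_area[i] / px2, nw2l[i])
        # nucleus must sit inside its (co-oriented, concentric) cell ellipse
        shrink = min(1.0, 0.85 * ca / na, 0.85 * cb / nb)
        na, nb = na * shrink, nb * shrink
        rows.append((
            cell_area[i], math.pi * na * nb * px2, ca, cb, na, nb, theta[i],
        ))
    return pd.DataFrame(
        rows,
        columns=["cell_area_um2", "nucleus_area_um2",
                 "cell_a_px", "cell_b_px", "nucleus_a_px", "nucleus_b_px",
                 "orientation"],
    )


def _place_clump(
    rng: np.random.Generator,
    shapes: pd.DataFrame,
    shape: tuple[int, int],
    placed: list[tuple[float, float, float]],
    clearance: float,
    contact_factor: float,
    margin: float,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Choose member centroids for one clump; returns (k, 2) row/col array."""
    k = len(shapes)
    spacing = contact_factor * 2.0 * float(shapes["cell_b_px"].mean())
    offsets = _hex_spiral(k) * spacing
    phi = rng.uniform(0, 2 * np.pi)
    rot = np.array([[math.cos(phi), -math.sin(phi)],
                    [math.sin(phi), math.cos(phi)]])
    offsets = offsets @ rot.T
    radius = float(
        np.max(np.hypot(offsets[:, 0], offsets[:, 1]) + shapes["cell_a_px"].values)
    )
    lo_r, hi_r = radius + margin, shape[0] - radius - margin
    lo_c, hi_c = radius + margin, shape[1] - radius - margin
    if lo_r >= hi_r or lo_c >= hi_c:
        raise PackingError(
            f"a clump of bounding radius {radius:.0f} px does not fit a "
            f"{shape} field; lower the cell density or area"
        )
    for _ in range(max_attempts):
        cr = rng.uniform(lo_r, hi_r)
        cc = rng.uniform(lo_c, hi_c)
        if all(
            math.hypot(cr - pr, cc - pc) > radius + pradius + clearance
            for pr, pc, pradius in placed
        ):
            placed.append((cr, cc, radius))
            return np.column_stack([offsets[:, 0] + cr, offsets[:, 1] + cc])
    raise PackingError(
        "could not place a clump without violating the inter-clump clearance; "
        "the field is too densely packed — lower expected_attached_cells"
    )


def sample_well_population(
    params: SimulationParams, condition: str, seed, well: str = "B02"
) -> pd.DataFrame:
    """Sample one well's ground-truth object population.

    The number of clumps is Poisson with mean ``expected_attached_cells *
    clump_geometric_p`` so the expected total cell count matches the preset;
    clump sizes are i.i.d. geometric, EdU labels i.i.d. Bernoulli.  Clumps are
    assigned to fields uniformly and placed with mutual contact inside a clump
    and the configured clearance between clumps.
    """
    if condition not in params.conditions:
        raise KeyError(f"condition {condition!r} has no parameter block")
    cp = params.conditions[condition]
    rng = np.random.default_rng(seed)
    lam = cp.expected_attached_cells * cp.clump_geometric_p
    n_clumps = int(rng.poisson(lam)) if lam > 0 else 0
    sizes = rng.geometric(cp.clump_geometric_p, n_clumps) if n_clumps else (
        np.zeros(0, dtype=int))
    n_feeders = int(rng.poisson(cp.feeder_rate))
    fields = rng.integers(1, params.n_fields + 1, n_clumps + n_feeders)

    placed: dict[int, list[tuple[float, float, float]]] = {
        f: [] for f in range(1, params.n_fields + 1)}
    records: list[pd.DataFrame] = []
    object_id = 1
    margin = params.border_margin_px
    for clump_idx in range(n_clumps + n_feeders):
        is_feeder = clump_idx >= n_clumps
        k = 1 if is_feeder else int(sizes[clump_idx])
        fld = int(fields[clump_idx])
        shapes = _sample_cell_shapes(
            rng, cp, k, params.pixel_size_um, feeder=is_feeder)
        centroids = _place_clump(
            rng, shapes, params.image_shape, placed[fld],
            params.clump_clearance_px, params.contact_factor, margin)
        edu = (np.zeros(k, dtype=int) if is_feeder
               else rng.binomial(1, cp.edu_positive_fraction, k))
        block = shapes.copy()
        block.insert(0, "object_id", np.arange(object_id, object_id + k))
        block.insert(1, "well", well)
        block.insert(2, "field", fld)
        block.insert(3, "centroid_row", centroids[:, 0])
        block.insert(4, "centroid_col", centroids[:, 1])
        block["clump_id"] = clump_idx + 1
        block["clump_size"] = k
        block["edu_label"] = edu
        block["is_feeder"] = is_feeder
        records.append(block)
        object_id += k
    if not records:
        return _empty_truth()
    truth = pd.concat(records, ignore_index=True)
    return truth[list(GROUND_TRUTH_COLUMNS)]


def _add_background(
    rng: np.random.Generator, shape: tuple[int, int],
    mean_sd: tuple[float, float], floor: float = 0.0,
) -> np.ndarray:
    img = rng.normal(mean_sd[0], mean_sd[1], shape)
    return np.maximum(img, floor)


def render_field(
    truth: pd.DataFrame, params: SimulationParams, seed
) -> FieldImage:
    """Render one field's ground truth into a four-channel image.

    Nuclei are filled ellipses in dapi and edu488 (EdU intensity drawn from
    the negative or positive log-normal per the true label); cellmask647
    renders whole cell bodies so clump members share touching boundaries;
    brightfield is strictly positive background.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    shape = params.image_shape
    im = params.intensity
    dapi = _add_background(rng, shape, im.dapi_background)
    edu = _add_background(rng, shape, im.edu_background)
    cellmask = _add_background(rng, shape, im.cellmask_background)
    brightfield = _add_background(rng, shape, im.brightfield_background, floor=1.0)

    wells = truth["well"].unique()
    well = str(wells[0]) if len(wells) else "B02"
    fields = truth["field"].unique()
    fld = int(fields[0]) if len(fields) else 1

    for row in truth.sort_values("object_id").itertuples():
        r, c = float(row.centroid_row), float(row.centroid_col)
        theta = float(row.orientation)
        rr, cc = draw_ellipse(r, c, row.cell_b_px, row.cell_a_px,
                              shape=shape, rotation=theta)
        cell_level = im.cellmask_scale * 10 ** rng.normal(0, im.cellmask_log_sd)
        cellmask[rr, cc] = np.maximum(cellmask[rr, cc], cell_level)

        rr, cc = draw_ellipse(r, c, row.nucleus_b_px, row.nucleus_a_px,
                              shape=shape, rotation=theta)
        dapi_level = im.dapi_scale * 10 ** rng.normal(0, im.dapi_log_sd)
        dapi[rr, cc] += dapi_level
        if int(row.edu_label):
            lvl = 10 ** rng.normal(im.edu_positive_log_mean, im.edu_positive_log_sd)
        else:
            lvl = 10 ** rng.normal(im.edu_negative_log_mean, im.edu_negative_log_sd)
        edu[rr, cc] += lvl

    channels = {
        "dapi": np.clip(dapi, 0, None),
        "edu488": np.clip(edu, 0, None),
        "cellmask647": np.clip(cellmask, 0, None),
        "brightfield": np.maximum(brightfield, 1.0),
    }
    return FieldImage(well=well, field=fld, channels=channels,
                      pixel_size_um=params.pixel_size_um)


def sample_edu_medians(
    params: SimulationParams | IntensityModel, n: int,
    positive_fraction: float, seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` EdU median intensities from the two-population mixture.

    Returns ``(values, labels)``; used to validate the EdU-positive-fraction
    estimator against known truth without full image rendering.
    """
    im = params.intensity if isinstance(params, SimulationParams) else params
    rng = np.random.default_rng(seed)
    labels = rng.binomial(1, positive_fraction, n)
    log_mean = np.where(labels, im.edu_positive_log_mean, im.edu_negative_log_mean)
    log_sd = np.where(labels, im.edu_positive_log_sd, im.edu_negative_log_sd)
    return 10 ** rng.normal(log_mean, log_sd), labels


def _well_seed_sequences(
    layout: PlateLayout, seed
) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    wells = list(layout.assay_wells)
    children = root.spawn(len(wells))
    return dict(zip(wells, children))


def sample_plate_truth(
    layout: PlateLayout, params: SimulationParams, seed
) -> pd.DataFrame:
    """Ground truth for every assay well of ``layout`` (no rendering)."""
    frames = []
    for well, ss in _well_seed_sequences(layout, seed).items():
        condition = layout.condition_of(well)
        if condition not in params.conditions:
            raise KeyError(f"layout condition {condition!r} has no parameter block")
        pop_ss, _ = ss.spawn(2)
        frames.append(sample_well_population(params, condition, pop_ss, well=well))
    if not frames:
        return _empty_truth()
    return pd.concat(frames, ignore_index=True)


def iter_simulated_fields(
    layout: PlateLayout, params: SimulationParams, seed
) -> Iterator[tuple[FieldImage, pd.DataFrame]]:
    """Stream (FieldImage, field ground truth) pairs for a whole plate.

    Uses the same seed derivation as :func:`sample_plate_truth`, so the truth
    tables agree exactly.
    """
    for well, ss in _well_seed_sequences(layout, seed).items():
        condition = layout.condition_of(well)
        if condition not in params.conditions:
            raise KeyError(f"layout condition {condition!r} has no parameter block")
        pop_ss, render_ss = ss.spawn(2)
        truth = sample_well_population(params, condition, pop_ss, well=well)
        field_seeds = render_ss.spawn(params.n_fields)
        for fld in range(1, params.n_fields + 1):
            sub = truth[truth["field"] == fld] if len(truth) else truth
            image = render_field(sub, params, field_seeds[fld - 1])
            image = FieldImage(well=well, field=fld, channels=image.channels,
                               pixel_size_um=params.pixel_size_um)
            yield image, sub.reset_index(drop=True)


def simulate_plate(
    layout: PlateLayout, params: SimulationParams, seed,
    outdir: str | Path,
) -> pd.DataFrame:
    """Render a full plate to ``outdir`` and return the ground-truth table.

    Images follow the default ``{well}_f{field}_{channel}.tif`` convention;
    the truth table and layout are written alongside as CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    for image, sub in iter_simulated_fields(layout, params, seed):
        write_field_image(image, outdir)
        frames.append(sub)
    truth = (pd.concat(frames, ignore_index=True) if frames else _empty_truth())
    write_table(truth, outdir / "ground_truth.csv", kind="ground_truth")
    write_plate_layout(layout, outdir / "layout.csv")
    return truth


def match_objects(
    truth: pd.DataFrame, predicted: pd.DataFrame, max_dist_px: float
) -> dict[str, float]:
    """Match predicted to true centroids per (well, field); recall/precision.

    One-to-one matching by minimum total distance (Hungarian assignment),
    accepting pairs within ``max_dist_px``.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    tp = fp = fn = 0
    keys = set(map(tuple, truth[["well", "field"]].itertuples(index=False))) | set(
        map(tuple, predicted[["well", "field"]].itertuples(index=False)))
    for well, fld in keys:
        t = truth[(truth["well"] == well) & (truth["field"] == fld)]
        p = predicted[(predicted["well"] == well) & (predicted["field"] == fld)]
        if len(t) == 0 or len(p) == 0:
            fn += len(t)
            fp += len(p)
            continue
        d = cdist(t[["centroid_row", "centroid_col"]].to_numpy(float),
                  p[["centroid_row", "centroid_col"]].to_numpy(float))
        rows, cols = linear_sum_assignment(d)
        matched = int(np.sum(d[rows, cols] <= max_dist_px))
        tp += matched
        fn += len(t) - matched
        fp += len(p) - matched
    recall = tp / (tp + fn) if tp + fn else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "recall": recall, "precision": precision}
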