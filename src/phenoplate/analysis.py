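"""Condition comparison: feature matrix, PCA and 68%-coverage group ellipses.

Well summaries from different substrate conditions are compared in a
standardised feature space (features mix units — um^2, fractions, counts —
so each column is z-scored) and projected by principal component analysis.
Per condition, the first two component scores are summarised by the
bivariate-normal contour containing the requested coverage (chi-square
quantile with 2 degrees of freedom; 0.68 is the 1-sigma-equivalent).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import FEATURES

logger = logging.getLogger(__name__)

#: Well-level statistics appended to the per-feature means/SDs.
WELL_LEVEL_FEATURES = (
    "log10_cell_count", "edu_positive_fraction", "fraction_single",
    "inverse_mean_clump_size",
)


def build_feature_matrix(
    summaries: pd.DataFrame,
    use_sds: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardised wells x features matrix from a WellSummary table.

    Columns: the transformed means (and, by default, SDs) of the 8 aggregated
    features over all cells, plus log10 cell count, EdU-positive fraction,
    fraction of single cells and inverse mean clump size.  Wells with any
    missing value are dropped (listwise deletion, logged); zero-variance
    columns are dropped with a warning.  Each remaining column is centred and
    scaled to unit variance.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 wells to build a feature matrix")
    cols = [f"{f}_mean" for f in FEATURES]
    if use_sds:
        cols += [f"{f}_sd" for f in FEATURES]
    data = summaries[cols].copy()
    data["log10_cell_count"] = np.log10(
        summaries["cell_count"].replace(0, np.nan).astype(float))
    for col in ("edu_positive_fraction", "fraction_single",
                "inverse_mean_clump_size"):
        data[col] = summaries[col].astype(float)
    data.index = summaries["well"].to_numpy()

    complete = data.dropna(axis=0, how="any")
    dropped = len(data) - len(complete)
    if dropped:
        logger.info("build_feature_matrix: %d wells dropped for missing values",
                    dropped)
    variances = complete.var(axis=0, ddof=0)
    constant = variances[variances == 0].index.tolist()
    if constant:
        logger.warning("dropping zero-variance columns: %s", constant)
        complete = complete.drop(columns=constant)
    standardized = (complete - complete.mean()) / complete.std(ddof=0)
    return standardized, list(standardized.columns)


@dataclass
class PCAResult:
    """Principal axes of a column-standardised well-feature matrix."""

    scores: np.ndarray          # wells x components
    loadings: np.ndarray        # features x components, orthonormal columns
    variance_fraction: np.ndarray
    feature_names: list[str]
    well_ids: list[str]
    mean: np.ndarray
    scale: np.ndarray


def run_pca(matrix: pd.DataFrame | np.ndarray,
            feature_names: list[str] | None = None) -> PCAResult:
    """PCA by singular-value decomposition of the centred matrix.

    Deterministic up to sign; the convention fixed here makes the
    largest-magnitude loading of every component positive.  All
    ``min(n - 1, p)``-plus-trailing components are returned so the variance
    fractions sum to 1 (degenerate directions carry zero variance).
    """
    if isinstance(matrix, pd.DataFrame):
        well_ids = [str(w) for w in matrix.index]
        feature_names = feature_names or [str(c) for c in matrix.columns]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        well_ids = [str(i) for i in range(X.shape[0])]
        feature_names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: per component, the largest-|loading| entry is positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * s
    variance = s**2 / max(n - 1, 1)
    total = variance.sum()
    fraction = variance / total if total > 0 else variance
    return PCAResult(
        scores=scores, loadings=Vt.T, variance_fraction=fraction,
        feature_names=feature_names, well_ids=well_ids, mean=mean, scale=scale,
    )


@dataclass(frozen=True)
class GroupEllipse:
    """Bivariate-normal coverage contour for one condition's PC1/PC2 scores."""

    condition: str
    centre: tuple[float, float]
    semi_axes: tuple[float, float]   # major, minor
    orientation: float               # radians, major axis vs PC1
    coverage: float = 0.68

    def boundary(self, n: int = 720) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, -s], [s, c]])
        return pts @ rot.T + np.asarray(self.centre)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - np.asarray(self.centre)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0


def group_ellipse(
    scores: np.ndarray, labels, coverage: float = 0.68,
) -> dict[str, GroupEllipse]:
    """Per-condition coverage ellipse of the first two component scores.

    The contour is the bivariate-normal ellipse at the chi-square(2 df)
    quantile of ``coverage`` fitted to each condition's scores.  Conditions
    with fewer than 3 wells get no ellipse (warning).
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    r2 = stats.chi2.ppf(coverage, df=2)
    out: dict[str, GroupEllipse] = {}
    for condition in pd.unique(labels):
        pts = scores[labels == condition]
        if len(pts) < 3:
            logger.warning("condition %r has %d wells (< 3): no ellipse",
                           condition, len(pts))
            continue
        centre = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        eigvals = np.clip(eigvals, 0, None)
        semi = np.maximum(np.sqrt(eigvals * r2), 1e-12)
        angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
        out[str(condition)] = GroupEllipse(
            condition=str(condition), centre=(float(centre[0]), float(centre[1])),
            semi_axes=(float(semi[0]), float(semi[1])),
            orientation=angle, coverage=coverage)
    return out


def ellipses_overlap(e1: GroupEllipse, e2: GroupEllipse, n: int = 720) -> bool:
    """Boolean overlap via dense boundary sampling plus centre containment."""
    if e1.contains(np.asarray([e2.centre])).any():
        return True
    if e2.contains(np.asarray([e1.centre])).any():
        return True
    if e2.contains(e1.boundary(n)).any():
        return True
    return bool(e1.contains(e2.boundary(n)).any())


NUCLEUS_DENSITY_FEATURES = (
    "nucleus_area_um2", "nucleus_roundness", "nucleus_width_to_length",
)


@dataclass
class ConditionReport:
    """Per-condition comparison of the well-level statistics."""

    stats: pd.DataFrame                 # condition x (feature, statistic)
    rank_by_cell_count: list[str]       # conditions, highest mean count first
    densities: dict[str, pd.DataFrame]  # feature -> (x, per-condition density)


def compare_conditions(
    summaries: pd.DataFrame,
    objects: pd.DataFrame | None = None,
    layout=None,
    grid_size: int = 256,
) -> ConditionReport:
    """Min-max/mean per condition and the cell-count rank order.

    With the optional object-level table (and a layout to map wells to
    conditions) per-condition kernel-density tables are produced for the
    nucleus area, roundness and width-to-length distributions.
    """
    if "condition" not in summaries.columns or summaries["condition"].eq("").all():
        raise ValueError("summaries must carry condition labels")
    quantities = ("cell_count", "edu_positive_fraction",
                  "inverse_mean_clump_size", "fraction_single")
    recs = []
    for condition, grp in summaries.groupby("condition"):
        row: dict = {"condition": condition, "n_wells": len(grp)}
        for q in quantities:
            vals = grp[q].astype(float)
            row[f"{q}_mean"] = float(vals.mean())
            row[f"{q}_min"] = float(vals.min())
            row[f"{q}_max"] = float(vals.max())
        recs.append(row)
    table = pd.DataFrame(recs).set_index("condition")
    if len(table) >= 2:
        rank = table["cell_count_mean"].sort_values(ascending=False).index.tolist()
    else:
        rank = []

    densities: dict[str, pd.DataFrame] = {}
    if objects is not None and len(objects):
        objs = objects.copy()
        if "condition" not in objs.columns:
            if layout is None:
                raise ValueError("pass a layout to map object wells to conditions")
            objs["condition"] = objs["well"].map(layout.condition_of)
        for feature in NUCLEUS_DENSITY_FEATURES:
            lo = float(objs[feature].min())
            hi = float(objs[feature].max())
            grid = np.linspace(lo, hi, grid_size)
            cols = {"x": grid}
            for condition, grp in objs.groupby("condition"):
                vals = grp[feature].to_numpy(dtype=float)
                if len(vals) >= 3 and np.std(vals) > 0:
                    cols[str(condition)] = stats.gaussian_kde(vals)(grid)
            densities[feature] = pd.DataFrame(cols)
    return ConditionReport(stats=table, rank_by_cell_count=rank,
                           densities=densities)
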