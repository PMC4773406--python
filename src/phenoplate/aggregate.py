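"""Well-level aggregation of cell-based measurements.

Each feature is variance-stabilised before averaging: log10 for the
right-skewed positive features (areas, intensity medians) and squaring for
the left-skewed bounded ratios (roundness, width-to-length).  Per well the
summary carries transformed means and standard deviations for all cells and
separately for single cells, the cell count, the EdU-positive fraction from
a Gaussian-main-peak decomposition of the log EdU median density, the
fraction of single cells, and the inverse mean clump size — the
maximum-likelihood parameter of a geometric clump-size law on {1, 2, ...}.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The eight aggregated phenotypic features (the ninth, cells per clump,
#: enters through fraction_single / inverse_mean_clump_size).
FEATURES = (
    "nucleus_area_um2", "nucleus_roundness", "nucleus_width_to_length",
    "cell_area_um2", "cell_roundness", "cell_width_to_length",
    "dapi_median", "edu488_median",
)

#: Default transform per feature: log10 for skewed positive quantities,
#: square for ratios bounded at 1.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "nucleus_area_um2": "log10",
    "nucleus_roundness": "square",
    "nucleus_width_to_length": "square",
    "cell_area_um2": "log10",
    "cell_roundness": "square",
    "cell_width_to_length": "square",
    "dapi_median": "log10",
    "edu488_median": "log10",
}

#: Minimum cells for kernel-density estimation of the EdU fraction.
MIN_CELLS_FOR_DENSITY = 30


def transform_feature(
    values, feature: str, transforms: dict[str, str] | None = None
) -> np.ndarray:
    """Apply the configured variance-stabilising transform to raw values.

    Non-positive values under log10 become NaN (excluded from aggregates)
    with a logged count.
    """
    mapping = DEFAULT_TRANSFORMS if transforms is None else transforms
    kind = mapping.get(feature, "identity")
    values = np.asarray(values, dtype=float)
    if kind == "log10":
        bad = ~(values > 0)
        if bad.any():
            logger.warning("%s: %d non-positive values excluded from log10",
                           feature, int(bad.sum()))
        out = np.full_like(values, np.nan)
        np.log10(values, out=out, where=values > 0)
        return out
    if kind == "square":
        return values**2
    if kind == "identity":
        return values.copy()
    raise ValueError(f"unknown transform {kind!r} for feature {feature!r}")


def _gaussian(t: np.ndarray, height: float, mu: float, sigma: float) -> np.ndarray:
    return height * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def edu_positive_fraction(
    edu_medians, min_n: int = MIN_CELLS_FOR_DENSITY, grid_size: int = 512,
    noise_floor_se: float = 1.0,
) -> float:
    """Fraction of EdU-positive cells via Gaussian-main-peak decomposition.

    The log10 EdU median density is estimated by Gaussian KDE (Silverman
    bandwidth); the main mode — the global density maximum — is taken to be
    the EdU-negative population.  A Gaussian is fitted to the sub-mode side
    of the density curve by least squares (initialised with the mirrored
    sub-mode spread of the data combined in quadrature with the KDE
    bandwidth, so the peak lives on the same smoothed scale as the empirical
    density); its mass is capped at 1.  The positive fraction is the area
    under the density above the fitted peak's mean that the peak does not
    explain, after subtracting ``noise_floor_se`` KDE sampling standard
    errors pointwise (otherwise the positive-part residual integrates pure
    sampling noise and a fully EdU-negative well reads a few percent
    positive).  The result is clipped to [0, 1].

    Invariant under rescaling all intensities by a constant (a log10 shift).
    Returns NaN (with a warning) below ``min_n`` values.
    """
    values = np.asarray(edu_medians, dtype=float)
    values = values[np.isfinite(values) & (values > 0)]
    if len(values) < min_n:
        logger.warning(
            "edu_positive_fraction: %d values < minimum %d; returning NaN",
            len(values), min_n)
        return float("nan")
    x = np.log10(values)
    spread = x.std(ddof=1)
    if spread == 0:
        return 0.0
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bandwidth = float(kde.factor) * spread
    grid = np.linspace(x.min() - 4 * bandwidth, x.max() + 4 * bandwidth, grid_size)
    density = kde(grid)
    imax = int(np.argmax(density))
    mode0, height0 = float(grid[imax]), float(density[imax])
    sub = x[x <= mode0]
    sigma0 = math.hypot(
        float(np.sqrt(np.mean((sub - mode0) ** 2))) if len(sub) else bandwidth,
        bandwidth)
    # include the full crest: the gridded mode can sit a fraction of sigma off
    # the true mode on a KDE wiggle, and a crest-truncated flank lets the
    # fitted width collapse.  One initial sigma stays well below a positive
    # component separated by >= 4 sigma.
    region = grid <= mode0 + sigma0
    try:
        from scipy.optimize import curve_fit

        (height, mu, sigma), _ = curve_fit(
            _gaussian, grid[region], density[region],
            p0=(height0, mode0, sigma0),
            bounds=([0.0, grid[0], 1e-6], [np.inf, grid[-1], np.inf]),
            maxfev=2000)
    except RuntimeError:  # fall back to the moment initialisation
        height, mu, sigma = height0, mode0, sigma0
    max_height = 1.0 / (sigma * math.sqrt(2 * math.pi))  # mass cap at 1
    height = min(float(height), max_height)
    peak = _gaussian(grid, height, mu, sigma)
    # KDE pointwise sampling error: sqrt(f R(K) / (n h)), R(Gauss) = 1/(2 sqrt(pi))
    se = np.sqrt(density / (2.0 * math.sqrt(math.pi) * len(x) * bandwidth))
    residual = np.clip(density - peak - noise_floor_se * se, 0.0, None)
    residual = np.where(grid > mu, residual, 0.0)  # positives are brighter
    fraction = float(np.trapezoid(residual, grid))
    return float(np.clip(fraction, 0.0, 1.0))


@dataclass(frozen=True)
class GeometricFit:
    """Geometric clump-size fit: p_hat = 1/mean plus a chi-square GOF."""

    p_hat: float
    n_clumps: int
    chi2: float
    dof: int
    p_value: float


def fit_geometric_clumps(sizes) -> GeometricFit:
    """Fit a geometric law on {1, 2, ...} to one well's clump sizes.

    ``p_hat = 1 / mean(sizes)`` is the maximum-likelihood estimator.  The
    goodness-of-fit chi-square compares observed counts per size against
    ``n * p (1-p)^(k-1)``, pooling the tail beyond the last size whose
    expected count is >= 5.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("fit_geometric_clumps requires at least one clump")
    if np.any(sizes < 1):
        raise ValueError("clump sizes must be >= 1")
    n = int(sizes.size)
    p_hat = 1.0 / float(sizes.mean())
    if p_hat >= 1.0:  # all singletons: degenerate fit, nothing to test
        return GeometricFit(p_hat=1.0, n_clumps=n, chi2=0.0, dof=0,
                            p_value=float("nan"))
    kmax = int(sizes.max())
    expected_full = n * p_hat * (1 - p_hat) ** (np.arange(1, kmax + 1) - 1)
    # pool the tail where expected counts fall below 5
    cut = int(np.searchsorted(expected_full < 5, True))
    cut = max(cut, 1)
    observed = np.bincount(sizes.astype(int), minlength=kmax + 2)[1:kmax + 1]
    obs = np.concatenate([observed[:cut], [observed[cut:].sum()]])
    exp_tail = n - expected_full[:cut].sum()  # geometric mass beyond the cut
    exp = np.concatenate([expected_full[:cut], [exp_tail]])
    if exp[-1] <= 0:
        obs, exp = obs[:-1], exp[:-1]
    dof = max(len(obs) - 2, 1)  # one estimated parameter
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.sum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan)))
    p_value = float(stats.chi2.sf(chi2, dof))
    return GeometricFit(p_hat=p_hat, n_clumps=n, chi2=chi2, dof=dof,
                        p_value=p_value)


def _feature_stats(
    table: pd.DataFrame, suffix: str, transforms: dict[str, str] | None,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for feature in FEATURES:
        tr = transform_feature(table[feature].to_numpy(), feature, transforms)
        tr = tr[np.isfinite(tr)]
        if len(tr) == 0:
            mean = sd = float("nan")
        else:
            mean = float(np.mean(tr))
            sd = float(np.std(tr, ddof=1)) if len(tr) > 1 else float("nan")
        out[f"{feature}_mean{suffix}"] = mean
        out[f"{feature}_sd{suffix}"] = sd
    return out


def aggregate_well(
    table: pd.DataFrame,
    clumps: pd.DataFrame,
    well: str,
    plate: str = "plate",
    condition: str | None = None,
    transforms: dict[str, str] | None = None,
) -> dict:
    """One well's summary row from its retained-cell table and clump table.

    ``table`` rows must be at qc_stage "cell" with ``n_per_clump`` filled.
    An empty well yields cell_count 0 with all aggregates missing.
    """
    rows = table[table["well"] == well]
    if len(rows) and not (rows["qc_stage"] == "cell").all():
        raise ValueError("aggregate_well expects rows at qc_stage 'cell'")
    crows = clumps[clumps["well"] == well] if len(clumps) else clumps
    summary: dict = {
        "plate": plate, "well": well,
        "condition": condition if condition is not None else "",
        "cell_count": int(len(rows)),
    }
    if not len(rows):
        for feature in FEATURES:
            for suffix in ("_mean", "_sd", "_mean_single", "_sd_single"):
                summary[f"{feature}{suffix}"] = float("nan")
        summary.update(edu_positive_fraction=float("nan"),
                       fraction_single=float("nan"),
                       inverse_mean_clump_size=float("nan"), n_clumps=0)
        return summary

    summary.update(_feature_stats(rows, "", transforms))
    singles = rows[rows["n_per_clump"] == 1]
    summary.update(_feature_stats(singles, "_single", transforms))
    summary["edu_positive_fraction"] = edu_positive_fraction(
        rows["edu488_median"].to_numpy())
    n_clumps = int(len(crows))
    n_singles = int((crows["clump_size"] == 1).sum()) if n_clumps else 0
    summary["fraction_single"] = n_singles / len(rows)
    summary["n_clumps"] = n_clumps
    if n_clumps:
        fit = fit_geometric_clumps(crows["clump_size"].to_numpy())
        summary["inverse_mean_clump_size"] = fit.p_hat
    else:
        summary["inverse_mean_clump_size"] = float("nan")
    return summary


def aggregate_plate(
    table: pd.DataFrame,
    clumps: pd.DataFrame,
    layout=None,
    plate: str = "plate",
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """WellSummary table over every well present in the object table."""
    wells = sorted(set(table["well"]).union(clumps["well"] if len(clumps) else []))
    rows = []
    for well in wells:
        condition = layout.condition_of(well) if layout is not None else None
        rows.append(aggregate_well(table, clumps, well, plate=plate,
                                   condition=condition, transforms=transforms))
    return pd.DataFrame(rows)
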