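"""Reaction norms, natural-spline fits and environmental optima.

A reaction norm is one genotype's growth rate as a function of one
environmental parameter's settings.  Optima are estimated by least-squares
fitting a natural cubic spline (piecewise cubic, linear beyond the boundary
knots) over the setting axis and locating the argmax of the fitted curve by
dense grid search within the observed range — natural splines do not permit
extrapolation, so no value outside the range is ever reported.

The sucrose axis is fitted on log10(setting) because its grid spans more
than three orders of magnitude; all other parameters use the raw axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ValidationError

__all__ = [
    "ReactionNorm",
    "SplineFit",
    "OptimumEstimate",
    "natural_spline_basis",
    "build_norm",
    "fit_natural_spline",
    "estimate_optimum",
    "elevation_and_shape",
]

log = logging.getLogger(__name__)

LOG_AXIS_PARAMS = frozenset({"sucrose"})


@dataclass
class ReactionNorm:
    """Per-setting means and standard errors plus the replicate-level data."""

    genotype: str
    env_param: str
    settings: np.ndarray
    mean_rates: np.ndarray
    se_rates: np.ndarray
    rep_settings: np.ndarray = field(default=None)  # type: ignore[assignment]
    rep_rates: np.ndarray = field(default=None)     # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.settings = np.asarray(self.settings, dtype=float)
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        self.se_rates = np.asarray(self.se_rates, dtype=float)
        if np.any(np.diff(self.settings) <= 0):
            raise ValidationError("settings must be strictly increasing")
        if not (len(self.settings) == len(self.mean_rates) == len(self.se_rates)):
            raise ValidationError("settings/means/SEs must have equal length")
        if self.rep_settings is None:
            self.rep_settings = self.settings.copy()
            self.rep_rates = self.mean_rates.copy()
        else:
            self.rep_settings = np.asarray(self.rep_settings, dtype=float)
            self.rep_rates = np.asarray(self.rep_rates, dtype=float)


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Basis (without intercept) for natural cubic splines on ``knots``.

    For K knots xi_1 < ... < xi_K the returned matrix has K-1 columns:
    x itself plus the K-2 functions d_k(x) - d_{K-1}(x), where
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
    Together with a constant these span the K-dimensional space of cubic
    splines that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = knots.size
    if K < 2:
        raise ValidationError("need at least 2 knots")

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [x]
    if K > 2:
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """Fitted natural spline for one reaction norm; evaluable in-range only."""

    genotype: str
    env_param: str
    knots: np.ndarray          # on the (possibly log) fitting axis
    coef: np.ndarray           # intercept first
    x_min: float               # original setting axis
    x_max: float
    log_axis: bool

    def _transform(self, settings: np.ndarray) -> np.ndarray:
        return np.log10(settings) if self.log_axis else settings

    def __call__(self, settings) -> np.ndarray:
        settings = np.asarray(settings, dtype=float)
        if np.any(settings < self.x_min - 1e-12) or np.any(settings > self.x_max + 1e-12):
            raise ValidationError(
                f"no extrapolation outside [{self.x_min}, {self.x_max}]"
            )
        basis = natural_spline_basis(self._transform(settings), self.knots)
        return self.coef[0] + basis @ self.coef[1:]

    predict = __call__


@dataclass
class OptimumEstimate:
    genotype: str
    env_param: str
    optimum_setting: float
    optimum_rate: float
    at_boundary: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_norm(table: pd.DataFrame, genotype: str, env_param: str) -> ReactionNorm:
    """Mean and SE per setting over non-missing replicates (zeros included)."""
    sub = table[(table["genotype"] == genotype) & (table["env_param"] == env_param)]
    sub = sub[sub["rate_mm_per_hr"].notna()]
    if "missing_flag" in sub.columns:
        sub = sub[sub["missing_flag"] == 0]
    grouped = sub.groupby("setting")["rate_mm_per_hr"]
    settings = np.array(sorted(grouped.groups))
    if settings.size < 4:
        raise ValidationError(
            f"genotype {genotype!r} has data at only {settings.size} settings "
            f"of {env_param!r} (need >= 4)"
        )
    full_grid = table[table["env_param"] == env_param]["setting"].unique()
    if settings.size < len(full_grid):
        log.warning(
            "genotype %s, %s: %d of %d settings have data",
            genotype, env_param, settings.size, len(full_grid),
        )
    means = grouped.mean().loc[settings].to_numpy()
    sds = grouped.std(ddof=1).loc[settings].to_numpy()
    ns = grouped.count().loc[settings].to_numpy()
    ses = np.where(ns > 1, sds / np.sqrt(ns), 0.0)
    return ReactionNorm(
        genotype=genotype,
        env_param=env_param,
        settings=settings,
        mean_rates=means,
        se_rates=ses,
        rep_settings=sub["setting"].to_numpy(dtype=float),
        rep_rates=sub["rate_mm_per_hr"].to_numpy(dtype=float),
    )


def fit_natural_spline(norm: ReactionNorm, df: int = 4, use_replicates: bool = True) -> SplineFit:
    """Least-squares natural-spline fit with ``df`` basis degrees of freedom.

    The basis has ``df`` columns plus an intercept, i.e. df + 1 total
    parameters; interior knots sit at quantiles of the fitting-axis data,
    boundary knots at its min/max.
    """
    if df < 2:
        raise ValidationError("df must be >= 2")
    n_distinct = len(np.unique(norm.settings))
    if df > n_distinct:
        raise ValidationError(f"df={df} exceeds the {n_distinct} distinct settings")
    x_raw = norm.rep_settings if use_replicates else norm.settings
    y = norm.rep_rates if use_replicates else norm.mean_rates
    log_axis = norm.env_param in LOG_AXIS_PARAMS
    x = np.log10(x_raw) if log_axis else np.asarray(x_raw, dtype=float)

    # K = df + 1 knots: 2 boundary + df - 1 interior at quantiles of the
    # distinct settings (keeps the basis invariant under replication)
    x_grid = np.log10(norm.settings) if log_axis else norm.settings
    probs = np.linspace(0.0, 1.0, df + 1)
    knots = np.unique(np.quantile(np.unique(x_grid), probs))
    if knots.size < df + 1:
        raise ValidationError("degenerate knot sequence (tied quantiles)")
    basis = np.column_stack([np.ones_like(x), natural_spline_basis(x, knots)])
    coef, *_ = np.linalg.lstsq(basis, np.asarray(y, dtype=float), rcond=None)
    return SplineFit(
        genotype=norm.genotype,
        env_param=norm.env_param,
        knots=knots,
        coef=coef,
        x_min=float(np.min(norm.settings)),
        x_max=float(np.max(norm.settings)),
        log_axis=log_axis,
    )


def estimate_optimum(fit: SplineFit, grid_step: float | None = None) -> OptimumEstimate:
    """Argmax of the fitted curve on a dense uniform grid within range.

    Ties break toward the lower setting; ``at_boundary`` marks an optimum at
    either end of the observed range.
    """
    span = fit.x_max - fit.x_min
    if grid_step is None:
        grid_step = span / 1000.0
    if not 0 < grid_step < span:
        raise ValidationError("grid_step must be positive and smaller than the range")
    n = int(round(span / grid_step)) + 1
    grid = np.linspace(fit.x_min, fit.x_max, n)
    values = fit(grid)
    idx = int(np.argmax(values))  # first max -> lower-setting tie break
    return OptimumEstimate(
        genotype=fit.genotype,
        env_param=fit.env_param,
        optimum_setting=float(grid[idx]),
        optimum_rate=float(values[idx]),
        at_boundary=idx in (0, n - 1),
    )


def elevation_and_shape(norm: ReactionNorm, control: ReactionNorm) -> dict:
    """Decompose a mutant-minus-control difference into elevation and shape.

    elevation_diff is the mean per-setting difference; shape_profile is the
    per-setting difference with the elevation removed (sums to zero).
    """
    if not np.array_equal(norm.settings, control.settings):
        raise ValidationError("norms must share the same settings grid")
    diff = norm.mean_rates - control.mean_rates
    elevation = float(np.mean(diff))
    shape = diff - elevation
    return {"elevation_diff": elevation, "shape_profile": shape}
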