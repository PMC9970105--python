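"""Monte Carlo propagation of coefficient uncertainty to mortality curves.

Each Monte Carlo replicate replaces every fixed-effect point estimate with an
independent draw from Normal(estimate, SE) and evaluates the inverse-logit
mortality probability; across many replicates the spread of probabilities
reflects estimation uncertainty.  Size-class curves across the severity
gradient (default -50..1350 RdNBR by 10, 75 draws per point, three years
post-fire) are smoothed with a tricube-weighted local linear smoother
(first-degree polynomial, span 0.25).

The plot random intercept is fixed at zero for prediction (population-level
curve); drawing plot effects from Normal(0, RE SD) is available as an option
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from statsmodels.nonparametric.smoothers_lowess import lowess

from pyrocast.glmm import MortalityModel

__all__ = [
    "MortalityCurve",
    "draw_coefficients",
    "mortality_probability",
    "species_curves",
    "default_tree_grid",
]

_P_EPS = 1e-15  # keep probabilities strictly inside (0, 1)


def draw_coefficients(
    model: MortalityModel, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Sample coefficient vectors, each element ~ Normal(estimate, SE) independently.

    Returns shape (k,) when ``size`` is None, else (size, k).  Zero standard
    errors reproduce the point estimates exactly.
    """
    se = model.std_errors
    if not np.all(np.isfinite(se)):
        raise ValueError("model has missing or non-finite standard errors")
    shape = model.coefficients.shape if size is None else (size, model.coefficients.size)
    return rng.normal(model.coefficients, se, size=shape)


def mortality_probability(draw: np.ndarray, dbh, severity, years, plot_effect=0.0):
    """Inverse-logit mortality probability for one coefficient draw.

    ``draw`` is (intercept, dbh, severity, years[, dbh:severity]); the plot
    random intercept defaults to zero (population-level prediction).
    """
    draw = np.asarray(draw, dtype=float)
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be > 0")
    severity = np.asarray(severity, dtype=float)
    eta = draw[..., 0] + draw[..., 1] * dbh + draw[..., 2] * severity + draw[..., 3] * years
    if draw.shape[-1] == 5:
        eta = eta + draw[..., 4] * dbh * severity
    eta = eta + plot_effect
    return np.clip(expit(eta), _P_EPS, 1.0 - _P_EPS)


@dataclass(frozen=True)
class MortalityCurve:
    """Sampled and smoothed mortality probabilities for one species x size class."""

    species_group: str
    dbh_class: float
    severities: np.ndarray  # strictly increasing grid
    samples: np.ndarray  # (n_grid, draws_per_point) probabilities
    mean: np.ndarray  # per-severity sample mean
    sd: np.ndarray  # per-severity sample SD
    smoothed_mean: np.ndarray
    smoothed_sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.severities) <= 0):
            raise ValueError("severity grid must be strictly increasing")


def default_tree_grid() -> np.ndarray:
    """Tree-level severity grid: -50..1350 RdNBR in 10-unit steps (141 points)."""
    return np.arange(-50.0, 1350.0 + 5.0, 10.0)


def _smooth(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    if x.size <= 3:
        return y.copy()
    return lowess(y, x, frac=span, return_sorted=False)


def species_curves(
    model: MortalityModel,
    dbh_classes: list[float] | None = None,
    severity_grid: np.ndarray | None = None,
    draws_per_point: int = 75,
    years: float = 3.0,
    seed: int = 0,
    *,
    span: float = 0.25,
    include_plot_effect: bool = False,
) -> list[MortalityCurve]:
    """Monte Carlo mortality-probability curves for several DBH size classes.

    Size classes beyond the species' maximum observed DBH are omitted.  Each
    grid point gets ``draws_per_point`` independent coefficient draws; the
    per-severity mean and SD of the sampled probabilities are smoothed with
    the local linear smoother at ``span``.
    """
    if dbh_classes is None:
        dbh_classes = [10.0, 20.0, 60.0]
    if not list(dbh_classes):
        raise ValueError("dbh_classes must be nonempty")
    grid = default_tree_grid() if severity_grid is None else np.asarray(severity_grid, float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("severity grid must be nondecreasing")
    rng = np.random.default_rng(seed)
    curves = []
    for dbh in dbh_classes:
        if np.isfinite(model.dbh_max) and dbh > model.dbh_max:
            continue  # class exceeds the data support for this species
        draws = draw_coefficients(model, rng, size=grid.size * draws_per_point)
        draws = draws.reshape(grid.size, draws_per_point, -1)
        plot_eff = 0.0
        if include_plot_effect:
            plot_eff = rng.normal(
                0.0, model.random_intercept_sd, size=(grid.size, draws_per_point)
            )
        p = mortality_probability(draws, dbh, grid[:, None], years, plot_effect=plot_eff)
        mean = p.mean(axis=1)
        sd = p.std(axis=1)
        curves.append(
            MortalityCurve(
                species_group=model.species_group,
                dbh_class=float(dbh),
                severities=grid,
                samples=p,
                mean=mean,
                sd=sd,
                smoothed_mean=_smooth(mean, grid, span),
                smoothed_sd=_smooth(sd, grid, span),
            )
        )
    return curves
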