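"""Species-level tree-mortality models.

Binomial (Bernoulli) logit regression of individual-tree death on diameter at
breast height (DBH, cm), remotely sensed burn severity (RdNBR) and years
surveyed post-fire, with a Gaussian random intercept per field plot to absorb
within-plot correlation of mortality outcomes.

The marginal likelihood integrates the plot intercept out of the Bernoulli
likelihood with adaptive Gauss--Hermite quadrature: for each plot the
integrand is re-centred at its mode and re-scaled by the curvature there, so a
modest number of nodes (default 15) is accurate even for large plots; one node
recovers the Laplace approximation.  Standard errors come from the observed
information (numerical Hessian of the marginal log-likelihood at the optimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "TREE_COLUMNS",
    "MortalityModel",
    "InestimableModelError",
    "fit_species_glmm",
    "aicc",
    "select_model",
    "nakagawa_r2",
    "standardized_effects",
]

#: required columns of a tree-record table
TREE_COLUMNS = ("plot_id", "species_group", "dbh_cm", "rdnbr", "years_post_fire", "status")

#: fixed-effect design terms, in order; the interaction term is optional
MAIN_TERMS = ("intercept", "dbh", "severity", "years")
INTERACTION_TERM = "dbh_severity"


class InestimableModelError(RuntimeError):
    """Raised when the mortality model cannot be estimated from the records
    (single outcome class, complete separation, or too few trees)."""


@dataclass(frozen=True)
class MortalityModel:
    """Fitted mortality model for one species group.

    ``coefficients`` and ``std_errors`` are ordered (intercept, dbh, severity,
    years[, dbh:severity]) on the logit scale.  ``random_intercept_sd`` is the
    plot-level SD on the logit scale.
    """

    species_group: str
    has_interaction: bool
    coefficients: np.ndarray
    std_errors: np.ndarray
    random_intercept_sd: float
    n_trees: int
    n_plots: int
    log_likelihood: float
    aicc: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    dbh_max: float = np.nan
    converged: bool = True

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        se = np.asarray(self.std_errors, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "std_errors", se)
        if coef.shape != se.shape:
            raise ValueError("coefficients and std_errors must have equal length")
        n_expected = 5 if self.has_interaction else 4
        if coef.size != n_expected:
            raise ValueError(f"expected {n_expected} coefficients, got {coef.size}")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")

    @property
    def terms(self) -> tuple[str, ...]:
        return MAIN_TERMS + ((INTERACTION_TERM,) if self.has_interaction else ())

    @property
    def n_parameters(self) -> int:
        """Estimated parameters: fixed effects plus the random-intercept SD."""
        return self.coefficients.size + 1

    def linear_predictor(self, dbh, severity, years):
        """Fixed-effects linear predictor (plot intercept at zero)."""
        dbh = np.asarray(dbh, dtype=float)
        severity = np.asarray(severity, dtype=float)
        years = np.asarray(years, dtype=float)
        b = self.coefficients
        eta = b[0] + b[1] * dbh + b[2] * severity + b[3] * years
        if self.has_interaction:
            eta = eta + b[4] * dbh * severity
        return eta


def _design_matrix(records: pd.DataFrame, include_interaction: bool) -> np.ndarray:
    dbh = records["dbh_cm"].to_numpy(dtype=float)
    sev = records["rdnbr"].to_numpy(dtype=float)
    yrs = records["years_post_fire"].to_numpy(dtype=float)
    cols = [np.ones_like(dbh), dbh, sev, yrs]
    if include_interaction:
        cols.append(dbh * sev)
    return np.column_stack(cols)


def _response(records: pd.DataFrame) -> np.ndarray:
    status = records["status"].astype(str).str.lower()
    bad = ~status.isin(("live", "dead"))
    if bad.any():
        raise ValueError(f"unknown status values: {sorted(status[bad].unique())}")
    return (status == "dead").to_numpy(dtype=float)


def _plot_index(records: pd.DataFrame) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(records["plot_id"], sort=True)
    return codes.astype(np.intp), len(uniques)


def _posterior_modes(eta_fix, y, plot_idx, n_plots, sigma2, b0=None, max_iter=60, tol=1e-11):
    """Per-plot mode and curvature of the integrand log f(b) = log-lik + log prior.

    The objective is strictly concave in b, so damped Newton converges; the
    step is clipped to avoid overshoot at extreme linear predictors.
    """
    b = np.zeros(n_plots) if b0 is None else b0.copy()
    inv_s2 = 1.0 / sigma2
    for _ in range(max_iter):
        mu = expit(eta_fix + b[plot_idx])
        g1 = np.bincount(plot_idx, weights=y - mu, minlength=n_plots) - b * inv_s2
        g2 = -np.bincount(plot_idx, weights=mu * (1.0 - mu), minlength=n_plots) - inv_s2
        step = g1 / g2
        np.clip(step, -4.0, 4.0, out=step)
        b -= step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(eta_fix + b[plot_idx])
    g2 = -np.bincount(plot_idx, weights=mu * (1.0 - mu), minlength=n_plots) - inv_s2
    return b, g2


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _marginal_nll(theta, X, y, plot_idx, n_plots, z, logw):
    """Negative marginal log-likelihood via adaptive Gauss--Hermite quadrature."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    eta_fix = X @ beta
    b_hat, g2 = _posterior_modes(eta_fix, y, plot_idx, n_plots, sigma2)
    tau = 1.0 / np.sqrt(-g2)  # curvature scale at the mode

    # nodes: b_k = b_hat + tau * z_k  (probabilists' Hermite nodes/weights)
    terms = np.empty((z.size, n_plots))
    for k, zk in enumerate(z):
        b_k = b_hat + tau * zk
        eta = eta_fix + b_k[plot_idx]
        # Bernoulli log-lik: y*eta - log(1+e^eta) summed per plot
        ll_tree = y * eta + log_expit(-eta)
        ll_plot = np.bincount(plot_idx, weights=ll_tree, minlength=n_plots)
        log_prior = -0.5 * (b_k / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
        terms[k] = logw[k] + 0.5 * zk * zk + ll_plot + log_prior
    m = terms.max(axis=0)
    log_int = m + np.log(np.sum(np.exp(terms - m), axis=0)) + np.log(tau)
    return -float(np.sum(log_int))


def _numerical_hessian(f, x, h=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -8.0, 3.0


def fit_species_glmm(
    records: pd.DataFrame,
    include_interaction: bool = False,
    *,
    n_quad: int = 15,
    min_trees: int = 50,
    gtol: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
) -> MortalityModel:
    """Fit the random-intercept logit mortality model for one species group.

    Parameters
    ----------
    records
        Tree records of a single species group (columns ``TREE_COLUMNS``).
    include_interaction
        Add the DBH x severity interaction to the main effects.
    n_quad
        Adaptive Gauss--Hermite nodes; 1 gives the Laplace approximation.
    min_trees
        Refuse to fit below this record count.
    gtol
        Projected-gradient tolerance for declaring convergence.
    n_restarts
        Additional jittered optimizer starts to guard against local optima.
    """
    if len(records) < min_trees:
        raise InestimableModelError(
            f"only {len(records)} trees; at least {min_trees} required for a stable fit"
        )
    groups = records["species_group"].unique()
    if len(groups) != 1:
        raise ValueError(f"records must hold a single species group, got {sorted(groups)}")
    y = _response(records)
    if y.min() == y.max():
        raise InestimableModelError(
            f"all trees are {'dead' if y[0] else 'live'}; model inestimable"
        )
    plot_idx, n_plots = _plot_index(records)
    if n_plots < 2:
        raise InestimableModelError("at least 2 plots are required for a random intercept")
    X = _design_matrix(records, include_interaction)
    p = X.shape[1]

    # scale columns for optimizer conditioning (severity is O(1000), dbh O(100))
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    Xs = X / scale

    z, w = hermegauss(n_quad)
    logw = np.log(w)

    def nll(theta):
        return _marginal_nll(theta, Xs, y, plot_idx, n_plots, z, logw)

    # start from plain logistic + moderate random-effect SD
    start = _plain_logistic(Xs, y)
    rng = np.random.default_rng(seed)
    starts = [np.append(start, np.log(0.3))]
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.normal(scale=0.2, size=p + 1)
        starts.append(starts[0] + jitter)

    bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    best = None
    for theta0 in starts:
        theta0 = theta0.copy()
        theta0[-1] = np.clip(theta0[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        res = minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    loglik = -best.fun
    sigma = float(np.exp(theta[-1]))
    converged = bool(best.success) or float(np.max(np.abs(best.jac))) < max(gtol, 1e-3)
    if not converged:
        warnings.warn(
            f"mortality model optimizer did not meet tolerance (status {best.status})",
            RuntimeWarning,
        )

    H = _numerical_hessian(nll, theta, h=1e-4)
    se_scaled = _wald_se(H, p)
    beta = theta[:p] / scale
    se = se_scaled / scale
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise InestimableModelError(
            "non-positive or non-finite standard errors; data may be separated"
        )

    return MortalityModel(
        species_group=str(groups[0]),
        has_interaction=include_interaction,
        coefficients=beta,
        std_errors=se,
        random_intercept_sd=0.0 if theta[-1] <= _LOG_SIGMA_MIN + 1e-9 else sigma,
        n_trees=len(records),
        n_plots=n_plots,
        log_likelihood=loglik,
        dbh_max=float(records["dbh_cm"].max()),
        converged=converged,
    )


def _plain_logistic(X, y, max_iter=100, ridge=1e-8):
    """IRLS logistic regression used for optimizer starts and the RE-free limit."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
            raise InestimableModelError("logistic start diverged; possible complete separation")
    return beta


def _wald_se(H, p):
    """SEs of the fixed effects from the observed information.

    Falls back to the fixed-effect block when the full Hessian is singular
    (e.g. the random-effect SD sits at its boundary).
    """
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)[:p]
        if np.all(d > 0):
            return np.sqrt(d)
    except np.linalg.LinAlgError:
        pass
    cov = np.linalg.pinv(H[:p, :p])
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def aicc_value(log_likelihood: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(model: MortalityModel) -> float:
    """Small-sample corrected Akaike information criterion.

    ``k`` counts the fixed effects plus the random-intercept SD.
    """
    return aicc_value(model.log_likelihood, model.n_parameters, model.n_trees)


def select_model(main: MortalityModel, interaction: MortalityModel) -> MortalityModel:
    """Choose between main-effects and interaction models.

    The interaction model is retained only when it improves AICc by at least 2;
    otherwise the simpler main-effects model is kept.
    """
    if main.n_trees != interaction.n_trees:
        raise ValueError(
            f"models fit on different records: n={main.n_trees} vs {interaction.n_trees}"
        )
    delta = aicc(main) - aicc(interaction)
    return interaction if delta >= 2.0 else main


_SIGMA2_LOGIT = np.pi ** 2 / 3.0  # distribution-specific variance of the logit link


def nakagawa_r2(model: MortalityModel, records: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R^2 on the logit-link scale (theoretical variances).

    marginal = var(fixed predictor) / (var(fixed) + var(plot RE) + pi^2/3);
    conditional adds the random-intercept variance to the numerator.
    """
    X = _design_matrix(records, model.has_interaction)
    eta = X @ model.coefficients
    s2_f = float(np.var(eta))
    s2_a = model.random_intercept_sd ** 2
    denom = s2_f + s2_a + _SIGMA2_LOGIT
    return s2_f / denom, (s2_f + s2_a) / denom


def with_fit_statistics(model: MortalityModel, records: pd.DataFrame) -> MortalityModel:
    """Return a copy of the model with AICc and R^2 filled in."""
    r2m, r2c = nakagawa_r2(model, records)
    return replace(model, aicc=aicc(model), r2_marginal=r2m, r2_conditional=r2c)


def standardized_effects(
    records: pd.DataFrame,
    include_interaction: bool = False,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit with z-scored predictors for cross-species effect-size comparison.

    DBH, severity and years are centred and scaled by their within-species SD,
    so coefficient magnitudes are comparable across predictors and species.
    Returns a table (species_group, predictor, estimate, std_error).
    """
    std = records.copy()
    for col, name in (("dbh_cm", "dbh"), ("rdnbr", "severity"), ("years_post_fire", "years")):
        x = std[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"predictor {name!r} has zero variance; cannot standardize")
        std[col] = (x - x.mean()) / sd
    model = fit_species_glmm(std, include_interaction, **fit_kwargs)
    rows = [
        {
            "species_group": model.species_group,
            "predictor": term,
            "estimate": est,
            "std_error": se,
        }
        for term, est, se in zip(model.terms, model.coefficients, model.std_errors)
    ]
    return pd.DataFrame(rows)
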