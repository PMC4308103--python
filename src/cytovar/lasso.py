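"""LASSO over a regularisation path with BIC model selection.

The criterion minimised is ``RSS + lambda * sum_j |beta_j|`` on a design whose
predictor columns are scaled to unit sample variance and whose response is
centred (the intercept is unpenalised and recovered afterwards).  Model
selection uses the per-observation BIC

    BIC = (RSS + log(n) * q * sigma2_hat) / n

with ``q`` the support size and ``sigma2_hat`` the residual variance of the
full (interaction) OLS fit, choosing the path point with the lowest BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._solvers import lasso_cd, lasso_cd_path
from .errors import ConvergenceError, ValidationError
from .io import DesignMatrix
from .linear import fit_ols

DEFAULT_N_LAMBDA = 100
DEFAULT_EPS = 1e-3
DEFAULT_TOL = 1e-9
MAX_ITER = 100_000


@dataclass(frozen=True)
class StandardizedDesign:
    """A design with unit-sample-variance columns and centred response."""

    X: np.ndarray           # standardized predictors
    y: np.ndarray           # centred response (original units)
    column_names: tuple
    x_mean: np.ndarray
    x_scale: np.ndarray     # sample SDs (ddof=1)
    y_mean: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def standardize(design: DesignMatrix) -> StandardizedDesign:
    """Centre/scale predictors to unit sample variance; centre the response."""
    X = np.asarray(design.X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [design.column_names[j] for j in np.flatnonzero(scale == 0)]
        raise ValidationError(f"zero-variance columns {bad}; design is degenerate")
    Xs = (X - mean) / scale
    y_mean = float(design.y.mean())
    return StandardizedDesign(Xs, design.y - y_mean, design.column_names,
                              mean, scale, y_mean)


@dataclass(frozen=True)
class LassoFit:
    """One LASSO solution: coefficients on both scales and the active set."""

    lam: float
    beta: np.ndarray            # standardized scale
    beta_original: np.ndarray   # back on the 0/1 coding
    intercept: float
    support: frozenset          # predictor names with nonzero coefficient
    rss: float                  # on the fitting data, original y units
    column_names: tuple

    @property
    def size(self) -> int:
        return len(self.support)


@dataclass(frozen=True)
class LassoPath:
    lambdas: np.ndarray
    fits: tuple
    n: int


@dataclass(frozen=True)
class BicSelection:
    chosen: LassoFit
    bic_values: np.ndarray
    sigma2_hat: float

    @property
    def size(self) -> int:
        return self.chosen.size


def lambda_max(sd: StandardizedDesign) -> float:
    """Smallest penalty at which the all-zero solution is optimal.

    From the stationarity condition of ``RSS + lam*||beta||_1`` at beta = 0:
    ``lam >= 2 |x_j' y|`` for every column.  A one-part-in-1e12 upward nudge
    keeps the boundary solution exactly zero under floating-point summation-
    order differences.
    """
    if sd.p == 0:
        return 0.0
    return float(2.0 * np.max(np.abs(sd.X.T @ sd.y))) * (1.0 + 1e-12)


def _package_fit(sd: StandardizedDesign, lam: float, beta_std: np.ndarray) -> LassoFit:
    beta_orig = beta_std / sd.x_scale
    intercept = sd.y_mean - float(beta_orig @ sd.x_mean)
    resid = sd.y - sd.X @ beta_std
    support = frozenset(
        sd.column_names[j] for j in range(sd.p) if beta_std[j] != 0.0
    )
    return LassoFit(float(lam), beta_std, beta_orig, intercept, support,
                    float(resid @ resid), sd.column_names)


def fit_lasso(
    sd: StandardizedDesign,
    lam: float,
    tol: float = DEFAULT_TOL,
    warm_start: np.ndarray | None = None,
) -> LassoFit:
    """Coordinate-wise minimisation of ``RSS + lam*||beta||_1`` to tolerance.

    Excluded predictors are exactly zero (soft-threshold output, no epsilon
    rounding).  Raises :class:`ConvergenceError` at the iteration cap.
    """
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    beta = np.zeros(sd.p) if warm_start is None else np.array(warm_start, dtype=float)
    status = lasso_cd(sd.X, sd.y, lam, beta, tol, MAX_ITER)
    if status < 0:
        grad = 2.0 * sd.X.T @ (sd.y - sd.X @ beta)
        gap = float(np.max(np.abs(np.abs(grad) - lam)))
        raise ConvergenceError(
            f"lasso did not converge in {MAX_ITER} iterations (stationarity gap {gap:.3e})"
        )
    return _package_fit(sd, lam, beta)


def lasso_path(
    sd: StandardizedDesign,
    n_lambda: int = DEFAULT_N_LAMBDA,
    eps: float = DEFAULT_EPS,
    tol: float = DEFAULT_TOL,
) -> LassoPath:
    """Warm-started fits on a log-spaced grid from lambda_max down to eps*lambda_max."""
    if n_lambda < 2:
        raise ValidationError("need at least 2 grid points")
    if not 0 < eps < 1:
        raise ValidationError("eps must be in (0, 1)")
    lmax = lambda_max(sd)
    if lmax == 0.0:
        # response orthogonal to every predictor: any grid is all-null
        lambdas = np.zeros(n_lambda)
        fits = tuple(_package_fit(sd, 0.0, np.zeros(sd.p)) for _ in range(n_lambda))
        return LassoPath(lambdas, fits, sd.n)
    lambdas = np.geomspace(lmax, eps * lmax, n_lambda)
    betas, status = lasso_cd_path(sd.X, sd.y, lambdas, tol, MAX_ITER)
    if np.any(status < 0):
        k = int(np.flatnonzero(status < 0)[0])
        raise ConvergenceError(f"lasso path failed to converge at lambda={lambdas[k]:.4g}")
    fits = tuple(_package_fit(sd, lambdas[k], betas[k]) for k in range(n_lambda))
    return LassoPath(lambdas, fits, sd.n)


def estimate_sigma2(design: DesignMatrix) -> float:
    """Noise-variance estimate: OLS residual variance of the full model.

    ``RSS_full / (n - p - 1)`` from the interaction-model fit on the same
    data — the standard low-dimensional plug-in for the BIC penalty.
    """
    if design.n - design.p - 1 < 1:
        raise ValidationError(
            f"sigma2 needs n - p - 1 >= 1 (n={design.n}, p={design.p})"
        )
    return fit_ols(design).sigma2_hat


def select_by_bic(
    path: LassoPath,
    sigma2_hat: float | None,
    rss_mode: str = "lasso",
    sd: StandardizedDesign | None = None,
) -> BicSelection:
    """Pick the path point minimising ``(RSS + log(n)*q*sigma2)/n``.

    ``rss_mode='lasso'`` (default) uses each fit's own RSS; ``'refit'`` uses
    the RSS of the unpenalised OLS refit on the fit's support (requires
    ``sd``).  ``sigma2_hat=None`` switches to the refit-per-support variance
    estimate ``RSS_refit/(n-q-1)`` (also requires ``sd``).  Ties go to the
    larger lambda, i.e. the sparser fit.
    """
    if not path.fits:
        raise ValidationError("empty path")
    if sigma2_hat is not None and sigma2_hat < 0:
        raise ValidationError("sigma2_hat must be non-negative")
    if (rss_mode == "refit" or sigma2_hat is None) and sd is None:
        raise ValidationError("refit conventions need the standardized design")
    n = path.n
    bics = np.empty(len(path.fits))
    logn = np.log(n)
    for k, fit in enumerate(path.fits):
        q = fit.size
        if rss_mode == "lasso":
            rss = fit.rss
        elif rss_mode == "refit":
            rss = _refit_rss(sd, fit)
        else:
            raise ValidationError(f"unknown rss_mode {rss_mode!r}")
        if sigma2_hat is None:
            if n - q - 1 < 1:
                raise ValidationError("per-support sigma2 needs n - q - 1 >= 1")
            s2 = _refit_rss(sd, fit) / (n - q - 1)
        else:
            s2 = sigma2_hat
        bics[k] = (rss + logn * q * s2) / n
    chosen = int(np.argmin(bics))  # first minimum = largest lambda (sparser)
    return BicSelection(path.fits[chosen], bics,
                        float("nan") if sigma2_hat is None else float(sigma2_hat))


def _refit_rss(sd: StandardizedDesign, fit: LassoFit) -> float:
    idx = [j for j, name in enumerate(sd.column_names) if name in fit.support]
    if not idx:
        return float(sd.y @ sd.y)
    Xa = sd.X[:, idx]
    coef, *_ = np.linalg.lstsq(Xa, sd.y, rcond=None)
    r = sd.y - Xa @ coef
    return float(r @ r)
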