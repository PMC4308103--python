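"""All-pairs interaction lasso under a strong-hierarchy restriction.

The two-way interaction model is

    Y = b0 + sum_j beta_j X_j + (1/2) sum_{j != k} theta_jk X_j X_k + eps

with Theta symmetric and zero on the diagonal, estimated by

    minimise  (1/2) sum_i (y_i - b0 - x_i'beta - (1/2) x_i'Theta x_i)^2
              + lam*||beta||_1 + (lam/2)*||Theta||_1

subject to the strong-hierarchy restriction: an interaction enters only when
both of its main effects do.  Following Bien-style convex relaxation, each
main effect is split into non-negative parts ``beta_j = b_j+ - b_j-`` and the
interaction magnitudes are capped by ``||Theta_j||_1 <= b_j+ + b_j-``.  For the
two-factor designs used here (p = 2, so Theta has the single free entry
theta_12, the coefficient of the X1*X2 column) the resulting QP is solved
exactly by accelerated projected proximal gradient with a closed-form-plus-
bisection projection (see ``_solvers``).  A scipy-based restricted-support
enumeration is kept as an independent high-precision reference.

Penalty selection follows cross-validation with the one-standard-error rule:
the largest lambda whose CV error is within one SE of the minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._solvers import hier_fista
from .errors import ConvergenceError, ValidationError
from .io import DesignMatrix

DEFAULT_N_LAMBDA = 20
DEFAULT_EPS = 0.01
DEFAULT_TOL = 1e-10
MAX_ITER = 100_000

_PREDICTORS = ("X1", "X2", "X1X2")


@dataclass(frozen=True)
class HierFit:
    """A strong-hierarchy interaction fit for two binary factors.

    ``beta``/``theta`` are on the original 0/1 coding; ``theta`` is the
    symmetric 2x2 interaction matrix with zero diagonal whose off-diagonal
    entry equals the coefficient of the X1*X2 column.  ``objective`` is the
    attained value of the penalised criterion (standardized-predictor scale);
    ``program_objective`` additionally counts the split-variable slack and is
    what the solver provably minimises.
    """

    lam: float
    beta: np.ndarray            # (beta1, beta2), original coding
    theta: np.ndarray           # 2x2 symmetric, zero diagonal
    intercept: float
    objective: float
    program_objective: float
    support: frozenset
    beta_std: np.ndarray
    theta_std: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    iterations: int

    @property
    def size(self) -> int:
        return len(self.support)

    def predict(self, X_mains: np.ndarray) -> np.ndarray:
        """Predict from a raw (n, 2) matrix of 0/1 main-effect columns."""
        X_mains = np.asarray(X_mains, dtype=float)
        x12 = X_mains[:, 0] * X_mains[:, 1]
        return (self.intercept + X_mains[:, 0] * self.beta[0]
                + X_mains[:, 1] * self.beta[1] + x12 * self.theta[0, 1])


@dataclass(frozen=True)
class HierPath:
    lambdas: np.ndarray
    fits: tuple


@dataclass(frozen=True)
class CvResult:
    """Cross-validation curve and the one-SE-rule selection."""

    lambdas: np.ndarray
    cv_error: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    chosen_fit: HierFit
    fold_errors: np.ndarray     # (folds, n_lambda)


class _Problem:
    """Standardized arrays and the QP data shared across a lambda grid."""

    def __init__(self, X_mains: np.ndarray, y: np.ndarray):
        X_mains = np.asarray(X_mains, dtype=float)
        if X_mains.ndim != 2 or X_mains.shape[1] != 2:
            raise NotImplementedError(
                "the hierarchy solver is implemented for the two-factor design (p = 2)"
            )
        x12 = X_mains[:, 0] * X_mains[:, 1]
        X3 = np.column_stack([X_mains, x12])
        self.x_mean = X3.mean(axis=0)
        self.x_scale = X3.std(axis=0, ddof=1)
        if np.any(self.x_scale == 0):
            bad = [_PREDICTORS[j] for j in np.flatnonzero(self.x_scale == 0)]
            raise ValidationError(f"constant columns {bad}; cannot standardize")
        self.Xs = (X3 - self.x_mean) / self.x_scale
        self.y_mean = float(np.mean(y))
        self.yc = np.asarray(y, dtype=float) - self.y_mean
        Z = np.column_stack([self.Xs[:, 0], -self.Xs[:, 0],
                             self.Xs[:, 1], -self.Xs[:, 1],
                             self.Xs[:, 2], -self.Xs[:, 2]])
        self.Z = Z
        self.G = Z.T @ Z
        self.c = Z.T @ self.yc
        lam_max_G = float(np.linalg.eigvalsh(self.G)[-1])
        self.step = 1.0 / lam_max_G

    def lambda_max(self) -> float:
        a = np.abs(self.Xs.T @ self.yc)
        # nudged up one part in 1e12 so the boundary fit is exactly empty
        return float(max(a[0], a[1], (a[0] + a[1] + a[2]) / 3.0)) * (1.0 + 1e-12)

    def package(self, lam: float, u: np.ndarray, iterations: int) -> HierFit:
        beta_std = np.array([u[0] - u[1], u[2] - u[3]])
        theta_std = float(u[4] - u[5])
        resid = self.yc - self.Z @ u
        loss = 0.5 * float(resid @ resid)
        objective = loss + lam * (abs(beta_std[0]) + abs(beta_std[1])) + lam * abs(theta_std)
        program_objective = loss + lam * float(np.sum(u))
        beta = beta_std / self.x_scale[:2]
        th = theta_std / self.x_scale[2]
        theta = np.array([[0.0, th], [th, 0.0]])
        intercept = self.y_mean - float(beta @ self.x_mean[:2]) - th * self.x_mean[2]
        support = frozenset(
            name for name, val in zip(_PREDICTORS, (beta_std[0], beta_std[1], theta_std))
            if val != 0.0
        )
        return HierFit(float(lam), beta, theta, intercept, objective,
                       program_objective, support, beta_std, theta_std,
                       self.x_mean, self.x_scale, self.y_mean, iterations)

    def solve(self, lam: float, tol: float, warm: np.ndarray | None) -> HierFit:
        u0 = np.zeros(6) if warm is None else np.asarray(warm, dtype=float)
        u, iters = hier_fista(self.G, self.c, lam, self.step, u0, tol, MAX_ITER)
        if iters < 0:
            grad = self.G @ u - self.c + lam
            gap = float(np.max(np.abs(np.minimum(grad, u))))
            raise ConvergenceError(
                f"hierarchy solver hit {MAX_ITER} iterations (optimality gap {gap:.3e})"
            )
        return self.package(lam, u, iters)


def _problem_from_design(design: DesignMatrix) -> _Problem:
    if design.model_form != "interaction":
        raise ValidationError(
            "fit_hier_lasso expects the interaction design (all pairwise products)"
        )
    return _Problem(design.X[:, :2], design.y)


def fit_hier_lasso(design: DesignMatrix, lam: float, tol: float = DEFAULT_TOL) -> HierFit:
    """Solve the strong-hierarchy interaction lasso at one penalty value."""
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    return _problem_from_design(design).solve(lam, tol, None)


def check_strong_hierarchy(fit: HierFit) -> bool:
    """True iff every nonzero theta_jk has both beta_j and beta_k nonzero."""
    p = fit.beta.shape[0]
    for j in range(p):
        for k in range(p):
            if fit.theta[j, k] != 0.0 and (fit.beta[j] == 0.0 or fit.beta[k] == 0.0):
                return False
    return True


def hier_path(
    design: DesignMatrix,
    n_lambda: int = DEFAULT_N_LAMBDA,
    eps: float = DEFAULT_EPS,
    tol: float = DEFAULT_TOL,
) -> HierPath:
    """Warm-started fits on a log grid from lambda_max down to eps*lambda_max."""
    prob = _problem_from_design(design)
    return _path_on_problem(prob, n_lambda, eps, tol)


def _grid(prob: _Problem, n_lambda: int, eps: float) -> np.ndarray:
    lmax = prob.lambda_max()
    if lmax == 0.0:
        return np.zeros(n_lambda)
    return np.geomspace(lmax, eps * lmax, n_lambda)


def _path_on_problem(prob, n_lambda, eps, tol, lambdas=None) -> HierPath:
    if n_lambda < 2:
        raise ValidationError("need at least 2 grid points")
    if not 0 < eps < 1:
        raise ValidationError("eps must be in (0, 1)")
    if lambdas is None:
        lambdas = _grid(prob, n_lambda, eps)
    fits = []
    warm = None
    for lam in lambdas:
        fit = prob.solve(float(lam), tol, warm)
        warm = _fit_to_u(fit)
        fits.append(fit)
    return HierPath(np.asarray(lambdas, dtype=float), tuple(fits))


def _fit_to_u(fit: HierFit) -> np.ndarray:
    b, t = fit.beta_std, fit.theta_std
    return np.array([max(b[0], 0), max(-b[0], 0), max(b[1], 0), max(-b[1], 0),
                     max(t, 0), max(-t, 0)])


def one_se_indices(cv_error: np.ndarray, cv_se: np.ndarray) -> tuple[int, int]:
    """Indices (on a decreasing penalty grid) of the CV minimum and of the
    one-SE choice: the largest penalty whose error is within one standard
    error of the minimum.  Ties in the minimum go to the larger penalty."""
    i_min = int(np.argmin(cv_error))
    band = cv_error[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_error <= band)[0])
    return i_min, i_1se


def cross_validate_hier(
    design: DesignMatrix,
    n_lambda: int = DEFAULT_N_LAMBDA,
    folds: int = 5,
    seed: int = 0,
    eps: float = DEFAULT_EPS,
    tol: float = DEFAULT_TOL,
    max_retries: int = 20,
) -> CvResult:
    """K-fold CV over the penalty grid with the one-standard-error rule.

    Folds are a seeded random partition balanced within genotype cells, so
    every training part sees all four cells.  ``cv_error`` is the mean over
    folds of the held-out MSE; ``lambda_1se`` is the largest penalty whose
    error is within one standard error of the minimum; ``chosen_fit`` is the
    refit on all rows at that penalty.
    """
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    prob = _problem_from_design(design)
    lambdas = _grid(prob, n_lambda, eps)
    X_mains, y = design.X[:, :2], design.y
    n = design.n
    rng = np.random.default_rng(seed)

    cells = [np.flatnonzero((X_mains[:, 0] == a) & (X_mains[:, 1] == b))
             for a in np.unique(X_mains[:, 0]) for b in np.unique(X_mains[:, 1])]
    cells = [c for c in cells if c.size]

    for _attempt in range(max_retries):
        assignment = np.empty(n, dtype=int)
        for cell in cells:
            perm = rng.permutation(cell)
            offset = int(rng.integers(folds))
            for i, row in enumerate(perm):
                assignment[row] = (i + offset) % folds
        ok = True
        for f in range(folds):
            tr = assignment != f
            sub = X_mains[tr]
            if (np.ptp(sub[:, 0]) == 0 or np.ptp(sub[:, 1]) == 0
                    or np.ptp(sub[:, 0] * sub[:, 1]) == 0 or tr.sum() < 5):
                ok = False
                break
        if ok:
            break
    else:
        raise ValidationError(
            f"could not draw {folds} folds with non-degenerate training parts"
        )

    fold_errors = np.empty((folds, len(lambdas)))
    for f in range(folds):
        tr = assignment != f
        te = ~tr
        sub = _Problem(X_mains[tr], y[tr])
        path = _path_on_problem(sub, len(lambdas), eps, tol, lambdas=lambdas)
        for k, fit in enumerate(path.fits):
            resid = y[te] - fit.predict(X_mains[te])
            fold_errors[f, k] = float(resid @ resid) / te.sum()

    cv_error = fold_errors.mean(axis=0)
    cv_se = fold_errors.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min, i_1se = one_se_indices(cv_error, cv_se)
    full_path = _path_on_problem(prob, len(lambdas), eps, tol,
                                 lambdas=lambdas[: i_1se + 1])
    return CvResult(lambdas, cv_error, cv_se, float(lambdas[i_min]),
                    float(lambdas[i_1se]), full_path.fits[-1], fold_errors)


# ---------------------------------------------------------------------------
# Independent reference: restricted-support enumeration via SLSQP.
# ---------------------------------------------------------------------------

#: hierarchy-feasible supports for p = 2, as index sets into u
_SUPPORT_VARS = (
    (),                      # intercept only
    (0, 1),                  # X1
    (2, 3),                  # X2
    (0, 1, 2, 3),            # X1, X2
    (0, 1, 2, 3, 4, 5),      # X1, X2, X1X2
)


def reference_best_objective(design: DesignMatrix, lam: float) -> float:
    """Best split-variable program objective over the hierarchy-feasible
    supports, each restricted subproblem solved by SLSQP to high precision.

    Serves as an independent global-optimality oracle (and exact fallback)
    for the proximal-gradient solver: the full-support subproblem is the
    unrestricted program, so the minimum over supports equals the program
    optimum.
    """
    prob = _problem_from_design(design)
    const = 0.5 * float(prob.yc @ prob.yc)  # makes the QP form equal 0.5||y-Zu||^2
    best = const  # empty support
    for vars_ in _SUPPORT_VARS[1:]:
        idx = np.asarray(vars_, dtype=int)
        G = prob.G[np.ix_(idx, idx)]
        c = prob.c[idx]
        m = len(idx)

        def fun(u, G=G, c=c):
            return 0.5 * u @ G @ u - c @ u + lam * u.sum()

        def jac(u, G=G, c=c):
            return G @ u - c + lam

        constraints = []
        if 4 in vars_:
            constraints = [
                {"type": "ineq", "fun": lambda u: u[0] + u[1] - u[4] - u[5],
                 "jac": lambda u: np.array([1., 1., 0., 0., -1., -1.])},
                {"type": "ineq", "fun": lambda u: u[2] + u[3] - u[4] - u[5],
                 "jac": lambda u: np.array([0., 0., 1., 1., -1., -1.])},
            ]
        res = minimize(fun, np.full(m, 0.01), jac=jac, method="SLSQP",
                       bounds=[(0.0, None)] * m, constraints=constraints,
                       options={"maxiter": 1000, "ftol": 1e-14})
        if res.fun + const < best:
            best = float(res.fun) + const
    return best
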