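"""Ordinary least squares for the nested model forms.

Three models of increasing complexity are compared throughout:

* ``simple``       ``Y = b0 + b1*X1``                     (chromosomal only)
* ``additive``     ``Y = b0 + b1*X1 + b2*X2``             (plus cytoplasmic)
* ``interaction``  ``Y = b0 + b1*X1 + b2*X2 + b3*X1*X2``

Fit quality is summarised by ``R2 = 1 - RSS/TSS`` and the adjusted
``Ra2 = 1 - (RSS/(n-q-1)) / (TSS/(n-1))`` with ``q`` non-intercept predictors,
and out-of-sample performance by the test-set mean squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, SingularFitError, ValidationError
from .io import MODEL_SIZE, DesignMatrix


@dataclass(frozen=True)
class OlsFit:
    """A fitted linear model on a 0/1-coded design."""

    model_form: str
    beta: np.ndarray          # (b0, b1, ..., bq) on the design's coding
    rss: float
    tss: float
    r2: float
    ra2: float
    n: int
    q: int
    coding: dict

    @property
    def sigma2_hat(self) -> float:
        """Residual variance estimate RSS/(n-q-1)."""
        return self.rss / (self.n - self.q - 1)


@dataclass(frozen=True)
class EvaluationResult:
    """Held-out performance of one fitted model."""

    model_form: str
    mse: float
    n_test: int
    ra2_test: float


def adjusted_r2(rss: float, tss: float, n: int, q: int) -> float:
    """``Ra2 = 1 - (RSS/(n-q-1)) / (TSS/(n-1))``; may be negative."""
    if n - q - 1 < 1:
        raise ValidationError(f"adjusted R2 needs n - q - 1 >= 1 (n={n}, q={q})")
    if tss <= 0:
        raise ValidationError("TSS must be positive for R2 statistics")
    return 1.0 - (rss / (n - q - 1)) / (tss / (n - 1))


def fit_ols(design: DesignMatrix) -> OlsFit:
    """Least squares with intercept; populates RSS, TSS, R2 and Ra2.

    Raises :class:`SingularFitError` on rank-deficient designs and
    :class:`ValidationError` when ``n < p + 2`` (so that ``n - q - 1 >= 1``).
    """
    n, q = design.n, design.p
    if n < q + 2:
        raise ValidationError(f"need n >= p + 2 to fit (n={n}, p={q})")
    Z = np.column_stack([np.ones(n), design.X])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise SingularFitError(
            f"rank-deficient {design.model_form} design (rank {rank} < {Z.shape[1]}); "
            f"columns {design.column_names} include a linear dependency"
        )
    beta, *_ = np.linalg.lstsq(Z, design.y, rcond=None)
    resid = design.y - Z @ beta
    rss = float(resid @ resid)
    centred = design.y - design.y.mean()
    tss = float(centred @ centred)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    ra2 = adjusted_r2(rss, tss, n, q) if tss > 0 else 1.0
    return OlsFit(design.model_form, beta, rss, tss, r2, ra2, n, q, dict(design.coding))


def predict(fit: OlsFit, design: DesignMatrix) -> np.ndarray:
    """Evaluate ``b0 + X @ b`` rowwise on a design with matching form/coding."""
    if design.model_form != fit.model_form:
        raise ContractError(
            f"fit is {fit.model_form!r} but design is {design.model_form!r}"
        )
    if dict(design.coding) != fit.coding:
        raise ContractError(
            f"coding mismatch: fit {fit.coding} vs design {design.coding}"
        )
    return fit.beta[0] + design.X @ fit.beta[1:]


def evaluate_on_test(fit: OlsFit, test_design: DesignMatrix) -> EvaluationResult:
    """Held-out MSE (and out-of-sample adjusted R2) of a trained fit.

    ``mse = mean((y_test - yhat_test)**2)``.  ``ra2_test`` recomputes the
    adjusted R2 on the test half (TSS about the test-set mean, n = n_test);
    it is ``nan`` when ``n_test - q - 1 < 1`` and may be negative.
    """
    if test_design.n < 1:
        raise ValidationError("empty test set")
    yhat = predict(fit, test_design)
    resid = test_design.y - yhat
    mse = float(resid @ resid) / test_design.n
    n_t, q = test_design.n, fit.q
    centred = test_design.y - test_design.y.mean()
    tss = float(centred @ centred)
    if n_t - q - 1 >= 1 and tss > 0:
        ra2_test = adjusted_r2(float(resid @ resid), tss, n_t, q)
    else:
        ra2_test = float("nan")
    return EvaluationResult(fit.model_form, mse, n_t, ra2_test)


def compare_models_by_mse(results: list[EvaluationResult]) -> str:
    """Model form with the lowest test MSE; ties go to the smaller model."""
    if len(results) < 2:
        raise ValidationError("need at least two evaluation results to compare")
    best = min(results, key=lambda r: (r.mse, MODEL_SIZE[r.model_form]))
    return best.model_form
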