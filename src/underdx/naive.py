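"""Classical multivariable logistic regression (no misclassification adjustment).

This is the comparator model: it treats the *recorded* schizophrenia code as
the true exposure. Maximum likelihood is computed by Newton/IRLS with
step-halving, and 95% intervals are Wald intervals exp(estimate +/- z * SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import PREDICTOR_ORDER, predictor_matrix


class SeparationError(RuntimeError):
    """The MLE does not exist (perfect or quasi-perfect separation)."""


@dataclass
class DesignMatrix:
    """Outcome vector plus the 10 predictors in canonical order (intercept implicit)."""

    y: np.ndarray
    X: np.ndarray
    names: list[str] = field(default_factory=lambda: list(PREDICTOR_ORDER))

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-d with one row per outcome")
        if self.X.shape[1] != len(self.names):
            raise ValueError("column count must match names")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("design contains non-finite values")


def build_design(cohort: pd.DataFrame, exposure: str = "reported") -> DesignMatrix:
    """Design matrix from a cohort table.

    ``exposure="reported"`` uses the recorded schizophrenia code (the naive
    analysis); ``exposure="true"`` uses the latent truth and is only available
    for simulated cohorts.
    """
    X, names = predictor_matrix(cohort, exposure=exposure)
    return DesignMatrix(y=cohort["admission"].to_numpy(float), X=X, names=names)


@dataclass
class LogisticFit:
    """MLE output: coefficient table plus fit diagnostics."""

    table: pd.DataFrame          # term, estimate, se, or_, ci_low, ci_high, level
    loglik: float
    loglik_path: list[float]     # per-iteration log-likelihood (non-decreasing)
    cov: np.ndarray              # inverse observed information
    n_iter: int
    converged: bool


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(design: DesignMatrix, level: float = 0.95,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Fit by Newton/IRLS to score norm < ``tol``.

    Raises
    ------
    ValueError
        Constant outcome or rank-deficient design.
    SeparationError
        Divergent coefficients (the hallmark of perfect separation), naming
        the offending column.
    """
    y, X = design.y, design.X
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic MLE undefined")
    Xf = np.column_stack([np.ones(y.size), X])
    names = ["intercept"] + list(design.names)
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(Xf.shape[1])
    beta[0] = np.log(y.mean() / (1.0 - y.mean()))
    eta = Xf @ beta
    ll = _loglik(y, eta)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(eta)
        grad = Xf.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (Xf * w[:, None]).T @ Xf
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as e:
            raise SeparationError(
                "information matrix singular during IRLS (fitted probabilities "
                f"degenerate); largest coefficient: {names[int(np.argmax(np.abs(beta)))]}"
            ) from e
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(50):
            cand = beta + scale * step
            eta_c = Xf @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            scale /= 2.0
        beta, eta, ll = cand, eta_c, ll_c
        path.append(ll)
        if np.max(np.abs(beta)) > 30.0:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficient for '{names[j]}' diverged (|estimate| > 30): "
                "perfect separation, MLE does not exist")
    if not converged:
        raise SeparationError(
            f"IRLS did not reach score norm < {tol} in {max_iter} iterations")

    p = expit(eta)
    H = (Xf * (p * (1 - p))[:, None]).T @ Xf
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = norm.ppf(0.5 + level / 2.0)
    old = np.seterr(over="ignore")  # a diverging Wald bound is honestly inf
    table = pd.DataFrame({
        "term": names,
        "estimate": beta,
        "se": se,
        "or_": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "level": level,
    })
    np.seterr(**old)
    return LogisticFit(table=table, loglik=ll, loglik_path=path, cov=cov,
                       n_iter=it, converged=converged)


def write_coefficient_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
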