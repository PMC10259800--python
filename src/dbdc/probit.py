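"""Single-bounded analysis: univariate probit on the first response.

The fit is delegated to statsmodels' Probit maximum likelihood; this module
adds the study's reporting conventions -- named coefficients, both classical
(inverse-Hessian) and robust (sandwich) covariances assembled explicitly from
the model's score and Hessian, and separation/convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .core import DesignMatrix

__all__ = ["ProbitFit", "SeparationError", "ConvergenceError",
           "fit_probit", "probit_loglik"]


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation: the MLE diverges."""


class ConvergenceError(RuntimeError):
    """The optimiser failed to reach the stated gradient tolerance."""


@dataclass
class ProbitFit:
    """A fitted univariate probit: Phi(x'beta) for P(yes)."""

    params: pd.Series
    cov_classical: pd.DataFrame
    cov_robust: pd.DataFrame
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    gradient_norm: float
    xbar: pd.Series

    def se(self, robust: bool = False) -> pd.Series:
        cov = self.cov_robust if robust else self.cov_classical
        return pd.Series(np.sqrt(np.diag(cov.values)), index=self.params.index)


def _check_design(design: DesignMatrix, y: np.ndarray) -> None:
    if not np.isin(y, (0, 1)).all():
        raise ValueError("response must be binary 0/1")
    if design.n != y.shape[0]:
        raise ValueError("design and response lengths differ")
    if design.n <= len(design.columns):
        raise ValueError("need more observations than parameters")
    sds = design.X.std(axis=0)
    for name, sd in zip(design.columns, sds):
        if name != "const" and sd == 0:
            raise ValueError(f"column {name!r} is constant; only 'const' may be")


def _check_separation(params: np.ndarray, X: np.ndarray, columns) -> None:
    # coefficients on unit-SD columns beyond 50 indicate (quasi-)separation
    sds = X.std(axis=0)
    scaled = np.abs(params) * np.where(sds > 0, sds, 1.0)
    if (scaled > 50).any():
        bad = [c for c, s in zip(columns, scaled) if s > 50]
        raise SeparationError(f"separation suspected in columns {bad}")


def fit_probit(design: DesignMatrix, response) -> ProbitFit:
    """Maximum-likelihood probit of a binary response on a named design.

    Newton optimisation (statsmodels) to gradient norm < 1e-8, with an
    L-BFGS fallback.  The classical covariance is the inverse negative
    Hessian; the robust covariance is the sandwich A^-1 B A^-1 with B the
    summed outer products of per-observation scores.
    """
    y = np.asarray(response, dtype=float)
    _check_design(design, y)
    model = sm.Probit(y, design.frame)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-12, disp=0,
                            warn_convergence=False)
        except np.linalg.LinAlgError:
            res = model.fit(method="lbfgs", maxiter=2000, disp=0)
        params = np.asarray(res.params, dtype=float)
        grad_norm = float(np.linalg.norm(model.score(params)))
        if not np.isfinite(grad_norm) or grad_norm > 1e-8:
            start = params if np.isfinite(params).all() else None
            res = model.fit(method="lbfgs", maxiter=5000, disp=0,
                            start_params=start)
            params = np.asarray(res.params, dtype=float)
            grad_norm = float(np.linalg.norm(model.score(params)))
    if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
        raise SeparationError(
            "perfect separation detected: the MLE diverges and coefficients "
            "are not identified"
        )
    if not np.isfinite(params).all():
        raise SeparationError(
            "likelihood degenerate (non-finite coefficients); the responses "
            "are likely perfectly separated"
        )
    _check_separation(params, design.X, design.columns)
    converged = np.isfinite(grad_norm) and grad_norm <= 1e-6
    if not converged:
        raise ConvergenceError(
            f"probit failed to converge (gradient norm {grad_norm:.2e}); "
            f"iterations: {res.mle_retvals}"
        )
    H = model.hessian(params)
    A = -H
    cov_classical = np.linalg.inv(A)
    S = model.score_obs(params)
    B = S.T @ S
    cov_robust = cov_classical @ B @ cov_classical
    idx = pd.Index(design.columns)
    return ProbitFit(
        params=pd.Series(params, index=idx),
        cov_classical=pd.DataFrame(cov_classical, index=idx, columns=idx),
        cov_robust=pd.DataFrame(cov_robust, index=idx, columns=idx),
        loglik=float(res.llf),
        loglik_null=float(res.llnull),
        converged=converged,
        n=design.n,
        gradient_norm=grad_norm,
        xbar=design.xbar,
    )


def probit_loglik(params, design: DesignMatrix, response) -> float:
    """Probit log-likelihood at arbitrary parameters (oracle hook)."""
    y = np.asarray(response, dtype=float)
    return float(sm.Probit(y, design.frame).loglike(np.asarray(params, float)))
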