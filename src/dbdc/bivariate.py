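"""Seemingly-unrelated bivariate probit for DBDC responses.

The two yes/no answers are modelled as threshold crossings of two latent
linear indices whose errors are standard bivariate normal with correlation
rho.  With q_k = 2 z_k - 1, each observation contributes

    log Phi2(q1 x1'b1, q2 x2'b2, q1 q2 rho)

to the log-likelihood.  Because the follow-up bid is a deterministic function
of the first answer, this joint likelihood is the exact full-information
likelihood of the DBDC design.  rho is optimised through atanh for an
unconstrained search and reported on the natural scale; the Wald test of
rho = 0 uses the delta method on the robust (sandwich) covariance, matching
the robust estimation convention of contingent-valuation practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from ._bvn import bivariate_cdf
from .core import DesignMatrix
from .probit import ConvergenceError, fit_probit, _check_separation

__all__ = [
    "BivariateProbitFit",
    "WaldTest",
    "bivariate_cdf",
    "bivariate_loglik",
    "fit_bivariate_probit",
    "response_correlation",
]

_SQRT_EPS = np.sqrt(np.finfo(float).eps)


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    df: int
    pvalue: float


@dataclass
class BivariateProbitFit:
    """A fitted seemingly-unrelated bivariate probit."""

    beta1: pd.Series
    beta2: pd.Series
    rho: float
    joint_covariance: pd.DataFrame   # classical, over (beta1, beta2, atanh(rho))
    covariance_robust: pd.DataFrame  # sandwich, same parameterisation
    loglik: float
    wald_rho: WaldTest | None
    converged: bool
    n: int
    gradient_norm: float
    se_rho: float
    xbar1: pd.Series
    xbar2: pd.Series

    def equation(self, k: int, robust: bool = True):
        """Coefficients, covariance block and design means for equation k."""
        if k not in (1, 2):
            raise ValueError("equation must be 1 or 2")
        coef = self.beta1 if k == 1 else self.beta2
        names = [f"eq{k}:{c}" for c in coef.index]
        cov = self.covariance_robust if robust else self.joint_covariance
        block = cov.loc[names, names].to_numpy()
        cov_df = pd.DataFrame(block, index=coef.index, columns=coef.index)
        return coef, cov_df, (self.xbar1 if k == 1 else self.xbar2)


def response_correlation(z1, z2) -> float:
    """Pearson (phi) correlation between the two binary responses."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("responses must have equal length")
    if z1.std() == 0 or z2.std() == 0:
        raise ValueError("a response vector has zero variance")
    return float(np.corrcoef(z1, z2)[0, 1])


def _pattern_probs(theta, X1, X2, q1, q2, p1, fix_rho=None):
    b1 = theta[:p1]
    if fix_rho is None:
        b2 = theta[p1:-1]
        rho = np.tanh(theta[-1])
    else:
        b2 = theta[p1:]
        rho = fix_rho
    a = q1 * (X1 @ b1)
    b = q2 * (X2 @ b2)
    r = q1 * q2 * rho
    P = np.clip(bivariate_cdf(a, b, r), 1e-300, 1.0)
    return a, b, rho, P


def bivariate_loglik(beta1, beta2, rho, design1: DesignMatrix,
                     design2: DesignMatrix, z1, z2) -> float:
    """Log-likelihood at arbitrary parameters (oracle hook for tests)."""
    q1 = 2.0 * np.asarray(z1, dtype=float) - 1.0
    q2 = 2.0 * np.asarray(z2, dtype=float) - 1.0
    a = q1 * (design1.X @ np.asarray(beta1, float))
    b = q2 * (design2.X @ np.asarray(beta2, float))
    P = np.clip(bivariate_cdf(a, b, q1 * q2 * rho), 1e-300, 1.0)
    return float(np.log(P).sum())


def _score_obs(theta, X1, X2, q1, q2, p1, fix_rho=None):
    """Per-observation score on the (beta1, beta2, atanh rho) scale."""
    a, b, rho, P = _pattern_probs(theta, X1, X2, q1, q2, p1, fix_rho)
    s = np.sqrt(max(1.0 - rho * rho, 1e-300))
    r = q1 * q2 * rho
    phi_a = stats.norm.pdf(a)
    phi_b = stats.norm.pdf(b)
    g1 = phi_a * ndtr((b - r * a) / s)
    g2 = phi_b * ndtr((a - r * b) / s)
    pdf2 = np.exp(-(a * a - 2.0 * r * a * b + b * b) / (2.0 * s * s)) \
        / (2.0 * np.pi * s)
    w1 = q1 * g1 / P
    w2 = q2 * g2 / P
    cols = [X1 * w1[:, None], X2 * w2[:, None]]
    if fix_rho is None:
        drho = q1 * q2 * pdf2 / P
        cols.append(((1.0 - rho * rho) * drho)[:, None])
    return np.hstack(cols), P


def _nll_grad(theta, X1, X2, q1, q2, p1, fix_rho=None):
    S, P = _score_obs(theta, X1, X2, q1, q2, p1, fix_rho)
    return -float(np.log(P).sum()), -S.sum(axis=0)


def _num_hessian(fun_grad, theta, *args):
    """Central finite differences of the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for j in range(k):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h
        tm[j] -= h
        gp = fun_grad(tp, *args)[1]
        gm = fun_grad(tm, *args)[1]
        H[:, j] = (gp - gm) / (2.0 * h)
    return (H + H.T) / 2.0


def fit_bivariate_probit(
    design1: DesignMatrix,
    design2: DesignMatrix,
    z1,
    z2,
    fix_rho: float | None = None,
    start: np.ndarray | None = None,
) -> BivariateProbitFit:
    """Fit the seemingly-unrelated bivariate probit by maximum likelihood.

    Start values come from the two univariate probit fits with atanh(rho) = 0;
    BFGS on (beta1, beta2, atanh rho) with the analytic gradient, accepted
    when the gradient norm falls below 1e-6.  ``fix_rho`` constrains the
    correlation (e.g. 0 for the independence fit used in likelihood-ratio
    style comparisons); the Wald test is then not defined and reported as None.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    n = design1.n
    if design2.n != n or z1.shape[0] != n or z2.shape[0] != n:
        raise ValueError("designs and responses must share row order and length")
    p1, p2 = len(design1.columns), len(design2.columns)
    nfree = p1 + p2 + (0 if fix_rho is not None else 1)
    if n <= nfree:
        raise ValueError("need more observations than parameters")
    q1 = 2.0 * z1 - 1.0
    q2 = 2.0 * z2 - 1.0

    if start is None:
        f1 = fit_probit(design1, z1)
        f2 = fit_probit(design2, z2)
        start = np.concatenate([f1.params.to_numpy(), f2.params.to_numpy(),
                                [] if fix_rho is not None else [0.0]])
    args = (design1.X, design2.X, q1, q2, p1, fix_rho)
    res = optimize.minimize(
        _nll_grad, start, args=args, jac=True, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 2000},
    )
    theta = res.x
    grad_norm = float(np.linalg.norm(_nll_grad(theta, *args)[1]))
    if grad_norm > 1e-6:
        # polish with Newton steps on the numerical Hessian
        for _ in range(20):
            g = _nll_grad(theta, *args)[1]
            H = _num_hessian(_nll_grad, theta, *args)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            theta = theta - step
            grad_norm = float(np.linalg.norm(_nll_grad(theta, *args)[1]))
            if grad_norm <= 1e-6:
                break
    converged = grad_norm <= 1e-6
    if not converged:
        raise ConvergenceError(
            f"bivariate probit failed to converge (gradient norm {grad_norm:.2e})"
        )

    b1 = theta[:p1]
    if fix_rho is None:
        b2 = theta[p1:-1]
        rho = float(np.tanh(theta[-1]))
    else:
        b2 = theta[p1:]
        rho = float(fix_rho)
    _check_separation(b1, design1.X, design1.columns)
    _check_separation(b2, design2.X, design2.columns)
    if abs(rho) > 0.9999:
        warnings.warn("rho estimate at the boundary |rho| ~ 1", RuntimeWarning)

    names = [f"eq1:{c}" for c in design1.columns] \
        + [f"eq2:{c}" for c in design2.columns]
    if fix_rho is None:
        names.append("atanh(rho)")
    H = _num_hessian(_nll_grad, theta, *args)   # Hessian of the negative ll
    cov_classical = np.linalg.inv(H)
    S, P = _score_obs(theta, *args[:-1], fix_rho)
    B = S.T @ S
    cov_robust = cov_classical @ B @ cov_classical
    idx = pd.Index(names)
    cov_classical = pd.DataFrame(cov_classical, index=idx, columns=idx)
    cov_robust = pd.DataFrame(cov_robust, index=idx, columns=idx)

    wald = None
    se_rho = float("nan")
    if fix_rho is None:
        var_eta = float(cov_robust.loc["atanh(rho)", "atanh(rho)"])
        se_rho = (1.0 - rho * rho) * np.sqrt(max(var_eta, 0.0))  # delta method
        if se_rho > 0:
            w = (rho / se_rho) ** 2
            wald = WaldTest(float(w), 1, float(stats.chi2.sf(w, 1)))
    loglik = float(np.log(P).sum())
    return BivariateProbitFit(
        beta1=pd.Series(b1, index=pd.Index(design1.columns)),
        beta2=pd.Series(b2, index=pd.Index(design2.columns)),
        rho=rho,
        joint_covariance=cov_classical,
        covariance_robust=cov_robust,
        loglik=loglik,
        wald_rho=wald,
        converged=converged,
        n=n,
        gradient_norm=grad_norm,
        se_rho=se_rho,
        xbar1=design1.xbar,
        xbar2=design2.xbar,
    )
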