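"""Mean-WTP point estimates and Krinsky-Robb simulated confidence intervals.

For a probit-type fit with bid coefficient beta0 and remaining coefficients
beta over design columns with sample means xbar, the mean willingness to pay
is the closed form

    mean WTP = -(xbar' beta) / beta0 .

The Krinsky-Robb procedure propagates estimation uncertainty by drawing
parameter vectors from the estimated sampling distribution N(theta_hat, V_hat)
and recomputing the WTP statistic for each draw; percentile intervals of the
draws form the confidence interval, and the achieved significance level (ASL)
for H0: WTP <= 0 vs H1: WTP > 0 is the fraction of draws at or below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WtpEstimate", "mean_wtp", "mean_wtp_se", "krinsky_robb",
           "wtp_from_fit"]


@dataclass
class WtpEstimate:
    """A simulated WTP estimate.

    ``point`` is the plug-in closed-form value at the fitted coefficients;
    ``draw_mean``/``draw_median`` summarise the Krinsky-Robb draw
    distribution.  Percentile intervals of a ratio statistic can be asymmetric
    and in pathological fits need not bracket the plug-in point, so no
    ordering is enforced.  ``ci_mc_se`` is a quantile-spacing estimate of the
    Monte-Carlo standard error of each CI endpoint.
    """

    point: float
    ci_lower: float
    ci_upper: float
    level: float
    asl: float
    n_draws: int
    seed: int | None
    n_discarded: int
    draw_mean: float
    draw_median: float
    ci_mc_se: tuple[float, float]
    draws: np.ndarray = field(repr=False, default=None)


def _split(coef: pd.Series, xbar: pd.Series, bid_name: str):
    if bid_name not in coef.index:
        raise KeyError(f"bid column {bid_name!r} not among coefficients")
    other = [c for c in coef.index if c != bid_name]
    xb = xbar.reindex(other)
    if xb.isna().any():
        raise KeyError(f"xbar lacks entries for {list(xb.index[xb.isna()])}")
    return other, xb.to_numpy()


def mean_wtp(coef: pd.Series, xbar: pd.Series, bid_name: str) -> float:
    """Closed-form mean WTP, -(xbar' beta)/beta0.

    ``xbar`` holds the means of the non-bid design columns (1 for the
    constant); a bid entry, if present, is ignored.
    """
    other, xb = _split(coef, xbar, bid_name)
    beta0 = float(coef[bid_name])
    if beta0 == 0.0:
        raise ZeroDivisionError("bid coefficient is zero; mean WTP undefined")
    return float(-(xb @ coef[other].to_numpy()) / beta0)


def mean_wtp_se(coef: pd.Series, cov: pd.DataFrame, xbar: pd.Series,
                bid_name: str) -> float:
    """Delta-method standard error of the closed-form mean WTP."""
    other, xb = _split(coef, xbar, bid_name)
    beta0 = float(coef[bid_name])
    num = float(xb @ coef[other].to_numpy())
    grad = pd.Series(0.0, index=coef.index)
    grad[other] = -xb / beta0
    grad[bid_name] = num / beta0 ** 2
    V = cov.loc[coef.index, coef.index].to_numpy()
    g = grad.to_numpy()
    return float(np.sqrt(g @ V @ g))


def _sym_sqrt(V: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(V)
    tol = -1e-8 * max(vals.max(), 1.0)
    if vals.min() < tol:
        raise ValueError("covariance is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def _endpoint_mc_se(draws: np.ndarray, q: float) -> float:
    """MC standard error of the q-quantile via quantile spacing."""
    n = draws.size
    dq = 0.01
    lo, hi = np.quantile(draws, [max(q - dq, 0.0), min(q + dq, 1.0)])
    dens_inv = (hi - lo) / (2 * dq) if hi > lo else 0.0
    return float(np.sqrt(q * (1 - q) / n) * dens_inv)


def krinsky_robb(
    coef: pd.Series,
    cov: pd.DataFrame | np.ndarray,
    xbar: pd.Series,
    bid_name: str,
    n_draws: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
    beta0_tol: float = 1e-12,
) -> WtpEstimate:
    """Krinsky-Robb simulated CI and ASL for the mean WTP.

    Draws are theta_hat + Z S with S the symmetric square root of the
    covariance, so the procedure is deterministic given ``seed``.  Draws with
    a numerically degenerate bid coefficient (|beta0| < ``beta0_tol``) are
    discarded and counted; negative-WTP draws are retained (they are what
    produce negative lower bounds for weakly identified fits).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    V = cov.loc[coef.index, coef.index].to_numpy() if isinstance(cov, pd.DataFrame) \
        else np.asarray(cov, dtype=float)
    if V.shape != (coef.size, coef.size):
        raise ValueError("covariance not conformable with the coefficients")
    root = _sym_sqrt(V)
    rng = np.random.default_rng(seed)
    draws_theta = coef.to_numpy() + rng.standard_normal((n_draws, coef.size)) @ root

    other, xb = _split(coef, xbar, bid_name)
    pos = {c: i for i, c in enumerate(coef.index)}
    num = -(draws_theta[:, [pos[c] for c in other]] @ xb)
    den = draws_theta[:, pos[bid_name]]
    keep = np.abs(den) >= beta0_tol
    n_disc = int(n_draws - keep.sum())
    if n_disc > 0.01 * n_draws:
        warnings.warn(
            f"{n_disc} of {n_draws} draws had a degenerate bid coefficient",
            RuntimeWarning,
        )
    wtp_d = num[keep] / den[keep]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(wtp_d, [alpha, 1.0 - alpha])
    return WtpEstimate(
        point=mean_wtp(coef, xbar, bid_name),
        ci_lower=float(lo),
        ci_upper=float(hi),
        level=level,
        asl=float(np.mean(wtp_d <= 0.0)),
        n_draws=n_draws,
        seed=seed,
        n_discarded=n_disc,
        draw_mean=float(wtp_d.mean()),
        draw_median=float(np.median(wtp_d)),
        ci_mc_se=(_endpoint_mc_se(wtp_d, alpha), _endpoint_mc_se(wtp_d, 1 - alpha)),
        draws=wtp_d,
    )


def wtp_from_fit(fit, bid_name: str, equation: int = 2, robust: bool = True,
                 n_draws: int = 10_000, seed: int | None = None,
                 level: float = 0.95) -> WtpEstimate:
    """Krinsky-Robb WTP from a fitted model.

    For a bivariate fit, ``equation`` selects the single-bounded (1) or
    double-bounded (2, default) equation; for a univariate probit fit the
    argument is ignored.
    """
    if hasattr(fit, "equation"):  # bivariate
        coef, cov, xbar = fit.equation(equation, robust=robust)
    else:
        coef = fit.params
        cov = fit.cov_robust if robust else fit.cov_classical
        xbar = fit.xbar
    return krinsky_robb(coef, cov, xbar, bid_name, n_draws=n_draws, seed=seed,
                        level=level)
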