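"""Synthetic DBDC respondent generation.

The generator emulates the Selangor HFMD-vaccine survey structure: covariates
drawn from the study's sample frequencies, a latent willingness to pay that is
linear in the effects-coded covariates with bivariate-normal errors across the
two responses, initial bids drawn uniformly from the MYR 100-400 schedule, and
the +/- MYR 50 follow-up rule.  Each response is a threshold crossing of its
own latent draw, so the generated data carry exactly the correlation structure
the seemingly-unrelated bivariate probit assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import (
    BidDesign,
    CATEGORY_LEVELS,
    COVARIATES,
    Respondent,
    frame_to_respondents,
)
from ._bvn import bivariate_cdf

__all__ = ["SyntheticConfig", "DEFAULT_COVARIATE_FREQS", "generate_frame",
           "generate_respondents", "pattern_probabilities"]

#: Sample category frequencies of the Selangor survey (normalised at use).
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "district": {
        "sabak bernam": 126.1, "kuala selangor": 251.2, "klang": 1025.1,
        "kuala langat": 270.1, "petaling": 2157.0, "sepang": 256.9,
        "ulu langat": 1370.2, "gombak": 815.2, "ulu selangor": 237.6,
    },
    "gender": {"male": 0.2974, "female": 0.7026},
    "age_band": {"20-30": 0.0744, "31-40": 0.7205, "41-50": 0.1872,
                 "51-60": 0.0179},
    "ethnicity": {"malay": 0.6487, "chinese": 0.2385, "indian": 0.1051,
                  "others": 0.0077},
    "education": {"high-school-or-below": 0.2128, "certificate-or-diploma": 0.3103,
                  "bachelor": 0.4051, "postgraduate": 0.0718},
    "income_band": {"<1000": 0.0333, "1001-3000": 0.2769, "3001-5000": 0.2590,
                    "5001-7000": 0.1051, ">=7001": 0.3256},
}


@dataclass
class SyntheticConfig:
    """True parameters of the latent-WTP data-generating process.

    gamma maps effects-coded design columns (plus "const") to MYR effects on
    the latent WTP; unreferenced columns get effect 0.  The defaults --
    intercept 400 MYR, error SD 300 MYR, cross-response correlation 0.7 --
    produce response-pattern shares broadly like the study's observed table.
    """

    n: int = 390
    gamma: Mapping[str, float] = field(default_factory=lambda: {"const": 400.0})
    sigma: float = 300.0
    rho_true: float = 0.7
    bid_design: BidDesign = field(default_factory=BidDesign)
    covariate_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_FREQS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if abs(self.rho_true) > 1:
            raise ValueError("|rho_true| must be <= 1")
        for var, freqs in self.covariate_freqs.items():
            if any(v < 0 for v in freqs.values()) or sum(freqs.values()) <= 0:
                raise ValueError(f"invalid frequency table for {var!r}")


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for var in ("district", *COVARIATES):
        freqs = config.covariate_freqs.get(var, DEFAULT_COVARIATE_FREQS[var])
        levels = [lv for lv in CATEGORY_LEVELS[var] if lv in freqs]
        p = np.array([freqs[lv] for lv in levels], dtype=float)
        cols[var] = rng.choice(levels, size=config.n, p=p / p.sum())
    return pd.DataFrame(cols)


def _schema_effects(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Effects coding against the full category schema (reference = last
    listed level), independent of which levels happen to be observed, so the
    latent index is well defined at any sample size."""
    blocks = [np.ones((len(frame), 1))]
    names = ["const"]
    for cov in COVARIATES:
        levels = CATEGORY_LEVELS[cov]
        ref = levels[-1]
        obs = frame[cov].to_numpy()
        for lv in levels[:-1]:
            col = np.where(obs == lv, 1.0, np.where(obs == ref, -1.0, 0.0))
            blocks.append(col[:, None])
            names.append(f"{cov}[{lv}]")
    return np.hstack(blocks), names


def generate_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a respondent table (same seed -> byte-identical CSV)."""
    rng = np.random.default_rng(config.seed)
    frame = _draw_covariates(config, rng)
    X, columns = _schema_effects(frame)
    gamma = dict(config.gamma)
    unknown = set(gamma) - set(columns)
    if unknown:
        raise ValueError(
            f"gamma refers to columns not in the design: {sorted(unknown)}; "
            f"available: {columns}"
        )
    gvec = np.array([gamma.get(c, 0.0) for c in columns])
    xgamma = X @ gvec

    zdraw = rng.standard_normal((config.n, 2))
    rho = config.rho_true
    e1 = config.sigma * zdraw[:, 0]
    if abs(rho) == 1.0:
        e2 = np.sign(rho) * e1
    else:
        e2 = config.sigma * (rho * zdraw[:, 0] + np.sqrt(1 - rho * rho) * zdraw[:, 1])
    wtp1 = xgamma + e1
    wtp2 = xgamma + e2

    bids = np.asarray(config.bid_design.initial_bids, dtype=float)
    bid1 = rng.choice(bids, size=config.n)
    z1 = (wtp1 >= bid1).astype(int)
    bid2 = np.where(z1 == 1, bid1 + config.bid_design.increment,
                    bid1 - config.bid_design.increment)
    z2 = (wtp2 >= bid2).astype(int)

    frame.insert(0, "id", [f"r{i + 1:05d}" for i in range(config.n)])
    frame["bid1"] = bid1
    frame["z1"] = z1
    frame["bid2"] = bid2
    frame["z2"] = z2
    return frame


def generate_respondents(config: SyntheticConfig) -> list[Respondent]:
    """Simulate :class:`Respondent` records (see :func:`generate_frame`)."""
    return frame_to_respondents(generate_frame(config))


def pattern_probabilities(
    xgamma, sigma: float, rho: float, bid1, bid2_up=None, bid2_down=None,
    increment: float = 50.0,
):
    """Analytic probabilities of the four response patterns.

    With latent WTP_k = xgamma + eps_k, eps bivariate normal with SD sigma and
    correlation rho, and threshold responses z_k = 1{WTP_k >= bid_k}, the four
    pattern probabilities are bivariate-normal orthant masses.  Serves as the
    closed-form oracle for the simulator and the likelihood.  Returns a dict
    with keys "YY", "YN", "NY", "NN"; inputs broadcast.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    xgamma = np.asarray(xgamma, dtype=float)
    bid1 = np.asarray(bid1, dtype=float)
    b_up = bid1 + increment if bid2_up is None else np.asarray(bid2_up, dtype=float)
    b_dn = bid1 - increment if bid2_down is None else np.asarray(bid2_down, dtype=float)
    a1 = (bid1 - xgamma) / sigma      # P(no at bid1) = Phi(a1)
    a_up = (b_up - xgamma) / sigma
    a_dn = (b_dn - xgamma) / sigma
    p_yy = bivariate_cdf(-a1, -a_up, rho)
    p_yn = ndtr(-a1) - p_yy
    p_nn = bivariate_cdf(a1, a_dn, rho)
    p_ny = ndtr(a1) - p_nn
    clip = lambda p: np.clip(p, 0.0, 1.0)
    return {"YY": clip(p_yy), "YN": clip(p_yn), "NY": clip(p_ny), "NN": clip(p_nn)}
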