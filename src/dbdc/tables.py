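"""Descriptive tables and screening diagnostics.

The response-distribution table (counts of the four DBDC answer patterns per
initial bid), frequency tables for the categorical covariates, Pearson
chi-square association screens between covariates and the two responses, and
variance-inflation-factor multicollinearity diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .core import DesignMatrix, _as_frame

__all__ = ["ResponseTable", "tabulate_responses", "frequency_table",
           "chisq_association", "vif"]

PATTERNS = ("YY", "YN", "NY", "NN")


def _pct(count: float, denom: float) -> float:
    if denom == 0:
        return float("nan")
    return float(
        Decimal(repr(100.0 * count / denom)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class ResponseTable:
    """Pattern counts per initial bid with the study's percentage layout.

    Bid-row percentages use the row total as denominator; the Total row uses
    the grand total.  Percentages are rounded half-up to one decimal.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.loc["Total", "Total"])


def tabulate_responses(data) -> ResponseTable:
    frame = _as_frame(data)
    if len(frame) == 0:
        raise ValueError("empty dataset")
    pat = frame["z1"].map({1: "Y", 0: "N"}) + frame["z2"].map({1: "Y", 0: "N"})
    counts = (
        pd.crosstab(frame["bid1"], pat)
        .reindex(columns=PATTERNS, fill_value=0)
        .sort_index()
    )
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    counts.index = [b if b == "Total" else float(b) for b in counts.index]
    n = int(counts.loc["Total", "Total"])
    percent = counts.astype(float).copy()
    for idx in counts.index:
        denom = n if idx == "Total" else int(counts.loc[idx, "Total"])
        for col in counts.columns:
            percent.loc[idx, col] = _pct(int(counts.loc[idx, col]),
                                         n if idx == "Total" else denom)
        percent.loc[idx, "Total"] = _pct(int(counts.loc[idx, "Total"]), n)
    return ResponseTable(counts=counts, percent=percent)


def frequency_table(data, covariate: str) -> pd.DataFrame:
    """Level counts and half-up 2 dp percentages for one covariate."""
    frame = _as_frame(data)
    cnt = frame[covariate].value_counts()
    pct = [
        float(Decimal(repr(100.0 * c / len(frame))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP))
        for c in cnt
    ]
    return pd.DataFrame({"n": cnt, "percent": pct})


def chisq_association(data, covariate: str, response: str = "z1"):
    """Pearson chi-square between a covariate and a response, no continuity
    correction (the convention of the usual survey cross-tabulation).

    ``response`` is ``"z1"`` (single-bounded, the first answer) or ``"z2"``
    (double-bounded, the follow-up answer).  Returns (statistic, df, p).
    """
    if response not in ("z1", "z2"):
        raise ValueError("response must be 'z1' or 'z2'")
    frame = _as_frame(data)
    table = pd.crosstab(frame[covariate], frame[response])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def vif(design: DesignMatrix) -> tuple[pd.Series, float]:
    """Variance inflation factors, VIF_j = 1/(1 - R^2_j), and their mean.

    Each non-intercept column is regressed on all the others (intercept
    included); exact collinearity is reported as an infinite VIF on the
    offending column rather than raised.
    """
    cols = [c for c in design.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("need at least two non-intercept columns")
    out = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(design.columns):
            if name == "const":
                continue
            v = float(variance_inflation_factor(design.X, j))
            out[name] = np.inf if (not np.isfinite(v) or v > 1e12) else v
    series = pd.Series(out)
    return series, float(series.mean())
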