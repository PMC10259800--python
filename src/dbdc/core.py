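"""Domain types for double-bounded dichotomous choice (DBDC) survey records.

A DBDC contingent-valuation survey presents each respondent with an initial
price (bid) for the good being valued; a "yes" raises the follow-up bid by a
fixed increment, a "no" lowers it.  The pair of yes/no answers brackets the
respondent's latent willingness to pay (WTP) in one of four intervals.  This
module holds the record schema, the bid schedule, effects coding of the
categorical covariates, and the interval logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_LEVELS",
    "COVARIATES",
    "BidDesign",
    "Respondent",
    "WtpInterval",
    "DesignMatrix",
    "RespondentDataError",
    "read_respondents",
    "respondents_to_frame",
    "frame_to_respondents",
    "encode_effects",
    "build_design",
    "implied_reference_effects",
    "wtp_bounds",
]

#: Canonical category labels (matched case-insensitively after trimming).
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "district": (
        "sabak bernam", "kuala selangor", "klang", "kuala langat", "petaling",
        "sepang", "ulu langat", "gombak", "ulu selangor",
    ),
    "gender": ("male", "female"),
    "age_band": ("20-30", "31-40", "41-50", "51-60"),
    "ethnicity": ("malay", "chinese", "indian", "others"),
    "education": (
        "high-school-or-below", "certificate-or-diploma", "bachelor",
        "postgraduate",
    ),
    "income_band": ("<1000", "1001-3000", "3001-5000", "5001-7000", ">=7001"),
}

#: Demographic covariates usable as model regressors (district is a sampling
#: stratum, not a regressor, in the default analysis).
COVARIATES: tuple[str, ...] = (
    "gender", "age_band", "ethnicity", "education", "income_band",
)

CSV_COLUMNS: tuple[str, ...] = (
    "id", "district", "gender", "age_band", "ethnicity", "education",
    "income_band", "bid1", "z1", "bid2", "z2",
)


class RespondentDataError(ValueError):
    """Raised when survey records violate the DBDC schema."""


def _norm(label: object) -> str:
    return str(label).strip().lower()


@dataclass(frozen=True)
class BidDesign:
    """The DBDC bid schedule: initial bids and the fixed follow-up increment.

    Defaults reproduce the Selangor HFMD-vaccine survey design: seven initial
    bids MYR 100-400 in steps of 50 and a +/- MYR 50 follow-up, with the
    MYR->USD conversion rate 11.10/50 used when reporting dollar figures.
    """

    initial_bids: tuple[float, ...] = (100, 150, 200, 250, 300, 350, 400)
    increment: float = 50
    usd_rate: float = 11.10 / 50

    def __post_init__(self) -> None:
        bids = tuple(float(b) for b in self.initial_bids)
        if not bids:
            raise ValueError("bid schedule is empty")
        if any(b <= 0 for b in bids) or any(
            b2 <= b1 for b1, b2 in zip(bids, bids[1:])
        ):
            raise ValueError("initial bids must be strictly increasing and positive")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if bids[0] - self.increment <= 0:
            raise ValueError("follow-up bid after a 'no' at the lowest bid would be <= 0")

    def follow_up(self, bid1: float, z1: int) -> float:
        """Follow-up bid: raised after a yes, lowered after a no."""
        return bid1 + self.increment if z1 else bid1 - self.increment

    @classmethod
    def from_dict(cls, d: Mapping) -> "BidDesign":
        kw = {}
        if "initial_bids" in d:
            kw["initial_bids"] = tuple(d["initial_bids"])
        if "increment" in d:
            kw["increment"] = float(d["increment"])
        if "usd_rate" in d:
            kw["usd_rate"] = float(d["usd_rate"])
        return cls(**kw)


@dataclass(frozen=True)
class Respondent:
    """One survey record: demographics, the two bids and the two answers."""

    id: str
    district: str
    gender: str
    age_band: str
    ethnicity: str
    education: str
    income_band: str
    bid1: float
    z1: int
    bid2: float
    z2: int

    def validate(self, design: BidDesign,
                 levels: Mapping[str, Sequence[str]] = CATEGORY_LEVELS) -> None:
        for var in ("district", *COVARIATES):
            if _norm(getattr(self, var)) not in levels[var]:
                raise RespondentDataError(
                    f"unknown {var} label {getattr(self, var)!r}"
                )
        if self.z1 not in (0, 1) or self.z2 not in (0, 1):
            raise RespondentDataError("z1 and z2 must be 0 or 1")
        if not any(math.isclose(self.bid1, b) for b in design.initial_bids):
            raise RespondentDataError(
                f"bid1={self.bid1} is not on the schedule {design.initial_bids}"
            )
        expected = design.follow_up(self.bid1, self.z1)
        if not math.isclose(self.bid2, expected):
            raise RespondentDataError(
                f"bid2={self.bid2} inconsistent with z1={self.z1} "
                f"(expected {expected})"
            )
        if self.bid2 <= 0:
            raise RespondentDataError("bid2 must be positive")

    @property
    def pattern(self) -> str:
        return ("N", "Y")[self.z1] + ("N", "Y")[self.z2]


@dataclass(frozen=True)
class WtpInterval:
    """Half-open interval [lower, upper) bracketing a latent WTP."""

    lower: float
    upper: float
    pattern: str

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"empty interval [{self.lower}, {self.upper})")


def wtp_bounds(r: Respondent, floor: float = 0.0) -> WtpInterval:
    """Bracket the respondent's WTP from the two answers.

    yes-yes  -> [bid2, inf)       (accepted the raised bid)
    yes-no   -> [bid1, bid2)      (accepted bid1, refused bid1 + increment)
    no-yes   -> [bid2, bid1)      (refused bid1, accepted bid1 - increment)
    no-no    -> [floor, bid2)     (refused both; floor defaults to 0, i.e.
                                   negative WTP for a vaccine treated as
                                   economically meaningless; pass -inf to
                                   leave the interval unbounded below)
    """
    if r.z1 and r.z2:
        return WtpInterval(r.bid2, math.inf, "YY")
    if r.z1:
        return WtpInterval(r.bid1, r.bid2, "YN")
    if r.z2:
        return WtpInterval(r.bid2, r.bid1, "NY")
    return WtpInterval(floor, r.bid2, "NN")


# ---------------------------------------------------------------------------
# frames and IO

def respondents_to_frame(respondents: Iterable[Respondent]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in respondents], columns=CSV_COLUMNS)


def frame_to_respondents(frame: pd.DataFrame) -> list[Respondent]:
    return [
        Respondent(
            id=str(row.id), district=_norm(row.district), gender=_norm(row.gender),
            age_band=_norm(row.age_band), ethnicity=_norm(row.ethnicity),
            education=_norm(row.education), income_band=_norm(row.income_band),
            bid1=float(row.bid1), z1=int(row.z1),
            bid2=float(row.bid2), z2=int(row.z2),
        )
        for row in frame.itertuples(index=False)
    ]


def read_respondents(
    path,
    design: BidDesign | None = None,
    levels: Mapping[str, Sequence[str]] = CATEGORY_LEVELS,
    on_invalid: str = "raise",
) -> list[Respondent]:
    """Read and validate a respondent CSV.

    The file must carry the documented header (id, district, gender, age_band,
    ethnicity, education, income_band, bid1, z1, bid2, z2).  Category labels
    are matched case-insensitively after trimming; unknown labels, off-schedule
    initial bids and follow-up bids inconsistent with the first answer are
    schema violations.  ``on_invalid="raise"`` (default) raises a
    :class:`RespondentDataError` naming the offending rows; ``"drop"`` returns
    the valid records only.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    design = design or BidDesign()
    frame = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise RespondentDataError(f"missing columns: {missing}")
    out: list[Respondent] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(frame[list(CSV_COLUMNS)].itertuples(index=False)):
        rownum = i + 2  # 1-based, counting the header line
        try:
            r = Respondent(
                id=str(row.id), district=_norm(row.district),
                gender=_norm(row.gender), age_band=_norm(row.age_band),
                ethnicity=_norm(row.ethnicity), education=_norm(row.education),
                income_band=_norm(row.income_band),
                bid1=float(row.bid1), z1=int(row.z1),
                bid2=float(row.bid2), z2=int(row.z2),
            )
            r.validate(design, levels)
        except (RespondentDataError, TypeError, ValueError) as exc:
            bad.append((rownum, str(exc)))
            continue
        out.append(r)
    if bad and on_invalid == "raise":
        msgs = "; ".join(f"row {n}: {m}" for n, m in bad[:10])
        raise RespondentDataError(f"{len(bad)} invalid rows ({msgs})")
    return out


# ---------------------------------------------------------------------------
# design matrices

@dataclass
class DesignMatrix:
    """A dense regressor matrix with named columns (intercept first)."""

    X: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match the column names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    @property
    def xbar(self) -> pd.Series:
        """Column means; exactly 1 for the intercept column."""
        return pd.Series(self.X.mean(axis=0), index=self.columns)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return respondents_to_frame(data)


def _effects_columns(
    frame: pd.DataFrame,
    covariate: str,
    reference: str | None,
    levels: Mapping[str, Sequence[str]],
) -> tuple[np.ndarray, list[str]]:
    obs = frame[covariate].map(_norm)
    schema = levels.get(covariate)
    observed = [lv for lv in (schema or sorted(obs.unique())) if lv in set(obs)]
    if len(observed) < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than 2 observed levels")
    ref = _norm(reference) if reference is not None else observed[-1]
    if ref not in observed:
        raise ValueError(f"reference level {ref!r} not observed for {covariate!r}")
    kept = [lv for lv in observed if lv != ref]
    cols = np.zeros((len(frame), len(kept)))
    for j, lv in enumerate(kept):
        cols[:, j] = (obs == lv).astype(float)
    cols[np.asarray(obs == ref), :] = -1.0
    names = [f"{covariate}[{lv}]" for lv in kept]
    return cols, names


def encode_effects(
    data,
    covariates: Sequence[str],
    reference: Mapping[str, str] | None = None,
    levels: Mapping[str, Sequence[str]] = CATEGORY_LEVELS,
) -> DesignMatrix:
    """Effects-code categorical covariates (intercept included).

    A covariate with k observed levels yields k-1 columns, one per non-reference
    level (1 on that level, -1 on the reference level, 0 elsewhere), so the
    implied reference-level effect is minus the sum of the estimated effects
    and all k level effects sum to zero.  The reference defaults to the last
    listed level of each covariate.
    """
    frame = _as_frame(data)
    reference = reference or {}
    blocks = [np.ones((len(frame), 1))]
    names = ["const"]
    for cov in covariates:
        cols, cnames = _effects_columns(frame, cov, reference.get(cov), levels)
        blocks.append(cols)
        names.extend(cnames)
    return DesignMatrix(np.hstack(blocks), names)


def build_design(
    data,
    bid: str | None = "bid1",
    covariates: Sequence[str] = (),
    reference: Mapping[str, str] | None = None,
    levels: Mapping[str, Sequence[str]] = CATEGORY_LEVELS,
) -> DesignMatrix:
    """Estimation design: intercept, the bid column (in MYR), then effects codes."""
    frame = _as_frame(data)
    dm = encode_effects(frame, covariates, reference, levels)
    if bid is None:
        return dm
    bidcol = np.asarray(frame[bid], dtype=float)[:, None]
    X = np.hstack([dm.X[:, :1], bidcol, dm.X[:, 1:]])
    return DesignMatrix(X, ["const", bid, *dm.columns[1:]])


def implied_reference_effects(
    coefficients: pd.Series, covariates: Sequence[str]
) -> pd.Series:
    """The effects-coding identity: each reference effect = -(sum of estimated)."""
    out = {}
    for cov in covariates:
        cols = [c for c in coefficients.index if c.startswith(f"{cov}[")]
        out[cov] = -float(coefficients[cols].sum())
    return pd.Series(out)
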