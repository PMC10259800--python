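import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dbdc import (
    BidDesign,
    Respondent,
    RespondentDataError,
    build_design,
    encode_effects,
    implied_reference_effects,
    read_respondents,
    respondents_to_frame,
    wtp_bounds,
)
from dbdc.synthetic import SyntheticConfig, generate_frame


def _resp(bid1, z1, z2, design=BidDesign(), **kw):
    base = dict(id="x", district="petaling", gender="female", age_band="31-40",
                ethnicity="malay", education="bachelor", income_band=">=7001")
    base.update(kw)
    return Respondent(bid1=float(bid1), z1=z1,
                      bid2=design.follow_up(float(bid1), z1), z2=z2, **base)


@pytest.mark.parametrize(
    "bid1,z1,z2,lower,upper,pattern",
    [
        (100, 1, 1, 150, math.inf, "YY"),   # accepted the raised bid
        (200, 1, 0, 200, 250, "YN"),
        (100, 0, 1, 50, 100, "NY"),
        (100, 0, 0, 0, 50, "NN"),
    ],
)
def test_wtp_bounds_four_patterns(bid1, z1, z2, lower, upper, pattern):
    iv = wtp_bounds(_resp(bid1, z1, z2), floor=0.0)
    assert (iv.lower, iv.upper, iv.pattern) == (lower, upper, pattern)


def test_wtp_bounds_floor_configurable():
    iv = wtp_bounds(_resp(100, 0, 0), floor=-math.inf)
    assert iv.lower == -math.inf and iv.upper == 50


@given(st.sampled_from([100, 150, 200, 250, 300, 350, 400]))
def test_patterns_partition_the_line_above_floor(bid1):
    """YY/YN/NY/NN intervals are disjoint and tile [floor, inf)."""
    ivs = [wtp_bounds(_resp(bid1, z1, z2), floor=0.0)
           for z1, z2 in [(0, 0), (0, 1), (1, 0), (1, 1)]]
    ivs.sort(key=lambda iv: iv.lower)
    assert ivs[0].lower == 0.0
    for left, right in zip(ivs, ivs[1:]):
        assert left.upper == right.lower  # adjacent half-open: no gap, no overlap
    assert ivs[-1].upper == math.inf


def test_bid_design_invariants():
    with pytest.raises(ValueError):
        BidDesign(initial_bids=(100, 100, 200))
    with pytest.raises(ValueError):
        BidDesign(increment=0)
    with pytest.raises(ValueError):
        BidDesign(initial_bids=(40, 100), increment=50)  # follow-up would be <= 0


# --- effects coding ---------------------------------------------------------

def _frame(levels):
    rows = []
    for lv in levels:
        rows.append(dict(id="x", district="petaling", gender="female",
                         age_band="31-40", ethnicity="malay", education=lv,
                         income_band=">=7001", bid1=100.0, z1=1, bid2=150.0, z2=1))
    return pd.DataFrame(rows)


def test_effects_coding_rows():
    custom = {"education": ("a", "b", "c")}
    frame = _frame(["a", "b", "c", "b"])
    dm = encode_effects(frame, ["education"], levels={**{
        k: v for k, v in custom.items()}, "district": ("petaling",)})
    assert dm.columns == ["const", "education[a]", "education[b]"]
    # level b -> (0, 1); reference level c -> (-1, -1)
    assert dm.X[1].tolist() == [1.0, 0.0, 1.0]
    assert dm.X[2].tolist() == [1.0, -1.0, -1.0]


def test_effects_coding_balanced_columns_sum_to_zero():
    frame = _frame(["a", "b", "c"] * 4)
    dm = encode_effects(frame, ["education"], levels={"education": ("a", "b", "c")})
    assert np.allclose(dm.X[:, 1:].sum(axis=0), 0.0)
    assert np.allclose(dm.xbar[["education[a]", "education[b]"]], 0.0)
    assert dm.xbar["const"] == 1.0


def test_effects_level_effects_sum_to_zero():
    coefs = pd.Series({"education[a]": 0.4, "education[b]": -0.1})
    ref = implied_reference_effects(coefs, ["education"])
    assert math.isclose(coefs.sum() + ref["education"], 0.0)


def test_single_level_covariate_rejected():
    frame = _frame(["a", "a"])
    with pytest.raises(ValueError, match="fewer than 2"):
        encode_effects(frame, ["education"], levels={"education": ("a", "b")})


def test_build_design_orders_bid_after_intercept():
    cfg = SyntheticConfig(n=60, seed=3)
    fr = generate_frame(cfg)
    dm = build_design(fr, bid="bid1", covariates=["gender"])
    assert dm.columns[:2] == ["const", "bid1"]
    assert np.array_equal(dm.X[:, 1], fr["bid1"].to_numpy())


# --- CSV IO -----------------------------------------------------------------

def test_read_respondents_roundtrip(tmp_path):
    frame = generate_frame(SyntheticConfig(n=390, seed=7))
    path = tmp_path / "resp.csv"
    frame.to_csv(path, index=False)
    got = read_respondents(path)
    assert len(got) == 390
    assert respondents_to_frame(got)["bid1"].tolist() == frame["bid1"].tolist()


def test_read_respondents_rejects_followup_violation(tmp_path):
    frame = generate_frame(SyntheticConfig(n=20, seed=7))
    frame.loc[4, "bid2"] = frame.loc[4, "bid1"] - 999  # break the +/- rule
    path = tmp_path / "bad.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(RespondentDataError, match="row 6"):
        read_respondents(path)
    kept = read_respondents(path, on_invalid="drop")
    assert len(kept) == 19


def test_read_respondents_unknown_label_and_missing_column(tmp_path):
    frame = generate_frame(SyntheticConfig(n=5, seed=1))
    frame.loc[0, "education"] = "wizard"
    p1 = tmp_path / "lab.csv"
    frame.to_csv(p1, index=False)
    with pytest.raises(RespondentDataError, match="education"):
        read_respondents(p1)
    p2 = tmp_path / "mis.csv"
    frame.drop(columns=["z2"]).to_csv(p2, index=False)
    with pytest.raises(RespondentDataError, match="missing columns"):
        read_respondents(p2)


def test_labels_matched_case_insensitively(tmp_path):
    frame = generate_frame(SyntheticConfig(n=5, seed=1))
    frame["education"] = frame["education"].str.upper() + "  "
    path = tmp_path / "case.csv"
    frame.to_csv(path, index=False)
    got = read_respondents(path)
    assert all(r.education in ("high-school-or-below", "certificate-or-diploma",
                               "bachelor", "postgraduate") for r in got)
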