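import itertools

import hypothesis
import pytest

from dbdc import BidDesign, Respondent

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")

#: Response counts by initial bid (YY, YN, NY, NN) from the published
#: Selangor HFMD-vaccine survey (390 analysed respondents).
STUDY_RESPONSE_COUNTS = {
    100: (40, 3, 12, 6),
    150: (32, 6, 16, 7),
    200: (32, 11, 10, 13),
    250: (28, 3, 8, 17),
    300: (17, 3, 12, 16),
    350: (32, 8, 8, 17),
    400: (13, 8, 3, 9),
}

_PATTERN_Z = {"YY": (1, 1), "YN": (1, 0), "NY": (0, 1), "NN": (0, 0)}

# cycled demographics so every covariate keeps >= 2 observed levels
_DEMO = itertools.cycle(
    [
        ("petaling", "female", "31-40", "malay", "bachelor", ">=7001"),
        ("klang", "male", "41-50", "chinese", "certificate-or-diploma", "1001-3000"),
        ("gombak", "female", "20-30", "indian", "high-school-or-below", "3001-5000"),
        ("sepang", "male", "31-40", "malay", "postgraduate", "5001-7000"),
    ]
)


def respondents_from_counts(counts, design=None):
    """Expand a {bid: (nYY, nYN, nNY, nNN)} table into Respondent records."""
    design = design or BidDesign()
    out = []
    i = 0
    for bid, row in counts.items():
        for pattern, k in zip(("YY", "YN", "NY", "NN"), row):
            z1, z2 = _PATTERN_Z[pattern]
            for _ in range(k):
                district, gender, age, eth, edu, inc = next(_DEMO)
                i += 1
                out.append(
                    Respondent(
                        id=f"s{i:04d}", district=district, gender=gender,
                        age_band=age, ethnicity=eth, education=edu,
                        income_band=inc, bid1=float(bid), z1=z1,
                        bid2=design.follow_up(float(bid), z1), z2=z2,
                    )
                )
    return out


@pytest.fixture(scope="session")
def bid_design():
    return BidDesign()


@pytest.fixture(scope="session")
def study_counts():
    return STUDY_RESPONSE_COUNTS


@pytest.fixture(scope="session")
def study_respondents(study_counts, bid_design):
    return respondents_from_counts(study_counts, bid_design)
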