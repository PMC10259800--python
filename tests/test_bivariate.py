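import numpy as np
import pytest
from scipy.integrate import dblquad

from dbdc import (
    bivariate_cdf,
    bivariate_loglik,
    build_design,
    fit_bivariate_probit,
    probit_loglik,
    response_correlation,
)
from dbdc.synthetic import SyntheticConfig, generate_frame, pattern_probabilities


def _quad_cdf(a, b, rho, lo=-8.5):
    def dens(y, x):
        s2 = 1 - rho * rho
        return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * s2)) \
            / (2 * np.pi * np.sqrt(s2))

    val, err = dblquad(dens, lo, a, lo, b, epsabs=1e-12, epsrel=1e-12)
    return val


def test_median_orthant_closed_forms():
    assert bivariate_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-14)
    for rho in (-0.95, -0.4, 0.3, 0.7, 0.95):
        expected = 0.25 + np.arcsin(rho) / (2 * np.pi)
        assert bivariate_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-12)


def test_degenerate_correlations_use_min_max_rule():
    from scipy.stats import norm

    a, b = 0.4, -0.9
    assert bivariate_cdf(a, b, 1.0) == pytest.approx(min(norm.cdf(a), norm.cdf(b)))
    assert bivariate_cdf(a, b, -1.0) == pytest.approx(
        max(norm.cdf(a) + norm.cdf(b) - 1, 0.0))


def test_cdf_rejects_out_of_range_correlation():
    with pytest.raises(ValueError):
        bivariate_cdf(0.0, 0.0, 1.5)


def test_pattern_likelihood_contributions_sum_to_one():
    """Over the four (z1, z2) cells at fixed parameters and bids."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        w1, w2 = rng.normal(size=2) * 2
        rho = rng.uniform(-0.98, 0.98)
        total = sum(
            bivariate_cdf(q1 * w1, q2 * w2, q1 * q2 * rho)
            for q1 in (-1.0, 1.0)
            for q2 in (-1.0, 1.0)
        )
        assert abs(total - 1.0) < 1e-10


def test_response_correlation_trivial_and_phi(study_respondents):
    z1 = np.array([r.z1 for r in study_respondents])
    z2 = np.array([r.z2 for r in study_respondents])
    assert response_correlation(z1, z1) == pytest.approx(1.0)
    assert response_correlation(z1, 1 - z1) == pytest.approx(-1.0)
    # phi coefficient by hand from the 2x2 pattern table (YY,YN,NY,NN)
    a, b, c, d = 194, 42, 69, 85  # z1z2: 11, 10, 01, 00
    phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    assert response_correlation(z1, z2) == pytest.approx(phi, abs=1e-12)
    with pytest.raises(ValueError, match="zero variance"):
        response_correlation(np.ones(5), z1[:5])


def test_tiny_instance_loglik_matches_quadrature():
    cfg = SyntheticConfig(n=8, seed=2)
    frame = generate_frame(cfg)
    d1 = build_design(frame, bid="bid1")
    d2 = build_design(frame, bid="bid2")
    beta1 = np.array([1.2, -0.003])
    beta2 = np.array([1.0, -0.0025])
    rho = 0.6
    mine = bivariate_loglik(beta1, beta2, rho, d1, d2, frame["z1"], frame["z2"])
    q1 = 2 * frame["z1"].to_numpy() - 1
    q2 = 2 * frame["z2"].to_numpy() - 1
    oracle = sum(
        np.log(_quad_cdf(q1[i] * (d1.X[i] @ beta1), q2[i] * (d2.X[i] @ beta2),
                         q1[i] * q2[i] * rho))
        for i in range(8)
    )
    assert mine == pytest.approx(oracle, abs=1e-8)


def test_constrained_rho_never_beats_unconstrained():
    cfg = SyntheticConfig(n=1200, seed=41)
    frame = generate_frame(cfg)
    d1 = build_design(frame, bid="bid1")
    d2 = build_design(frame, bid="bid2")
    free = fit_bivariate_probit(d1, d2, frame["z1"], frame["z2"])
    indep = fit_bivariate_probit(d1, d2, frame["z1"], frame["z2"], fix_rho=0.0)
    assert indep.loglik <= free.loglik + 1e-9
    assert indep.wald_rho is None


def test_wald_invariant_to_consistent_sign_flip():
    cfg = SyntheticConfig(n=800, seed=53)
    frame = generate_frame(cfg)
    d1 = build_design(frame, bid="bid1")
    d2 = build_design(frame, bid="bid2")
    fit = fit_bivariate_probit(d1, d2, frame["z1"], frame["z2"])
    flipped = fit_bivariate_probit(d1, d2, 1 - frame["z1"], 1 - frame["z2"])
    assert flipped.rho == pytest.approx(fit.rho, abs=1e-5)
    np.testing.assert_allclose(flipped.beta1, -fit.beta1, atol=1e-5)
    assert flipped.wald_rho.statistic == pytest.approx(
        fit.wald_rho.statistic, rel=1e-3)


def test_generator_patterns_agree_with_fit_probabilities():
    """The fitted model reproduces the analytic pattern shares it was
    simulated from (a joint sanity check of generator and likelihood)."""
    cfg = SyntheticConfig(n=4000, seed=61)
    frame = generate_frame(cfg)
    d1 = build_design(frame, bid="bid1")
    d2 = build_design(frame, bid="bid2")
    fit = fit_bivariate_probit(d1, d2, frame["z1"], frame["z2"])
    # implied sigma/gamma0 from each equation should agree roughly
    sig1 = -1 / fit.beta1["bid1"]
    sig2 = -1 / fit.beta2["bid2"]
    assert sig1 == pytest.approx(300, rel=0.15)
    assert sig2 == pytest.approx(300, rel=0.15)
    probs = pattern_probabilities(400.0, 300.0, fit.rho, 250.0)
    assert abs(sum(map(float, probs.values())) - 1) < 1e-10
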