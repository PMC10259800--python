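# dbdc — double-bounded dichotomous choice contingent valuation

`dbdc` is a Python toolkit for planning and analysing **double-bounded
dichotomous choice (DBDC)** contingent-valuation surveys, of the kind used to
estimate parents' willingness to pay (WTP) for a hand, foot and mouth disease
(HFMD / EV71) vaccination course in Selangor, Malaysia.  In a DBDC survey each
respondent sees an initial price (bid) for the good; a "yes" raises the
follow-up bid by a fixed increment, a "no" lowers it, and the two yes/no
answers bracket the respondent's latent WTP in one of four intervals.

The package covers the full pipeline:

- **Survey design** — Krejcie–Morgan finite-population sample size
  s = [z²p(1−p)/e²] / [1 + z²p(1−p)/(e²N)], largest-remainder allocation
  across strata, defensive sample doubling, fixed-rate MYR→USD conversion.
- **Data model** — the respondent CSV schema, the bid schedule with its
  ±MYR 50 follow-up rule, effects coding of categorical covariates, and the
  WTP interval implied by each of the YY/YN/NY/NN patterns.
- **Simulation** — respondents drawn from a latent model
  WTP_k = x'γ + ε_k with (ε₁, ε₂) bivariate normal (SD σ, correlation ρ), so
  every estimator can be validated by parameter recovery.
- **Estimation** — univariate (single-bounded) probit on the first response
  and the core **seemingly-unrelated bivariate probit**, which maximises
  Σ log Φ₂(q₁x₁'β₁, q₂x₂'β₂, q₁q₂ρ), q_k = 2z_k − 1, with robust (sandwich)
  covariance and a Wald test of ρ = 0.
- **WTP inference** — the closed-form mean WTP, −(x̄'β)/β₀ where β₀ is the
  bid coefficient, with **Krinsky–Robb** simulated confidence intervals and
  achieved significance levels (ASL) from 10,000 parameter draws.
- Descriptive tables, chi-square association screens, and VIF diagnostics.

## Respondent CSV schema

One row per respondent with header
`id,district,gender,age_band,ethnicity,education,income_band,bid1,z1,bid2,z2`.
`z1`/`z2` are 0/1; `bid1` must sit on the configured schedule (default
MYR 100–400 in steps of 50) and `bid2` must equal `bid1 ± 50` according to
`z1`.  Category labels are matched case-insensitively after trimming;
education has four levels (high-school-or-below, certificate-or-diploma,
bachelor, postgraduate) and household income five bands (<1000 … >=7001 MYR).

## Worked example

Simulate a survey-sized dataset (n = 390) from the default latent model
(γ₀ = 400 MYR, σ = 300 MYR, ρ = 0.7), fit the bivariate probit, and compute
the double-bounded Krinsky–Robb WTP:

```python
from dbdc import (build_design, fit_bivariate_probit, response_correlation,
                  tabulate_responses, wtp_from_fit)
from dbdc.synthetic import SyntheticConfig, generate_frame

frame = generate_frame(SyntheticConfig(n=390, seed=20200113))
print(tabulate_responses(frame).counts.loc["Total"].tolist())
# [208, 51, 56, 75, 390]            # YY, YN, NY, NN counts and total

d1 = build_design(frame, bid="bid1")
d2 = build_design(frame, bid="bid2")
fit = fit_bivariate_probit(d1, d2, frame["z1"], frame["z2"])
print(round(fit.rho, 3), round(response_correlation(frame.z1, frame.z2), 3))
# 0.714 0.379                       # latent rho vs raw response correlation

est = wtp_from_fit(fit, bid_name="bid2", equation=2,
                   n_draws=10_000, seed=20200113)
print(f"{est.point:.2f} [{est.ci_lower:.2f}, {est.ci_upper:.2f}] ASL={est.asl:.4f}")
# 380.99 [338.94, 454.57] ASL=0.0000
```

The fitted ρ = 0.714 is the correlation of the *latent* errors; the raw
correlation between the two binary answers (0.379) is necessarily smaller.
The mean WTP of MYR 380.99 recovers the true γ₀ = 400 to within sampling
error at n = 390, the percentile CI comes from 10,000 draws of the
coefficient vector, and ASL = 0 means no draw produced WTP ≤ 0.

The same pipeline is scriptable from the shell:

```bash
dbdc design-size --population 6509400      # {"sample_size": 384, "doubled": 768}
dbdc simulate --n 390 --seed 7 --out resp.csv
dbdc fit-db --data resp.csv --eq1 "bid1 + education + income_band" \
            --eq2 "bid2 + education + income_band" --out fit.json
dbdc wtp --fit fit.json --equation 2 --draws 10000 --seed 7 --out wtp.json
```

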