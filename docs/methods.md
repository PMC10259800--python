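# Methods

## The elicitation format and its latent model

A double-bounded dichotomous choice (DBDC) survey asks each respondent
whether they would pay an initial bid P¹ for the good (here a two-dose HFMD
vaccination course); a "yes" is followed by P² = P¹ + 50 MYR, a "no" by
P² = P¹ − 50 MYR.  The two answers bracket the latent willingness to pay:

| pattern | interval |
|---|---|
| yes–yes | [P², ∞) |
| yes–no  | [P¹, P²) |
| no–yes  | [P², P¹) |
| no–no   | [floor, P²) |

The no–no lower bound is not identified by the design.  The default floor is
0 — negative WTP for a vaccine is treated as economically meaningless — with
−∞ available for users who prefer the unbounded convention.  The four
intervals partition [floor, ∞) for every bid pair, which the tests check
directly.

Each answer is modelled as a threshold crossing of its own latent index,

    z_k* = x_k'β_k + ε_k,   z_k = 1{z_k* > 0},   k = 1, 2,

with (ε₁, ε₂) standard bivariate normal with correlation ρ after scaling.  In
WTP terms the index is x'γ + ε_k − bid_k with γ = σβ (coefficients in MYR)
and σ = −1/β_bid, so the bid coefficient is negative whenever demand slopes
down.  The two equations share no parameter restrictions ("seemingly
unrelated"); they are tied only through ρ.

## Likelihood

With q_k = 2z_k − 1, each observation contributes

    log Φ₂(q₁ x₁'β₁, q₂ x₂'β₂, q₁q₂ρ),

where Φ₂ is the bivariate standard-normal CDF.  Because the follow-up bid is
a deterministic function of the first answer, this joint probability equals
the exact orthant mass of the realised response pattern, so the SUR bivariate
probit is the full-information likelihood of the DBDC design; no endogeneity
correction for the follow-up bid is needed under the model.  The four pattern
contributions sum to one at any parameter value, which is asserted to 1e-10.

**Φ₂ kernel.**  The likelihood needs Φ₂ vectorised over observations.  The
package ports the classic Drezner–Wesolowsky/Genz double-precision algorithm:
Gauss–Legendre quadrature (6/12/20 nodes by |ρ|) on the arcsine form for
|ρ| < 0.925 and the transformed near-singular integral above, with closed
forms at ρ ∈ {0, ±1}.  Absolute error is below 5e-16; tests compare it to an
independent 2-D adaptive quadrature oracle at 1e-10.

**Optimisation.**  ρ is searched through η = atanh ρ so the problem is
unconstrained.  Start values are the two univariate probit fits and η = 0;
BFGS with the analytic gradient runs to gradient norm 1e-9 (accepted below
1e-6, with Newton polishing on the finite-difference Hessian as a fallback).
Pattern probabilities are floored at 1e-300 to keep the search stable far
from the optimum.  Quasi-separation is flagged when any coefficient exceeds
50 on a unit-SD column.

**Covariances.**  The classical covariance is the inverse of the
finite-difference Hessian of the negative log-likelihood (central differences
of the analytic gradient, step 1e-5 scaled); the robust covariance is the
sandwich A⁻¹BA⁻¹ with B the summed outer products of per-observation scores.
The Wald statistic for ρ = 0 is (ρ̂/SE ρ̂)² with SE ρ̂ = (1−ρ̂²)·SE η̂ by the
delta method, using the robust covariance — contingent-valuation practice
favours robust estimation, and the package follows it.  The univariate
(single-bounded) probit is fitted through statsmodels' Probit behind the same
reporting surface, with both covariances assembled from the model's Hessian
and score.

## Mean WTP and Krinsky–Robb intervals

For a fitted equation with bid coefficient β₀ and remaining coefficients β
over columns with sample means x̄ (1 for the constant),

    mean WTP = −(x̄'β)/β₀,

which under the latent model equals x̄'γ — the population mean WTP of an
average respondent.  The Krinsky–Robb procedure draws θ_d ~ N(θ̂, V̂) via the
symmetric (eigen) square root, recomputes WTP_d for each draw, and reports
the percentile interval at the requested level, the draw mean and median, and
the achieved significance level ASL = P(WTP_d ≤ 0) for H₀: WTP ≤ 0 against
H₁: WTP > 0.  Defaults: 10,000 draws, 95% level, seeded and fully
reproducible.  Negative draws are retained — they are exactly what produces
negative lower bounds for weakly identified single-bounded fits — and only
draws with |β₀| below an absolute 1e-12 tolerance are discarded (warned above
1%, counted always).  A quantile-spacing estimate of each endpoint's
Monte-Carlo SE is reported so users can judge draw-count adequacy.  The
percentile interval of a ratio is asymmetric and, for pathological fits, need
not bracket the plug-in point; the estimate object does not hide this.

The default double-bounded WTP uses equation 2 (the follow-up response, whose
price variable is the follow-up bid), with equation 1 giving the
single-bounded analogue.

## Design arithmetic

Krejcie–Morgan sample size uses round-half-up to the nearest integer, capped
at the population (6,509,400 → 384; halving margins quadruples core size).
Stratum allocation uses largest-remainder (Hamilton) apportionment — ties
broken toward the larger stratum — because independent per-stratum rounding
cannot reproduce a fixed total; the Selangor populations give Petaling 127 of
384.  A handful of the survey's published per-district cells are not
consistent with any single rounding rule, so only the stable cells are
asserted.  Currency conversion uses the exact ratio 11.10/50 = 0.222 with
half-up rounding to 2 dp.  Table percentages are rounded half-up to 1 dp;
where a published percentage disagrees with its own count ratio (e.g. a NY
total share printed one tick high), the package reproduces the arithmetic.

## The synthetic generator

`SyntheticConfig` defaults encode the study's conditions: n = 390 analysed
respondents; covariates drawn from the survey's sample frequencies (female
70.26%, Malay 64.87%, bachelor 40.51%, …; districts by population share);
initial bids uniform over {100, …, 400} — the survey randomised bids but
published no assignment weights, so uniform is a neutral stand-in, not a
claim about the study; latent intercept γ₀ = 400 MYR, σ = 300 MYR,
ρ = 0.7, values chosen once so that pattern shares and the implied raw
response correlation (≈0.36–0.38 vs the study's 0.39) resemble the published
table.  Effects coding in the generator runs against the full category
schema so the latent index is defined at any n.  The generator is the
package's test bed: closed-form pattern probabilities (bivariate orthant
masses) serve as its analytic oracle, and empirical pattern frequencies are
checked against them at n = 10⁵ within 3 Monte-Carlo SEs.

What the generator does **not** emulate: protest zeros and never-payers (the
study excluded 52 such respondents before analysis), item nonresponse,
anchoring/shift effects between the two answers, and any dependence of bid
assignment on respondent characteristics.  Passing recovery tests therefore
show the estimators are correct under the latent model, not that the model
is true of any real survey.

## Validation experiments and problem sizes

- Oracle equivalence: Φ₂ vs 2-D quadrature (≤1e-10); joint log-likelihood at
  ρ = 0 vs the sum of univariate probit log-likelihoods (≤1e-8); grouped
  probit on the study's published per-bid first-response tallies vs a
  12-round 41×41 grid-refinement search (coefficients to 1e-4).
- Parameter recovery: ρ and both bid coefficients within 3 reported SEs at
  n = 5,000; closed-form mean WTP within 3 delta-method SEs of γ₀ at
  n = 20,000.
- Replicated experiments at the study scale use 200 independent replicates
  of n = 390 with pre-assigned seeds: Krinsky–Robb 95% coverage of the true
  mean WTP (expected 90–99%), and the single- vs double-bounded efficiency
  comparison.

On the efficiency comparison, the package's own finding is cautionary: with
intercept + bid designs in both equations, the SUR structure transfers most
of the follow-up information to *both* equations, the asymptotic SE gap
between the equation-2 and single-bounded mean-WTP estimators is only a few
percent at n = 390, and the replicate SD of a ratio-form estimator is
dominated by rare near-zero bid-coefficient draws.  The Monte-Carlo SD
ordering at a few hundred replicates is therefore close to a coin flip even
when the asymptotic ordering is strict, and the corresponding test can fail
for this structural reason rather than an implementation defect; the large
efficiency gains reported for real DBDC surveys rest on the single-bounded
bid coefficient being far more weakly identified in the field than a
correctly specified symmetric simulation makes it.

## Known limitations

- No interval-data (shared-coefficient) DBDC estimator; the package follows
  the SUR bivariate probit formulation throughout.
- No hurdle model for never-payers; generator and estimators condition on
  willingness to engage with the valuation question.
- The chi-square screen and VIF are descriptive conveniences (scipy /
  statsmodels under the hood), not model-selection machinery; replicating a
  published covariate subset remains the analyst's recipe.
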