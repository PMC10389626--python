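# Methods

## The model

`condsurv` models mortality among patients who have survived at least one
year after esophagectomy for esophageal cancer. Time is measured from the
1-year post-surgery landmark; follow-up is administratively capped at 4
landmark-years (5 post-surgery years). Each patient carries an event code
d ∈ {0 censored, 1 death from esophageal cancer, 2 death from another cause}
and covariate design vectors x_α, x_η, x_φ, x_γ, x_ρ, one per model
parameter.

The joint density of (d, t) factorizes into a cause-assignment probability
and a cause-conditional survival time:

* **Cause assignment.** f2(d=1 | x) = logit⁻¹(x_α′α) is the probability that
  a patient's eventual death is cancer-related; other-cause death gets the
  complement.
* **Cause-conditional survival.** S4(t | d, x) = logit⁻¹(v) with the linear
  time index

      v(t | d, x) = 1{d=1}·x_γ′γ + x_η′η + log(t)·x_φ′φ + 1{d=1}·log(t)·x_ρ′ρ.

  This is a log-logistic accelerated-failure-time form: η shifts the
  location of log survival time, φ is the log-time slope, and γ, ρ shift the
  location and slope for the cancer cause. S4 decreases from 1 to 0 in t iff
  the log-time slope is negative for both causes (φ₀ < 0 and φ₀ + ρ₀ < 0
  with intercept-only time terms); fits violating this are flagged, not
  rejected. Weibull and Gompertz alternatives replace the logit link by the
  complementary log-log link (the Gompertz also replaces log t by t); they
  exist only for AIC comparison and have no sampling support.

A note on the link orientation: with negative log-time slopes, the inverse
logit of v is the unique orientation under which survival decreases in time,
every published coefficient sign is clinically coherent (higher stage
harmful, longer education protective), and the published calculator example
is reproduced. The package uses it throughout.

* **Likelihood.** Death dates are recorded to the day, so an observed death
  at t contributes the interval mass f4 = S4(t) − S4(t + δ) with δ = 1/365.25
  landmark-years (configurable), times f2(d | x); a censored record
  contributes the mixture survival f5(t | x) = Σ_j S4(t | j, x) f2(j | x).
  The landmark origin makes every observed t positive, so no left-truncation
  term appears — the likelihood conditions on 1-year survival by
  construction.

## Covariate encoding

The final model's design vectors are

    x_α = (1, age_s, SCC, chemo, stage II, stage III, stage IV, R1/R2)
    x_η = (1, age_s, female, education>12, SCC, stage III, stage IV, R1/R2,
           reoperation)

with age_s = (age − 65.1)/10 (center = derivation-cohort median age, scale
one decade; both configurable). In x_η, stage II shares the 0–I reference
level. Education is binary (≤12 vs >12 years); a 3-band years column is
collapsed on input. The time-term vectors x_φ, x_γ, x_ρ are intercept-only
by default but accept arbitrary covariates, which the selection procedure
exploits. Unknown term names resolve to raw numeric columns of the cohort
table, which is how simulated predictors are planted in selection studies.

The published coefficient set ships as a flat key-value text fixture
(`condsurv/data/published_model.txt`) and loads via
`published_parameters()`.

## Fitting

`fit_mle` maximizes the log-likelihood by BFGS with a hand-derived analytic
gradient (unit-tested against central differences for all three families).
Defaults: 3 jittered starting points (σ = 0.1, seeded) from a neutral start
(zeros; η₀ = 1, φ₀ = −0.5, ρ₀ = −0.1, inside the monotone region), relative
gradient tolerance 1e−8, at most 1000 iterations. Off-support parameter
values (non-positive interval masses) return a large finite penalty so line
searches back off. Standard errors invert the observed information (numeric
Hessian of the negative log-likelihood via central differences of the
gradient); a singular information matrix falls back to a pseudo-inverse with
`se_available = False`. AIC = 2k − 2ℓ with k the total coefficient count.

## Prediction

Cause-specific cumulative incidence follows directly from the mixture:
CIF_cancer(t) = [1 − S4(t | 1)]·f2, CIF_other(t) = [1 − S4(t | 2)]·(1 − f2),
CIF = CIF_cancer + CIF_other = 1 − f5. Conditional risks for a patient who
has survived t0 landmark-years use

    CIF_cancer(t | t>t0) = [CIF_cancer(t+t0) − CIF_cancer(t0)] / [1 − CIF(t0)]
    CIF(t | t>t0)        = 1 − [1 − CIF(t+t0)] / [1 − CIF(t0)]

with CIF(0) ≡ 0, so t0 = 0 (exactly one post-surgery year) reduces to the
unconditional CIF. The public calculator accepts t0 in post-surgery years
(≥ 1) and shifts internally; requests beyond the 5-year post-surgery support
are refused unless explicitly overridden, because the model was fitted on
capped follow-up. Predicted risks are point estimates; no interval is
attached.

The shipped coefficients are printed to two decimals; forward error analysis
puts the induced uncertainty in the worked-example risks at up to ~0.4
percentage points, hence the 0.5 pp tolerance used when comparing to the
published calculator outputs (observed deviations: ≤ 0.08 pp for the 2-year
scenario, ~0.3 pp for the 6-month scenario).

## Variable selection

Candidates are tested one at a time against the accumulating model,
parameter by parameter in the order η, α, φ, γ, ρ, and retained when the
two-sided Wald p-value (observed-information covariance) is below 0.05; a
likelihood-ratio variant is available behind `statistic="lr"`. Stage enters
as a multi-df group (with the stage-II merge applied in η); after each
parameter's main effects, pairwise interactions of the retained terms are
tested within that parameter, except in ρ, which already represents a
three-way interaction. Age and sex are forced into η and age into α a
priori; sex in α is left to testing (the published final model carries no
sex term in α). The wording "tested separately in each parameter" admits
variants; the add-one-term-at-a-time scheme with retained terms carried
forward is the one implemented, and it is deterministic given the seed.

`stability_selection` repeats the pass on B bootstrap resamples (with
replacement, at the cohort size; default B = 100) and keeps a term when its
inclusion count exceeds B/2. **Caveat:** inclusion counts are *not*
Binomial(B, 0.05) for a null term. Bootstrap replicates resample one cohort;
conditional on that cohort's chance association z₀, the per-replicate
selection probability is approximately P(|N(z₀, 1)| > z_{0.975}), so counts
concentrate near B·q(z₀) and a cohort in the outer ~5% tail yields counts
above B/2 for a pure-noise term. The per-test type-I rate across *fresh*
cohorts is at the nominal level (verified by simulation in the test suite);
the bootstrap count on a single cohort measures the stability of that
cohort's evidence, not the sampling-theory level.

## Validation

* **Time-dependent AUC.** Marker = predicted CIF at the horizon (total for
  all-cause, cancer-specific otherwise); cases = outcome events by the
  horizon; controls = patients event-free and under observation at the
  horizon, including records administratively censored exactly at it;
  records censored strictly before the horizon are excluded. No IPCW
  correction is applied because the emulated cohorts have complete potential
  follow-up to the cap, so pre-horizon censoring is absent by design. AUC is
  pairwise concordance with half-credit for ties, computed from mid-ranks.
  Horizons 2 and 4 landmark-years correspond to 3 and 5 post-surgery years.
* **Bootstrap cross-validation.** Per replicate: resample with replacement,
  refit, and score either on the resample (`apparent`, the literal reading)
  or on the out-of-bag records (`out_of_bag`, the default, which guards
  against optimism); report the median and the 2.5–97.5% quantile interval.
  The internal-vs-external AUC difference resamples both cohorts (default
  200 replicates) with the fitted model held fixed.
* **Calibration.** Hosmer–Lemeshow over deciles of predicted risk:
  statistic Σ (O_g − E_g)² / [E_g(1 − p̄_g)], df = groups − 2, upper-tail
  chi-square p (df floored at 1 so degenerate groupings stay defined;
  zero-variance groups merge into a neighbor). The df convention presumes
  the model was refit on the evaluated data, so the type-I simulation in
  the acceptance suite refits each replicate cohort before testing.
* **Goodness of fit.** The intercept-only model's f5 is overlaid on the
  Kaplan–Meier all-cause survival curve (lifelines), and the sup-norm
  discrepancy over observed times is reported.

## Synthetic cohorts

The generator draws covariates independently from configurable marginals
whose defaults match the derivation cohort of 1-year survivors (73.8% men,
51.9% squamous cell carcinoma, 33.2% neoadjuvant therapy, stage distribution
32.2/38.9/24.7/4.2%, 9.2% R1/R2, 8.4% reoperation, 14.9% >12 years
education, Charlson 0/1/≥2 at 56.0/29.3/14.7%, age ~ Normal(65.1, 9.5)
truncated to [30, 95]); a `validation_like` preset mirrors the external
cohort (81% adenocarcinoma, 69.4% neoadjuvant therapy, older and more
male). Event causes are Bernoulli(f2); event times invert the log-logistic
survival in closed form, t = exp((logit(u) − a)/b) with u ~ U(0,1); times
beyond the cap are censored there. An optional surgery-origin mode draws
latent post-surgery times and rejects first-year deaths, for sensitivity
analyses of the landmark convention.

What the generator does *not* emulate: the real cohorts' joint covariate
dependence (marginals only, though a pairwise overlay can be configured via
extra covariates), calendar-period effects, or cause-of-death
misclassification. Consequently, passing tests demonstrate internal
consistency of the method — the estimator recovers the generating process it
assumes — not transportability to registry data.

## Problem sizes and numerical choices

The test suite's simulation studies use the sizes the method's properties
are stated at: n = 5000 with 20 replicates for parameter recovery (every
coefficient within 3 estimated SEs; mean absolute bias < 0.05), 200
refitted replicates of n = 5000 for the Hosmer–Lemeshow type-I rate,
n = 2000 with B = 100 (noise) and B = 20 (strong effect) for selection
counts, and 200 000 forward draws for Monte-Carlo agreement of the
conditional-risk formulas. Bootstrap AUC defaults are 1000 replicates
(cross-validation) and 200 (difference CIs); tests exercise scaled-down
replicate counts with fixed seeds. All randomness flows through
`numpy.random.Generator` objects seeded explicitly; pipeline stages split
one root seed via `SeedSequence`, so stage outputs are bit-reproducible.

## Known limitations

* The real Swedish registry cohorts are not public; all empirical claims
  here are about synthetic data generated from the published coefficients.
  Cohort-specific AUC levels (≈0.71–0.76 in the source cohorts) are not
  reproduction targets.
* The Weibull/Gompertz alternatives are parametrized for AIC comparison
  only; the Gompertz form is defective at the time origin (S4(0⁺) < 1).
* Interactions are tested within a parameter only; cross-parameter
  interactions are out of scope.
* With very few deaths of one cause the cause-assignment block is weakly
  identified; `fit_mle` warns on cohorts lacking either cause and flags
  non-invertible information matrices rather than failing.
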