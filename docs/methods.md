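# Methods

This note documents the statistical model, the synthetic data-generating
process, the decision rules, and the numerical and design choices behind
`adaptrial`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survival model and conjugate inference

Time to event is exponential with constant hazard λ (units: per year).
Censoring is represented implicitly: a record stores only the observed
follow-up time and an event flag, which is exactly the information the
censored-exponential likelihood uses. Calendar quantities (enrollment,
follow-up, analysis schedule, horizon) are stored in months and converted
to years in a single place, the sufficient-statistic reduction
(`sufficient_stats`, division by 12). This asymmetry is deliberate: trial
calendars are naturally monthly, while hazards of 0.02–0.07 per year are
the scale on which 2-year EFS of 88–95% lives.

With a Gamma(α, β) prior (rate parameterization; the standard normalizer
β^α/Γ(α)), the posterior after d events and t person-years is
Gamma(α + d, β + t). The posterior-predictive survival at horizon τ and its
SD come from the Laplace transform of the Gamma law,

    E[e^{−τλ}] = (β̃/(β̃+τ))^α̃,
    Var[e^{−τλ}] = (β̃/(β̃+2τ))^α̃ − (β̃/(β̃+τ))^{2α̃},

used exactly rather than by a delta-method approximation. The posterior SD
of EFS is the denominator of the interim z statistic, so using the exact
form avoids a small-shape bias that the normal approximation would add.

Priors are specified by a hazard mean m and SD s and moment-matched:
α = m²/s², β = m/s². The graded strengths used throughout the simulation
studies are SD = 0.01 (strong), 0.02 (moderate), 0.05 (weak), plus the
Jeffreys prior π(λ) ∝ 1/λ, implemented as the improper Gamma(0, 0) limit.
An improper posterior (Jeffreys with zero events) refuses to produce
predictive quantities; the interim engine records such stages as
"insufficient data" and continues, and the single-look test counts them as
non-rejections.

## Synthetic trial generator

The generator emulates a 6-year single-arm de-intensification trial:

* nine enrollment cohorts, one every 4 months for 3 years; cohort size
  max(Poisson(10), 6), or a fixed size for the sample-size sweeps;
* per cohort, a hazard λ_j ~ Uniform(hazard range) and an event rate
  p_j ~ Uniform(event-rate range), shared by the cohort's members;
* each patient is an event case with probability p_j (the cohort event
  count is Binomial(n_j, p_j)); an event case's failure time is drawn from
  Exp(λ_j) conditioned to fall inside the patient's observation window
  (horizon − enrollment), so realized events are observable;
* non-event patients are administratively censored at the horizon;
* 10% of event-free patients (rounded) are then lost to follow-up at a
  Uniform(0, follow-up) time.

The low event rate models a mostly-cured population: only a small fraction
of patients can fail at all, and the hazard controls when those failures
occur. Two consequences of the window-conditioning deserve note. First,
the fitted exponential model is (mildly) misspecified with respect to the
generator — the model's effective hazard reflects both λ_j and p_j. The
generating (λ, p) pairs of the null scenarios put that effective hazard at
or above the historical-control hazard −ln(EFS₀)/τ, and the alternative
scenarios put it well below, which is what the type-I and power studies
require. Second, a calibration identity (Jeffreys posterior mean → true λ)
holds only when λ·window is large enough that the conditioning bias
e^{−λw} is negligible; the test suite checks it at λ = 1.5/yr.

Reproducibility: one seeded `numpy` Generator per trial, with a fixed
stream order (cohort sizes, hazards, event rates, per-cohort event flags
and times, censoring lottery). Identical (config, seed) gives identical
datasets.

Interim snapshots administratively censor the full dataset at the analysis
calendar time: patients enrolled later are absent, ongoing follow-up is cut
at (analysis − enrollment) with the event flag cleared. Sufficient
statistics are therefore monotone in the snapshot time, and the snapshot at
the horizon is the dataset itself.

## Interim analysis and stopping rules

Analyses run at fixed calendar months (default 18, 24, 30, 36, 42, 48).
The stage-k posterior can be computed by chaining the previous stage's
posterior with the increment in sufficient statistics or by a one-shot
update of the design prior with the cumulative snapshot; conjugacy makes
the two identical, and `run_trial` computes both and raises if they ever
disagree (an exact, always-on cross-check).

Two efficacy-decision families are implemented behind one switch:

* `linear-posterior-threshold` (default): stop when
  P(EFS ≥ EFS₀ | data) ≥ β_k with β_k = 1 − α·k/K. This linearly relaxing
  rule is the design's native criterion and is the default because it
  reproduces the reported stopping behavior of the simulation studies
  (strongly informative prior: median stop at month 30).
* `obrien-fleming-spending` / `pocock-spending`: one-sided z-boundaries for
  ẑ_k = (ÊFS_k − EFS₀)/σ̂(EFS_k) from an error-spending construction at
  information fractions k/K (analysis count, not event count — the design
  fixes calendar-time looks). Boundaries are found by the standard
  recursive-integration scheme for Gaussian group-sequential tests: the
  partial-sum process is Brownian at the information times; the sub-density
  of the non-stopped process is propagated on a 1601-point grid (trapezoid
  rule, lower cut at −9 on the partial-sum scale) and each critical value
  is solved by Brent's method so the incremental crossing probability
  equals the spent error. Accuracy is ~1e−4 on crossing probabilities,
  verified against direct multivariate-normal computations in the tests.

Futility monitoring is an optional extension (off by default): stop when
the posterior probability of meeting the target falls below a floor γ_f.
The design literature the package follows names futility monitoring but
prescribes no rule, so none is imposed.

`adaptive_sample_size` summarizes the design's realized sample size: it
simulates trials, runs the schedule, and reports the distribution of
enrollment at stopping and of the stopping month — the Bayesian analogue of
a fixed-design sample-size calculation.

## Operating characteristics

The single-look test rejects when P(EFS ≥ EFS₀ | data) ≥ 0.95. Type-I
error and power sweeps run M replicates at each nominal n on a grid
(default 80–225 by 5), with equal cohorts of round(n/9) patients (the
realized total, 9·round(n/9), is reported alongside). The minimal sample
size is the smallest grid n whose empirical rate reaches the target (0.80).

Common random numbers: each replicate owns a seed spawned from the master
seed, reused across all sample sizes and shared by all priors (every prior
is evaluated on the same dataset's sufficient statistics). Prior and
sample-size comparisons are therefore paired, which is what makes a
10-patient difference in minimal n detectable at M = 1000.

The interim study records, per prior, the calendar month of the first
efficacy stop (+∞ when no boundary is crossed; medians are taken over the
full distribution including non-stops) and per-stage median z among
evaluable stages.

Problem sizes: the shipped studies use M = 1000 replicates (sweeps over 30
grid points), which puts Monte-Carlo SEs on rates at ≤ 1.6 points and runs
the full battery in well under a minute; the reduced-scale example uses
M = 200 for interactive use.

## Numerical and design choices

* Gamma tails use `scipy.stats.gamma` / `scipy.special.gammainc`; no
  hand-rolled special functions.
* The moment-matching map is exact, so `posterior_mean_var ∘
  prior_from_mean_sd` round-trips (m, s²) to machine precision.
* Sufficient-statistic subtraction clamps exposure at 0 to absorb rounding
  in snapshot increments; chaining equality is still checked to 1e−9.
* Event times are clamped to [1e−6, window] months to keep records valid
  under floating-point edge draws.
* The survival-table CSV writes floats with `%.17g` and reads with
  pandas' round-trip parser, so file round-trips are exact.
* Analysis times before first enrollment yield empty snapshots; with a
  proper prior the stage is evaluated on the prior alone (zero increment),
  which is the correct Bayesian statement, and with an improper prior it is
  recorded as insufficient.

## Known limitations

* The exponential (constant-hazard) likelihood cannot represent delayed
  relapse waves or cure fractions; the historical-control comparison
  inherits whatever biases the benchmark carries.
* The generator draws cohort-level hazards and event rates independently
  and uniformly; real accrual has within-cohort heterogeneity, dropout
  dynamics, and non-administrative censoring patterns it does not model.
  Passing operating-characteristic tests therefore demonstrates internal
  consistency of the design under its stated generating mechanism, not
  performance on any particular real trial.
* With very weak proper priors (shape ≪ 1) and no observed events, the
  posterior predictive EFS is close to 1 and early looks can cross the
  efficacy criterion on sparse data. Under favorable (H₁) scenarios these
  are correct early stops, but designs intending conservative early
  behavior should prefer O'Brien–Fleming spending boundaries, which spend
  almost no error at the first looks.
* The z statistic is treated as standard normal by the spending
  construction; its exact finite-sample law under the conjugate posterior
  is skewed, making the sequential procedure conservative at the null
  boundary (verified empirically in the tests) rather than exactly
  α-spending.
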