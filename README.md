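# adaptrial

Single-arm Bayesian adaptive trial design for de-intensified oncologic
treatment: conjugate exponential–Gamma survival inference, multi-stage
interim analysis with sequential stopping criteria, Bayesian sample-size
determination, and a trial simulator for Monte-Carlo operating
characteristics.

## The problem

De-escalation of cancer therapy (for example, omitting radiation after a
complete response to chemotherapy in pediatric Hodgkin lymphoma) is studied
in populations with high cure rates and low event rates. A randomized
comparison would need impractically many patients and years to accumulate
events, so a **single-arm trial against a historical control** is often the
only feasible design: the new, less intensive regimen must demonstrate that
its event-free survival (EFS) at a horizon τ (typically 2 years) meets a
benchmark EFS₀ established from prior studies.

## The model

Each patient's time to event is exponential with constant hazard λ (per
year). With follow-up times *tᵢ* (exposure) and event indicators *δᵢ*, the
likelihood is L(λ) = ∏ᵢ (λe^{−λtᵢ})^{δᵢ} (e^{−λtᵢ})^{1−δᵢ}, and a Gamma
prior G(α, β) on λ is conjugate:

    λ | data  ~  Gamma(α + Σδᵢ, β + Σtᵢ)

Everything downstream is closed form:

* posterior mean (α+Σδ)/(β+Σt), variance (α+Σδ)/(β+Σt)²;
* posterior-predictive EFS at τ years:  Ŝ(τ) = (β̃/(β̃+τ))^{α̃}  with
  posterior parameters (α̃, β̃), and its exact posterior SD via the Gamma
  Laplace transform;
* tail probabilities P(λ ≥ r | data), hence
  P(EFS ≥ EFS₀ | data) = P(λ ≤ −ln(EFS₀)/τ | data).

Priors are elicited by moment matching a stated hazard mean and SD
(`prior_from_mean_sd`: α = m²/s², β = m/s²); the non-informative Jeffreys
prior π(λ) ∝ 1/λ is the improper Gamma(0, 0) limit and becomes proper after
the first observed event.

At each of K scheduled interim looks the trial tests H₀: EFS ≤ EFS₀ against
H₁: EFS > EFS₀ using either

* the stage-wise posterior-probability rule β_k = 1 − α·k/K (stop for
  efficacy when P(EFS ≥ EFS₀ | data) ≥ β_k; the package default), or
* one-sided z-boundaries ẑ_k = (ÊFS_k − EFS₀)/σ̂(EFS_k) from an
  error-spending construction (O'Brien–Fleming- or Pocock-type) at
  information fractions k/K.

## Worked example

Run a six-stage interim analysis (months 18–48) on a simulated trial — nine
4-month cohorts, yearly hazards in (0.02, 0.03), cohort event rates in
(0.05, 0.10) — testing 2-year EFS against a 92% historical control with a
strongly informative prior (hazard mean 0.025/yr, SD 0.01):

```sh
python examples/03_interim_analysis.py
```

```
 stage  analysis_month  n_enrolled  n_events  efs_hat  z_score  posterior_prob_meets_target  efficacy_criterion      decision
     1            18.0          56         1   0.9517   1.8203                       0.9502              0.9917      continue
     2            24.0          62         1   0.9559   2.2539                       0.9746              0.9833      continue
     3            30.0          87         1   0.9605   2.8204                       0.9901              0.9750 stop-efficacy

efficacy criterion met at month 30: P(EFS >= 92%) = 0.9901 >= 0.9750
```

At month 30 the posterior probability that the de-intensified regimen's
2-year EFS meets the 92% benchmark (0.9901) exceeds the stage-3 threshold
β₃ = 1 − 0.05·3/6 = 0.975, so the trial stops early for efficacy after
enrolling 87 of the planned ~91 patients — 18 months before the final look.

The other example scripts each exercise one capability: `01` the conjugate
update and predictive EFS, `02` the trial simulator and the CSV survival
table, `04` reduced-scale operating characteristics (minimal sample size
for 80% power per prior strength; stopping-month distributions). The same
functionality is exposed as a CLI (`adaptrial simulate | analyze | interim |
oc | boundaries`).

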