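"""Six-stage interim analysis of a simulated trial.

Analyses run at months 18, 24, ..., 48.  At each look the posterior is
refreshed from the calendar snapshot, the 2-year EFS estimate is compared
with the 92% historical control, and the stage's posterior-probability
threshold beta_k = 1 - alpha*k/K decides continue / stop-efficacy.
"""

from adaptrial import InterimPlan, SimConfig, prior_from_mean_sd, run_trial, simulate_trial
from adaptrial.io import stage_report_frame

dataset = simulate_trial(
    SimConfig(hazard_range=(0.02, 0.03), event_rate_range=(0.05, 0.10), seed=6)
)
plan = InterimPlan(
    prior=prior_from_mean_sd(0.025, 0.01),   # strongly informative
    efs0=0.92,
    alpha=0.05,
)
stages = run_trial(dataset, plan)

cols = ["stage", "analysis_month", "n_enrolled", "n_events", "efs_hat",
        "z_score", "posterior_prob_meets_target", "efficacy_criterion", "decision"]
print(stage_report_frame(stages)[cols].round(4).to_string(index=False))
last = stages[-1]
if last.decision == "stop-efficacy":
    print(f"\nefficacy criterion met at month {last.analysis_time:.0f}: "
          f"P(EFS >= 92%) = {last.posterior_prob_meets_target:.4f} >= "
          f"{last.efficacy_criterion:.4f}")
else:
    print("\nno stopping boundary crossed; trial runs to completion")
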