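"""Operating characteristics at reduced scale (200 replicates, ~10 s).

Sweeps the single-look posterior-probability test over sample sizes to find
the minimal n reaching 80% power per prior strength, then estimates the
stopping-month distribution of the six-stage interim design.  The full-size
(M = 1000) studies live in scripts/acceptance.py.
"""

from adaptrial import GammaParams, InterimPlan, OCConfig, empirical_power, interim_oc
from adaptrial.scenarios import INTERIM_CASE1, POWER_CASE1, prior_grid

reps = 200

oc = OCConfig(
    scenario=POWER_CASE1["scenario"],
    prior_grid=prior_grid(POWER_CASE1["prior_mean"]),
    efs0=POWER_CASE1["efs0"],
    reps=reps,
    sample_sizes=tuple(range(80, 226, 15)),
    seed=5,
)
res = empirical_power(oc, target=0.80)
print("minimal sample size reaching 80% power (common replicate seeds):")
for prior, n in res.minimal_n.items():
    print(f"  {prior:9s} -> {n}")

oc = OCConfig(
    scenario=INTERIM_CASE1["scenario"],
    prior_grid=prior_grid(INTERIM_CASE1["prior_mean"], ("strong", "jeffreys")),
    efs0=INTERIM_CASE1["efs0"],
    reps=reps,
    seed=5,
)
ioc = interim_oc(oc, InterimPlan(prior=GammaParams.jeffreys()))
print("\nmedian first efficacy-stop month, six-stage design:")
for prior, m in ioc.median_stop_month.items():
    frac = float((ioc.stopping_months[prior] < float("inf")).mean())
    print(f"  {prior:9s} -> month {m:.0f} (stopped in {100 * frac:.0f}% of trials)")
# A stronger favorable prior reaches the efficacy boundary sooner, shortening
# the trial; the non-informative prior needs observed events to catch up.
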