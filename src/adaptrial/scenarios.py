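"""Canonical simulation-study scenarios and prior grids.

Data-generating parameterizations for the package's standard simulation
studies: single-look type-I-error and power sweeps (equal cohort sizes,
sample size swept), and the six-stage interim designs (Poisson accrual).
Hazards are per year; the prior for each scenario is centered near the
scenario's hazard range and graded by SD: strongly informative (0.01),
moderately informative (0.02), weakly informative (0.05), plus the
non-informative Jeffreys prior.
"""

from __future__ import annotations

from .conjugate import GammaParams, prior_from_mean_sd
from .simulate import SimConfig

__all__ = [
    "TYPE1_CASE1", "TYPE1_CASE2", "POWER_CASE1", "POWER_CASE2",
    "INTERIM_CASE1", "INTERIM_CASE2", "INTERIM_CASE3", "INTERIM_CASE4",
    "prior_grid", "SWEEP_SAMPLE_SIZES",
]

# Single-look studies: type-I error under the null (hazard at the historical
# control), power under the alternative (hazard well below it).
TYPE1_CASE1 = dict(
    scenario=SimConfig(hazard_range=(0.041, 0.042), event_rate_range=(0.22, 0.23)),
    prior_mean=0.038, efs0=0.92,
)
TYPE1_CASE2 = dict(
    scenario=SimConfig(hazard_range=(0.053, 0.054), event_rate_range=(0.27, 0.28)),
    prior_mean=0.048, efs0=0.90,
)
POWER_CASE1 = dict(
    scenario=SimConfig(hazard_range=(0.02, 0.03), event_rate_range=(0.07, 0.12)),
    prior_mean=0.025, efs0=0.92,
)
POWER_CASE2 = dict(
    scenario=SimConfig(hazard_range=(0.03, 0.04), event_rate_range=(0.10, 0.15)),
    prior_mean=0.033, efs0=0.90,
)

# Six-stage interim designs (analyses at months 18, 24, ..., 48).
INTERIM_CASE1 = dict(
    scenario=SimConfig(hazard_range=(0.02, 0.03), event_rate_range=(0.05, 0.10)),
    prior_mean=0.025, efs0=0.92,
)
INTERIM_CASE2 = dict(
    scenario=SimConfig(hazard_range=(0.03, 0.04), event_rate_range=(0.10, 0.15)),
    prior_mean=0.035, efs0=0.90,
)
INTERIM_CASE3 = dict(
    scenario=SimConfig(hazard_range=(0.04, 0.05), event_rate_range=(0.05, 0.10)),
    prior_mean=0.045, efs0=0.94,
)
INTERIM_CASE4 = dict(
    scenario=SimConfig(hazard_range=(0.06, 0.07), event_rate_range=(0.10, 0.15)),
    prior_mean=0.065, efs0=0.92,
)

SWEEP_SAMPLE_SIZES = tuple(range(80, 226, 5))

PRIOR_SDS = {"strong": 0.01, "moderate": 0.02, "weak": 0.05}


def prior_grid(mean: float, which: tuple[str, ...] = ("strong", "moderate", "weak", "jeffreys")):
    """(label, GammaParams) pairs for the graded prior strengths."""
    out = []
    for label in which:
        if label == "jeffreys":
            out.append(("jeffreys", GammaParams.jeffreys()))
        else:
            out.append((label, prior_from_mean_sd(mean, PRIOR_SDS[label])))
    return tuple(out)
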