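"""Monte-Carlo operating characteristics of the single-arm Bayesian design.

Reproduces the simulation studies at desk scale: empirical type-I error and
power of the single-look posterior-probability test across a sample-size
sweep, minimal sample size for a target power, and stopping-time
distributions of the multi-stage interim design across prior strengths.

Common random numbers: every replicate owns one seed (spawned from the
master seed), and that seed is re-used for every sample size and evaluated
against every prior on the same dataset, so comparisons across priors and
across n are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammainc

from .conjugate import (
    GammaParams,
    efs_hazard_threshold,
    sufficient_stats,
    update_posterior,
    prob_efs_meets_target,
    ImproperPosteriorError,
)
from .interim import InterimPlan, run_trial
from .simulate import SimConfig, TrialDataset, simulate_trial

__all__ = [
    "OCConfig",
    "OCResult",
    "single_look_test",
    "empirical_type1",
    "empirical_power",
    "interim_oc",
    "minimal_sample_size",
]


@dataclass(frozen=True)
class OCConfig:
    """Scenario, prior grid and sweep settings for an operating-characteristics study."""

    scenario: SimConfig
    prior_grid: tuple[tuple[str, GammaParams], ...]
    efs0: float = 0.92
    tau: float = 2.0
    decision_prob: float = 0.95
    reps: int = 1000
    sample_sizes: tuple[int, ...] = tuple(range(80, 226, 5))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.prior_grid:
            raise ValueError("prior_grid must not be empty")
        if not 0.0 < self.efs0 < 1.0:
            raise ValueError("efs0 must lie in (0, 1)")


@dataclass
class OCResult:
    """Tidy rejection-rate table plus per-prior summaries."""

    rates: pd.DataFrame                       # prior, n_nominal, n_realized, rate, se
    minimal_n: dict[str, int | None] = field(default_factory=dict)
    stage_median_z: pd.DataFrame | None = None
    stopping_months: dict[str, np.ndarray] = field(default_factory=dict)
    median_stop_month: dict[str, float] = field(default_factory=dict)


def single_look_test(
    dataset: TrialDataset,
    prior: GammaParams,
    efs0: float,
    tau: float = 2.0,
    decision_prob: float = 0.95,
) -> int:
    """One-shot test: 1 iff P(EFS_hat >= EFS0 | data) >= decision_prob.

    An improper posterior (Jeffreys prior, zero events) counts as no
    rejection.
    """
    stats = sufficient_stats(dataset.records)
    try:
        post = update_posterior(prior, stats)
    except ImproperPosteriorError:
        return 0
    return int(prob_efs_meets_target(post, efs0, tau) >= decision_prob)


def _rejection_sweep(oc: OCConfig) -> OCResult:
    """Shared engine for the type-I and power sweeps.

    For each nominal n the scenario runs with equal cohorts of round(n/9)
    patients; rejection uses the regularized lower Gamma tail directly,
    which equals ``single_look_test`` (cross-checked in the test suite).
    """
    r = efs_hazard_threshold(oc.efs0, oc.tau)
    labels = [lab for lab, _ in oc.prior_grid]
    shapes = np.array([p.shape for _, p in oc.prior_grid])
    rates_prior = np.array([p.rate for _, p in oc.prior_grid])
    improper = np.array([p.improper for _, p in oc.prior_grid])

    rep_seeds = np.random.SeedSequence(oc.seed).spawn(oc.reps)
    rows = []
    for n in oc.sample_sizes:
        g = max(1, round(n / oc.scenario.n_groups))
        cfg = replace(oc.scenario, fixed_group_size=g, seed=None)
        hits = np.zeros(len(labels))
        n_realized = g * oc.scenario.n_groups
        for child in rep_seeds:
            rng = np.random.default_rng(child)
            ds = simulate_trial(cfg, rng)
            st = sufficient_stats(ds.records)
            post_shape = shapes + st.n_events
            post_rate = rates_prior + st.total_exposure
            prob = np.where(
                improper & (st.n_events == 0),
                0.0,
                gammainc(np.maximum(post_shape, 1e-300), post_rate * r),
            )
            hits += prob >= oc.decision_prob
        rate = hits / oc.reps
        se = np.sqrt(rate * (1.0 - rate) / oc.reps)
        for lab, rt, s in zip(labels, rate, se):
            rows.append(
                {"prior": lab, "n_nominal": n, "n_realized": n_realized,
                 "rate": float(rt), "se": float(s)}
            )
    return OCResult(rates=pd.DataFrame(rows))


def minimal_sample_size(result: OCResult, target: float = 0.80) -> dict[str, int | None]:
    """Smallest nominal n on the sweep grid whose empirical rate >= target."""
    out: dict[str, int | None] = {}
    for lab, grp in result.rates.groupby("prior", sort=False):
        ok = grp.loc[grp["rate"] >= target, "n_nominal"]
        out[lab] = int(ok.min()) if len(ok) else None
    return out


def empirical_type1(oc: OCConfig) -> OCResult:
    """Empirical type-I error sweep: scenario generated under the null."""
    return _rejection_sweep(oc)


def empirical_power(oc: OCConfig, target: float = 0.80) -> OCResult:
    """Empirical power sweep plus minimal n reaching ``target`` per prior."""
    res = _rejection_sweep(oc)
    res.minimal_n = minimal_sample_size(res, target)
    return res


def interim_oc(oc: OCConfig, plan: InterimPlan) -> OCResult:
    """Stopping-time distribution of the K-stage design across priors.

    Each replicate's dataset is shared by every prior on the grid (paired
    comparisons).  Per prior, records the calendar month of the first
    efficacy stop (+inf when no boundary is crossed) and the per-stage
    median z among evaluable, still-running stages.
    """
    rep_seeds = np.random.SeedSequence(oc.seed).spawn(oc.reps)
    K = plan.n_stages
    months = {lab: np.full(oc.reps, np.inf) for lab, _ in oc.prior_grid}
    zs: dict[str, list[list[float]]] = {lab: [[] for _ in range(K)] for lab, _ in oc.prior_grid}

    plans = {lab: replace(plan, prior=p) for lab, p in oc.prior_grid}
    for i, child in enumerate(rep_seeds):
        rng = np.random.default_rng(child)
        ds = simulate_trial(replace(oc.scenario, seed=None), rng)
        for lab, _ in oc.prior_grid:
            for stage in run_trial(ds, plans[lab]):
                if stage.posterior is not None:
                    zs[lab][stage.stage - 1].append(stage.z_score)
                if stage.decision == "stop-efficacy":
                    months[lab][i] = stage.analysis_time

    z_rows = []
    for lab, _ in oc.prior_grid:
        for k in range(K):
            vals = zs[lab][k]
            z_rows.append(
                {"prior": lab, "stage": k + 1,
                 "analysis_time": plan.analysis_times[k],
                 "median_z": float(np.median(vals)) if vals else float("nan"),
                 "n_evaluable": len(vals)}
            )

    rows = []
    median_stop = {}
    for lab, _ in oc.prior_grid:
        m = months[lab]
        stopped = np.isfinite(m)
        rate = float(stopped.mean())
        rows.append(
            {"prior": lab, "n_nominal": -1, "n_realized": -1,
             "rate": rate, "se": float(np.sqrt(rate * (1 - rate) / oc.reps))}
        )
        median_stop[lab] = float(np.median(m))

    return OCResult(
        rates=pd.DataFrame(rows),
        stage_median_z=pd.DataFrame(z_rows),
        stopping_months={lab: months[lab] for lab, _ in oc.prior_grid},
        median_stop_month=median_stop,
    )
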