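"""K-stage adaptive analysis: snapshots, posterior chaining, stopping rules.

At each scheduled calendar time the accumulated data are administratively
censored, the conjugate posterior is refreshed, and the standardized score

    z_k = (EFS_hat_k - EFS0) / sd(EFS_k)

is compared against the stage's efficacy criterion.  By conjugacy the
stage-k posterior can equivalently be computed by chaining the previous
stage's posterior with the increment of the sufficient statistics or by a
one-shot update of the design prior with the cumulative snapshot; both
paths are computed and cross-checked on every stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .boundaries import DECISION_RULES, linear_posterior_thresholds, z_boundaries
from .conjugate import (
    GammaParams,
    SufficientStats,
    predictive_survival,
    predictive_survival_sd,
    prob_efs_meets_target,
    sufficient_stats,
    update_posterior,
)
from .simulate import SimConfig, TrialDataset, simulate_trial, snapshot

__all__ = ["InterimPlan", "StageResult", "z_statistic", "run_trial", "adaptive_sample_size"]

DEFAULT_ANALYSIS_TIMES = (18.0, 24.0, 30.0, 36.0, 42.0, 48.0)


@dataclass(frozen=True)
class InterimPlan:
    """Schedule, historical control, significance level and decision family."""

    prior: GammaParams
    efs0: float = 0.92
    horizon_tau: float = 2.0                     # EFS horizon, years
    alpha: float = 0.05
    analysis_times: tuple[float, ...] = DEFAULT_ANALYSIS_TIMES  # calendar months
    spending: str = "linear-posterior-threshold"
    futility_threshold: float | None = None      # posterior-probability floor

    def __post_init__(self) -> None:
        if not 0.0 < self.efs0 < 1.0:
            raise ValueError("efs0 must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.horizon_tau <= 0:
            raise ValueError("horizon_tau must be positive")
        if len(self.analysis_times) < 1:
            raise ValueError("at least one analysis time is required")
        if any(b <= a for a, b in zip(self.analysis_times, self.analysis_times[1:])):
            raise ValueError("analysis_times must be strictly increasing")
        if self.spending not in DECISION_RULES:
            raise ValueError(
                f"unknown decision rule {self.spending!r}; supported: "
                + ", ".join(DECISION_RULES)
            )
        if self.futility_threshold is not None and not 0.0 <= self.futility_threshold < 1.0:
            raise ValueError("futility_threshold must lie in [0, 1)")

    @property
    def n_stages(self) -> int:
        return len(self.analysis_times)

    def efficacy_criteria(self) -> list[float]:
        """Per-stage efficacy criterion: z-boundary or posterior threshold."""
        if self.spending == "linear-posterior-threshold":
            return linear_posterior_thresholds(self.n_stages, self.alpha)
        return z_boundaries(self.n_stages, self.alpha, self.spending)


@dataclass(frozen=True)
class StageResult:
    stage: int                      # 1-based
    analysis_time: float            # months
    n_enrolled: int
    n_events: int
    exposure_years: float
    posterior: GammaParams | None
    efs_hat: float = float("nan")
    efs_sd: float = float("nan")
    z_score: float = float("nan")
    efficacy_criterion: float = float("nan")
    posterior_prob_meets_target: float = float("nan")
    decision: str = "continue"      # continue | stop-efficacy | stop-futility
    note: str = ""


def z_statistic(efs_hat: float, efs0: float, efs_sd: float) -> float:
    """Standardized distance of the model EFS from the historical control."""
    if not efs_sd > 0:
        raise ValueError("efs_sd must be positive (degenerate posterior)")
    return (efs_hat - efs0) / efs_sd


def run_trial(dataset: TrialDataset, plan: InterimPlan) -> list[StageResult]:
    """Execute the scheduled interim analyses until a stop or the last stage.

    A stage whose snapshot carries zero events under an improper (Jeffreys)
    prior is recorded as "insufficient data" and the trial continues.  The
    posterior at every evaluable stage is verified to be identical whether
    obtained by one-shot cumulative update or by chaining stage increments.
    """
    if len(dataset.records) == 0:
        raise ValueError("dataset is empty")
    criteria = plan.efficacy_criteria()
    posterior_rule = plan.spending == "linear-posterior-threshold"

    results: list[StageResult] = []
    prev_stats = SufficientStats(0, 0.0)
    chained: GammaParams = plan.prior

    for k, t_k in enumerate(plan.analysis_times, start=1):
        snap = snapshot(dataset, t_k)
        stats = sufficient_stats(snap.records)
        crit = criteria[k - 1]

        if plan.prior.improper and stats.n_events == 0:
            results.append(
                StageResult(
                    stage=k, analysis_time=t_k, n_enrolled=len(snap.records),
                    n_events=stats.n_events, exposure_years=stats.total_exposure,
                    posterior=None, efficacy_criterion=crit,
                    note="insufficient data (no events under improper prior)",
                )
            )
            # prev_stats is not advanced: the improper prior has absorbed no
            # data yet, so the next evaluable stage chains the full increment.
            continue

        pooled = update_posterior(plan.prior, stats)
        chained = update_posterior(chained, stats - prev_stats)
        if not (np.isclose(pooled.shape, chained.shape, rtol=0, atol=1e-9)
                and np.isclose(pooled.rate, chained.rate, rtol=0, atol=1e-9)):
            raise AssertionError(
                "chaining-pooling equivalence violated: "
                f"{chained} vs {pooled} at stage {k}"
            )
        prev_stats = stats
        posterior = pooled

        efs_hat = predictive_survival(posterior, plan.horizon_tau)
        efs_sd = predictive_survival_sd(posterior, plan.horizon_tau)
        pprob = prob_efs_meets_target(posterior, plan.efs0, plan.horizon_tau)
        z = z_statistic(efs_hat, plan.efs0, efs_sd) if efs_sd > 0 else float("nan")

        if posterior_rule:
            efficacious = pprob >= crit
        else:
            efficacious = z >= crit
        futile = (
            plan.futility_threshold is not None
            and pprob < plan.futility_threshold
        )

        if efficacious:
            decision = "stop-efficacy"
        elif futile:
            decision = "stop-futility"
        else:
            decision = "continue"

        results.append(
            StageResult(
                stage=k, analysis_time=t_k, n_enrolled=len(snap.records),
                n_events=stats.n_events, exposure_years=stats.total_exposure,
                posterior=posterior, efs_hat=efs_hat, efs_sd=efs_sd, z_score=z,
                efficacy_criterion=crit, posterior_prob_meets_target=pprob,
                decision=decision,
            )
        )
        if decision != "continue":
            break

    return results


def adaptive_sample_size(
    config: SimConfig,
    plan: InterimPlan,
    reps: int = 200,
    seed: int | None = None,
) -> dict:
    """Distribution of realized enrollment and stopping month under the design.

    Simulates ``reps`` trials, runs the interim schedule on each, and
    summarizes the enrollment at the stopping analysis (full accrual when no
    boundary is crossed) and the stopping month (the last analysis time when
    the trial runs to completion).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    n_stop = np.empty(reps)
    month_stop = np.empty(reps)
    stopped = np.zeros(reps, dtype=bool)
    for i, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        ds = simulate_trial(replace(config, seed=None), rng)
        stages = run_trial(ds, plan)
        last = stages[-1]
        if last.decision != "continue":
            stopped[i] = True
            n_stop[i] = last.n_enrolled
            month_stop[i] = last.analysis_time
        else:
            n_stop[i] = len(ds.records)
            month_stop[i] = plan.analysis_times[-1]

    qs = (0.1, 0.25, 0.5, 0.75, 0.9)
    return {
        "reps": reps,
        "stop_fraction": float(stopped.mean()),
        "enrollment_mean": float(n_stop.mean()),
        "enrollment_median": float(np.median(n_stop)),
        "enrollment_quantiles": {q: float(np.quantile(n_stop, q)) for q in qs},
        "stopping_month_mean": float(month_stop.mean()),
        "stopping_month_median": float(np.median(month_stop)),
        "stopping_month_quantiles": {q: float(np.quantile(month_stop, q)) for q in qs},
    }
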