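"""Conjugate Gamma-exponential inference for single-arm survival trials.

The time-to-event outcome of each patient is modelled as exponential with a
constant hazard ``lambda`` (per year).  With a Gamma(shape, rate) prior on the
hazard, the posterior after observing ``d`` events over a total exposure of
``t`` years is Gamma(shape + d, rate + t) -- the event count and total
exposure are the only data reductions the model ever needs.

All calendar quantities (enrollment, follow-up) are carried in *months*;
hazards and Gamma rate parameters are *per year*.  The conversion happens in
exactly one place, :func:`sufficient_stats`, to avoid silent unit bugs.

The posterior-predictive survival at a horizon ``tau`` (years) is available in
closed form through the Laplace transform of the Gamma distribution::

    S(tau) = E[exp(-tau * lam)] = (rate / (rate + tau)) ** shape

which is the model's estimate of event-free survival (EFS) at ``tau``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import gamma as _gamma_dist

__all__ = [
    "MONTHS_PER_YEAR",
    "SurvivalRecord",
    "GammaParams",
    "SufficientStats",
    "sufficient_stats",
    "update_posterior",
    "posterior_mean_var",
    "prior_from_mean_sd",
    "predictive_survival",
    "predictive_survival_sd",
    "posterior_tail_prob",
    "prob_efs_meets_target",
    "efs_hazard_threshold",
]

MONTHS_PER_YEAR = 12.0


class ImproperPosteriorError(ValueError):
    """Raised when a predictive quantity is requested from an improper law."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up.

    Parameters
    ----------
    patient_id
        Opaque identifier.
    enroll_time
        Calendar months from trial start to enrollment (>= 0).
    followup_time
        Months from enrollment to the event or to censoring (> 0).
    event
        1 if the event (death, progression, relapse) was observed at the end
        of follow-up, 0 if the patient was censored there.  Censoring times
        are not stored separately: the observed follow-up together with the
        indicator is all the exponential likelihood uses.
    """

    patient_id: str
    enroll_time: float
    followup_time: float
    event: int

    def __post_init__(self) -> None:
        if self.enroll_time < 0:
            raise ValueError(f"enroll_time must be >= 0, got {self.enroll_time}")
        if not self.followup_time > 0:
            raise ValueError(
                f"followup_time must be > 0, got {self.followup_time} "
                f"(patient {self.patient_id})"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class GammaParams:
    """Gamma(shape, rate) law for the hazard; doubles as prior and posterior.

    ``rate`` carries units of exposure time (years), so the Gamma mean
    ``shape / rate`` is a per-year hazard.  The Jeffreys prior
    ``pi(lam) ~ 1/lam`` is represented as the improper limit shape -> 0,
    rate -> 0 with ``improper=True``; it becomes proper as soon as the data
    contribute at least one event.
    """

    shape: float
    rate: float
    improper: bool = False

    def __post_init__(self) -> None:
        if self.improper:
            if self.shape != 0.0 or self.rate != 0.0:
                raise ValueError("improper (Jeffreys) params must be (0, 0)")
        else:
            if not (self.shape > 0 and self.rate > 0):
                raise ValueError(
                    f"proper GammaParams need shape > 0 and rate > 0, "
                    f"got ({self.shape}, {self.rate})"
                )

    @classmethod
    def jeffreys(cls) -> "GammaParams":
        """The non-informative Jeffreys prior, pi(lam) proportional to 1/lam."""
        return cls(0.0, 0.0, improper=True)

    @property
    def is_proper(self) -> bool:
        return not self.improper


@dataclass(frozen=True)
class SufficientStats:
    """Event count and total exposure (years) -- all the model needs."""

    n_events: int
    total_exposure: float

    def __post_init__(self) -> None:
        if self.n_events < 0 or self.total_exposure < 0:
            raise ValueError("sufficient statistics must be nonnegative")
        if self.total_exposure == 0 and self.n_events > 0:
            raise ValueError("events without exposure are impossible")

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(
            self.n_events + other.n_events,
            self.total_exposure + other.total_exposure,
        )

    def __sub__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(
            self.n_events - other.n_events,
            max(self.total_exposure - other.total_exposure, 0.0),
        )


def sufficient_stats(records, months_per_year: float = MONTHS_PER_YEAR) -> SufficientStats:
    """Reduce survival records to (event count, exposure in years).

    Follow-up is stored in months and converted here, the single
    months-to-years boundary of the package.
    """
    n_events = 0
    total_months = 0.0
    for rec in records:
        if rec.followup_time <= 0:
            raise ValueError(f"record {rec.patient_id} has nonpositive follow-up")
        n_events += rec.event
        total_months += rec.followup_time
    return SufficientStats(n_events, total_months / months_per_year)


def update_posterior(prior: GammaParams, stats: SufficientStats) -> GammaParams:
    """Conjugate update: Gamma(a, b) -> Gamma(a + events, b + exposure).

    With the improper Jeffreys prior the posterior is proper only once at
    least one event has been observed; requesting an update before then
    raises :class:`ImproperPosteriorError` so callers can wait for data.
    """
    if prior.improper and (stats.n_events < 1 or stats.total_exposure <= 0):
        raise ImproperPosteriorError(
            "Jeffreys prior with zero observed events yields an improper "
            "posterior; wait for at least one event before updating"
        )
    return GammaParams(prior.shape + stats.n_events, prior.rate + stats.total_exposure)


def _require_proper(p: GammaParams) -> None:
    if not p.is_proper:
        raise ImproperPosteriorError("operation requires a proper Gamma law")


def posterior_mean_var(p: GammaParams) -> tuple[float, float]:
    """Mean shape/rate (per-year hazard) and variance shape/rate**2."""
    _require_proper(p)
    return p.shape / p.rate, p.shape / p.rate**2


def prior_from_mean_sd(mean: float, sd: float) -> GammaParams:
    """Moment-match a Gamma prior to a stated hazard mean and SD (per year).

    shape = (mean/sd)**2 and rate = mean/sd**2, the unique Gamma with those
    two moments; ``posterior_mean_var`` round-trips (mean, sd**2) exactly.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError(f"mean and sd must be positive, got ({mean}, {sd})")
    return GammaParams((mean / sd) ** 2, mean / sd**2)


def predictive_survival(p: GammaParams, horizon: float) -> float:
    """Posterior-predictive event-free survival at ``horizon`` years.

    Mixing the exponential survival exp(-tau*lam) over a Gamma(shape, rate)
    posterior gives (rate/(rate+tau))**shape exactly.
    """
    _require_proper(p)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return (p.rate / (p.rate + horizon)) ** p.shape


def predictive_survival_sd(p: GammaParams, horizon: float) -> float:
    """Posterior SD of the survival probability exp(-tau*lam) at ``horizon``.

    Exact via the Gamma Laplace transform:
    Var = (rate/(rate+2*tau))**shape - (rate/(rate+tau))**(2*shape).
    """
    _require_proper(p)
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    second = (p.rate / (p.rate + 2.0 * horizon)) ** p.shape
    first = (p.rate / (p.rate + horizon)) ** p.shape
    return math.sqrt(max(second - first * first, 0.0))


def posterior_tail_prob(p: GammaParams, r: float, direction: str = "at-or-above") -> float:
    """P(lam >= r) (``at-or-above``) or its complement (``below``)."""
    _require_proper(p)
    if r < 0:
        raise ValueError("hazard threshold r must be >= 0")
    if direction not in ("at-or-above", "below"):
        raise ValueError("direction must be 'at-or-above' or 'below'")
    upper = float(_gamma_dist.sf(r, a=p.shape, scale=1.0 / p.rate))
    return upper if direction == "at-or-above" else 1.0 - upper


def efs_hazard_threshold(efs0: float, tau: float) -> float:
    """Hazard below which exp(-tau*lam) meets or exceeds ``efs0``."""
    if not 0.0 < efs0 < 1.0:
        raise ValueError("efs0 must lie strictly between 0 and 1")
    if not tau > 0:
        raise ValueError("tau must be positive")
    return -math.log(efs0) / tau


def prob_efs_meets_target(p: GammaParams, efs0: float, tau: float) -> float:
    """Posterior probability that EFS at ``tau`` years meets ``efs0``.

    The event {exp(-tau*lam) >= efs0} equals {lam <= -ln(efs0)/tau}, so this
    is a lower Gamma tail.
    """
    return posterior_tail_prob(p, efs_hazard_threshold(efs0, tau), "below")
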