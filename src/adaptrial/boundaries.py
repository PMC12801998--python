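"""Sequential stopping boundaries for K scheduled analyses.

Two families of efficacy criteria coexist:

* posterior-probability thresholds ``beta_k = 1 - alpha * k / K`` (the
  linearly relaxing rule applied directly to the posterior probability that
  EFS meets the historical control), and
* z-scale critical values from a one-sided error-spending construction at
  equally spaced information fractions ``k / K``, with O'Brien-Fleming-type
  or Pocock-type spending functions.

The spending boundaries are computed by the standard recursive-integration
scheme for Gaussian group-sequential tests: the partial-sum process is
Brownian at the information times, the sub-density of the non-stopped
process is propagated numerically on a grid, and each critical value is
solved so the incremental crossing probability equals the spent error.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["SPENDING_RULES", "linear_posterior_thresholds", "z_boundaries", "spending_function"]

SPENDING_RULES = ("obrien-fleming-spending", "pocock-spending")
DECISION_RULES = SPENDING_RULES + ("linear-posterior-threshold",)


def linear_posterior_thresholds(K: int, alpha: float) -> list[float]:
    """Posterior-probability efficacy thresholds beta_k = 1 - alpha*k/K.

    Strictly decreasing in k, ending at 1 - alpha at the final analysis.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return [1.0 - alpha * k / K for k in range(1, K + 1)]


def spending_function(rule: str, alpha: float, t: np.ndarray) -> np.ndarray:
    """Cumulative one-sided type-I error spent by information fraction t."""
    t = np.asarray(t, dtype=float)
    if rule == "obrien-fleming-spending":
        zq = norm.ppf(1.0 - alpha / 2.0)
        return 2.0 * (1.0 - norm.cdf(zq / np.sqrt(t)))
    if rule == "pocock-spending":
        return alpha * np.log1p((np.e - 1.0) * t)
    raise ValueError(
        f"unknown spending rule {rule!r}; supported: {', '.join(SPENDING_RULES)}"
    )


@lru_cache(maxsize=64)
def _z_boundaries_cached(K: int, alpha: float, rule: str, ngrid: int) -> tuple[float, ...]:
    info = np.arange(1, K + 1) / K
    cum_spend = spending_function(rule, alpha, info)
    cum_spend[-1] = alpha  # both families spend exactly alpha at t = 1
    inc_spend = np.diff(cum_spend, prepend=0.0)

    # Stage 1: the partial sum S_1 ~ N(0, t_1); boundary solves the tail directly.
    sd1 = np.sqrt(info[0])
    u = norm.isf(min(max(inc_spend[0], 1e-15), 1 - 1e-15)) * sd1
    bounds = [u / sd1]

    lo = -9.0  # S-scale lower cut; total sd <= 1 so mass below is negligible
    x = np.linspace(lo, u, ngrid)
    g = norm.pdf(x, scale=sd1)  # sub-density of the non-stopped process

    for k in range(1, K):
        v = info[k] - info[k - 1]
        sv = np.sqrt(v)
        dx = x[1] - x[0]

        def crossing(u_new: float) -> float:
            tail = norm.sf((u_new - x) / sv)
            return float(np.trapezoid(g * tail, dx=dx))

        target = max(inc_spend[k], 1e-15)
        hi = float(x[-1] + 8.0 * sv)
        if crossing(hi) >= target:
            u_new = hi
        else:
            u_new = brentq(lambda z: crossing(z) - target, lo, hi, xtol=1e-10)
        bounds.append(u_new / np.sqrt(info[k]))

        x_new = np.linspace(lo, u_new, ngrid)
        kernel = norm.pdf((x_new[:, None] - x[None, :]) / sv) / sv
        g = kernel @ g * dx
        x = x_new

    return tuple(float(b) for b in bounds)


def z_boundaries(K: int, alpha: float, rule: str = "obrien-fleming-spending",
                 ngrid: int = 1601) -> list[float]:
    """One-sided z-scale critical values at information fractions k/K.

    The cumulative crossing probability under the null equals ``alpha``
    after the final analysis.  For ``K == 1`` every family reduces to the
    fixed-sample critical value ``Phi^{-1}(1 - alpha)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rule not in SPENDING_RULES:
        raise ValueError(
            f"unknown spending rule {rule!r}; supported: {', '.join(SPENDING_RULES)}"
        )
    if K == 1:
        return [float(norm.isf(alpha))]
    return list(_z_boundaries_cached(K, float(alpha), rule, ngrid))
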