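"""Posterior engine for the one-parameter empiric CRM.

The working model is ``R(d_k) = Pr(DLT at dose d_k) ~ alpha_k ** exp(a)``
with skeleton constants ``alpha_k`` and a scalar parameter ``a`` given a
mean-zero normal prior.  After each patient cohort the posterior of ``a``
is updated against the accumulated binomial DLT data, DLT probabilities
are estimated by plugging the posterior mean into the model, and the next
cohort is assigned to the dose whose estimate is closest to the target —
subject to a no-skip escalation restriction and a stopping rule that halts
the trial if even the lowest dose is credibly too toxic.

All posterior integrals use deterministic Simpson quadrature on a fixed
grid of the parameter axis, evaluated in log space with max-subtraction,
so that identical data always yield identical recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Literal

import numpy as np
from scipy.integrate import simpson
from scipy.stats import norm

from .errors import InvalidDesignError, InvalidStateError, NumericalError

__all__ = [
    "DesignSpec",
    "TrialState",
    "PosteriorSummary",
    "Recommendation",
    "log_likelihood",
    "posterior_mean_a",
    "estimate_dlt_probs",
    "recommend_dose",
    "safety_check",
    "next_action",
]

# quadrature grid on the model parameter a: posterior mass for realistic
# phase I sample sizes is far inside [-10, 10]
A_GRID = np.linspace(-10.0, 10.0, 2001)

SAFETY_INTERVAL_LEVEL = 0.90  # central posterior probability interval at dose 1

Status = Literal["accruing", "stopped_safety", "completed"]


@dataclass(frozen=True)
class DesignSpec:
    """Immutable configuration of a CRM design.

    Parameters
    ----------
    theta : float
        Target DLT probability defining the MTD.
    skeleton : tuple of float
        Working-model constants, strictly increasing in (0, 1).
    sigma_a : float
        SD of the mean-zero normal prior on the model parameter.
    start_dose : int
        1-based index of the dose for the first cohort.
    cohort_size : int
        Patients accrued between model updates (1, 2 or 3).
    max_n : int
        Maximum sample size; must be a multiple of ``cohort_size``.
    stop_count : int
        The trial stops, declaring the MTD, when the next recommended dose
        already has this many patients treated on it.  A value above
        ``max_n`` means every trial accrues to the maximum sample size.
    """

    theta: float
    skeleton: tuple[float, ...]
    sigma_a: float
    start_dose: int = 1
    cohort_size: int = 2
    max_n: int = 24
    stop_count: int = 100

    def __post_init__(self) -> None:
        sk = np.asarray(self.skeleton, dtype=float)
        if sk.size < 1 or np.any(sk <= 0) or np.any(sk >= 1):
            raise InvalidDesignError("skeleton values must lie strictly in (0, 1)")
        if sk.size > 1 and np.any(np.diff(sk) <= 0):
            raise InvalidDesignError("skeleton must be strictly increasing")
        if not 0.0 < self.theta < 1.0:
            raise InvalidDesignError(f"target rate must be in (0, 1), got {self.theta}")
        if self.sigma_a <= 0:
            raise InvalidDesignError(f"prior SD must be positive, got {self.sigma_a}")
        if self.cohort_size not in (1, 2, 3):
            raise InvalidDesignError(
                f"cohort size must be 1, 2 or 3, got {self.cohort_size}"
            )
        if self.max_n < 1 or self.max_n % self.cohort_size != 0:
            raise InvalidDesignError(
                "max sample size must be a positive multiple of the cohort size"
            )
        if not 1 <= self.start_dose <= sk.size:
            raise InvalidDesignError(
                f"starting dose {self.start_dose} outside 1..{sk.size}"
            )
        if self.stop_count < 1:
            raise InvalidDesignError("n-at-dose stopping count must be >= 1")
        object.__setattr__(self, "skeleton", tuple(float(v) for v in sk))

    @property
    def K(self) -> int:
        return len(self.skeleton)


@dataclass(frozen=True)
class TrialState:
    """Accumulated evaluable-patient data, per dose.

    ``y[k]`` counts DLTs and ``n[k]`` evaluated patients at dose ``k+1``.
    Replaced (non-evaluable) patients must already be excluded by the
    caller.  ``current_dose`` is the most recently administered level and
    anchors the no-skip escalation restriction.
    """

    y: tuple[int, ...]
    n: tuple[int, ...]
    current_dose: int
    status: Status = "accruing"

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        n = np.asarray(self.n, dtype=int)
        if y.shape != n.shape or y.ndim != 1:
            raise InvalidStateError("DLT and patient-count vectors must match in length")
        if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
            raise InvalidStateError("require 0 <= DLTs <= patients at every dose")
        if not 1 <= self.current_dose <= n.size:
            raise InvalidStateError(
                f"current dose {self.current_dose} outside 1..{n.size}"
            )
        object.__setattr__(self, "y", tuple(int(v) for v in y))
        object.__setattr__(self, "n", tuple(int(v) for v in n))

    @classmethod
    def empty(cls, K: int, start_dose: int = 1) -> "TrialState":
        return cls(y=(0,) * K, n=(0,) * K, current_dose=start_dose)

    @property
    def n_total(self) -> int:
        return int(sum(self.n))

    def with_cohort(self, dose: int, n_new: int, dlts: int) -> "TrialState":
        """Return a new state after observing ``dlts``/``n_new`` at ``dose``."""
        y = list(self.y)
        n = list(self.n)
        y[dose - 1] += dlts
        n[dose - 1] += n_new
        return replace(self, y=tuple(y), n=tuple(n), current_dose=dose)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior point summary after an update.

    ``a_hat`` is the posterior mean of the model parameter; ``p_hat`` the
    plug-in DLT-probability estimates ``alpha_k ** exp(a_hat)``;
    ``p1_interval`` the central 90% credible interval for the DLT
    probability at the lowest dose, which drives the safety stopping rule.
    """

    a_hat: float
    p_hat: tuple[float, ...]
    p1_interval: tuple[float, float]


@dataclass(frozen=True)
class Recommendation:
    """One audit-ready recommendation record."""

    dose: int | None
    stop_reason: str | None
    posterior: PosteriorSummary
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )


def log_likelihood(
    a: float | np.ndarray, state: TrialState, skeleton: np.ndarray
) -> float | np.ndarray:
    """Binomial log likelihood of the empiric model at parameter ``a``.

    ``sum_k [ y_k * exp(a) * log alpha_k + (n_k - y_k) * log(1 - alpha_k**exp(a)) ]``

    Doses with no evaluated patients contribute zero.  If some
    ``alpha_k**exp(a)`` rounds to 1 while non-DLT outcomes were observed
    there, the result floors to ``-inf`` rather than raising.
    Vectorized over ``a``.
    """
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    sk = np.asarray(skeleton, dtype=float)
    y = np.asarray(state.y, dtype=float)
    n = np.asarray(state.n, dtype=float)
    e = np.exp(a_arr)[:, None]  # (n_a, 1)
    log_sk = np.log(sk)[None, :]  # (1, K)
    p = np.exp(e * log_sk)  # alpha_k ** exp(a), always in (0, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        miss = np.log1p(-p)  # -inf where p == 1
    tox_term = y * e * log_sk
    miss_term = np.where(n - y > 0, (n - y) * miss, 0.0)
    ll = np.sum(np.where(n > 0, tox_term + miss_term, 0.0), axis=1)
    return ll if np.ndim(a) else float(ll[0])


def _log_posterior_grid(state: TrialState, design: DesignSpec) -> np.ndarray:
    sk = np.asarray(design.skeleton)
    return log_likelihood(A_GRID, state, sk) + norm.logpdf(
        A_GRID, loc=0.0, scale=design.sigma_a
    )


def posterior_mean_a(
    state: TrialState, design: DesignSpec, a_grid: np.ndarray = A_GRID
) -> float:
    """Posterior mean of the model parameter by Simpson quadrature.

    ``a_hat = ∫ a L(a) φ(a; 0, sigma_a²) da / ∫ L(a) φ(a; 0, sigma_a²) da``
    evaluated in log space with max-subtraction for stability.  With no
    data the likelihood is flat and the prior mean (0) is returned to
    quadrature tolerance.
    """
    sk = np.asarray(design.skeleton)
    lp = log_likelihood(a_grid, state, sk) + norm.logpdf(
        a_grid, loc=0.0, scale=design.sigma_a
    )
    m = np.max(lp)
    if not np.isfinite(m):
        raise NumericalError("posterior density is degenerate on the quadrature grid")
    w = np.exp(lp - m)
    denom = simpson(w, x=a_grid)
    numer = simpson(a_grid * w, x=a_grid)
    if not np.isfinite(denom) or denom <= 0.0:
        raise NumericalError("posterior normalizing integral is not finite")
    return float(numer / denom)


def estimate_dlt_probs(a_hat: float, skeleton: np.ndarray) -> np.ndarray:
    """Plug-in DLT probability estimates ``alpha_k ** exp(a_hat)``."""
    sk = np.asarray(skeleton, dtype=float)
    return sk ** np.exp(a_hat)


def recommend_dose(p_hat: np.ndarray, theta: float, state: TrialState) -> int:
    """Dose with estimated DLT rate closest to target, capped by no-skip.

    Ties in ``|p_hat - theta|`` break to the lower dose.  Escalation may
    move at most one level above the most recent administered dose;
    de-escalation is unrestricted.
    """
    p = np.asarray(p_hat, dtype=float)
    k_star = int(np.argmin(np.abs(p - theta))) + 1  # first minimum -> lower dose
    if k_star > state.current_dose + 1:
        return state.current_dose + 1
    return k_star


def safety_check(
    state: TrialState, design: DesignSpec
) -> tuple[bool, tuple[float, float]]:
    """Stopping rule: is even the lowest dose credibly above the target?

    Computes the central 90% posterior credible interval for
    ``R(d_1) = alpha_1 ** exp(a)`` by normalizing the posterior density of
    ``a`` on the quadrature grid, inverting its CDF at the 5th and 95th
    percentiles, and mapping through the (decreasing) model, so the
    a-quantiles swap roles.  The trial stops if the lower limit exceeds
    ``theta``.  With no data the interval comes from the prior alone.
    """
    lp = _log_posterior_grid(state, design)
    m = np.max(lp)
    if not np.isfinite(m):
        raise NumericalError("posterior density is degenerate on the quadrature grid")
    w = np.exp(lp - m)
    # trapezoid CDF on the grid, then inverse by interpolation
    dx = np.diff(A_GRID)
    seg = 0.5 * (w[1:] + w[:-1]) * dx
    cdf = np.concatenate(([0.0], np.cumsum(seg)))
    total = cdf[-1]
    if not np.isfinite(total) or total <= 0.0:
        raise NumericalError("posterior normalizing integral is not finite")
    cdf /= total
    tail = (1.0 - SAFETY_INTERVAL_LEVEL) / 2.0
    a_lo, a_hi = np.interp([tail, 1.0 - tail], cdf, A_GRID)
    alpha1 = design.skeleton[0]
    lower = alpha1 ** np.exp(a_hi)  # decreasing map: upper a -> lower p
    upper = alpha1 ** np.exp(a_lo)
    return bool(lower > design.theta), (float(lower), float(upper))


def next_action(state: TrialState, design: DesignSpec) -> Recommendation:
    """Full model update: safety check, posterior, next-dose recommendation.

    Deterministic in the trial data (the wall-clock timestamp is attached
    only for audit).  With an empty state the first cohort is assigned to
    the design's starting dose without consulting the model fit, though
    the prior-based posterior summary is still reported.
    """
    stop, interval = safety_check(state, design)
    a_hat = posterior_mean_a(state, design)
    p_hat = estimate_dlt_probs(a_hat, np.asarray(design.skeleton))
    summary = PosteriorSummary(
        a_hat=a_hat,
        p_hat=tuple(float(v) for v in p_hat),
        p1_interval=interval,
    )
    if stop:
        return Recommendation(dose=None, stop_reason="safety", posterior=summary)
    if state.n_total == 0:
        return Recommendation(dose=design.start_dose, stop_reason=None, posterior=summary)
    dose = recommend_dose(p_hat, design.theta, state)
    return Recommendation(dose=dose, stop_reason=None, posterior=summary)
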