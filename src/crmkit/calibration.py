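"""Design calibration for the Bayesian CRM.

Two default design choices are automated here so that a study team only has
to supply the target DLT rate and the number of dose levels:

* the **skeleton** — the vector of working-model constants
  ``alpha_1 < ... < alpha_K`` — built by the indifference-interval
  recursion, which spaces adjacent values so that doses remain
  distinguishable within a band ``[theta - delta, theta + delta]`` around
  the target;
* the **least-informative prior** standard deviation ``sigma_a`` for the
  mean-zero normal prior on the model parameter ``a``, chosen so that the
  implied prior distribution over *which dose is the MTD* is as close to
  uniform as possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect
from scipy.stats import norm

from .errors import InvalidDesignError

__all__ = [
    "SkeletonRequest",
    "generate_skeleton",
    "mtd_intervals",
    "interval_boundaries",
    "prior_mtd_probs",
    "least_informative_sigma",
]

# bracket for root finding on the model parameter a; the boundary function
# alpha_k^exp(a) + alpha_{k+1}^exp(a) - 2*theta is continuous and strictly
# decreasing in a, and its root lies well inside [-20, 20] for any valid
# skeleton with theta in (0, 1)
_A_BRACKET = (-20.0, 20.0)
_ROOT_XTOL = 1e-10

# grid over which the least-informative sigma is searched
_SIGMA_GRID = np.arange(0.1, 3.0 + 1e-12, 0.01)


@dataclass(frozen=True)
class SkeletonRequest:
    """Inputs for the indifference-interval skeleton construction.

    Parameters
    ----------
    delta : float
        Indifference half-width, in probability units. Values of 0.04-0.10
        are typical; 0.05 is the recommended default for targets near 0.25.
    theta : float
        Target DLT probability defining the MTD.
    nu : int
        1-based index of the prior guess of the MTD; the skeleton value at
        this dose equals ``theta`` exactly. The median dose is the
        conventional choice.
    K : int
        Number of dose levels.
    """

    delta: float
    theta: float
    nu: int
    K: int

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < self.theta < 1.0):
            raise InvalidDesignError(
                f"require 0 < delta < theta < 1; got delta={self.delta}, theta={self.theta}"
            )
        if not self.theta + self.delta < 1.0:
            raise InvalidDesignError(
                f"theta + delta must be below 1; got {self.theta + self.delta}"
            )
        if self.K < 1:
            raise InvalidDesignError(f"need at least one dose level, got K={self.K}")
        if not 1 <= self.nu <= self.K:
            raise InvalidDesignError(
                f"prior MTD index nu={self.nu} outside 1..{self.K}"
            )


def generate_skeleton(req: SkeletonRequest) -> np.ndarray:
    """Build the indifference-interval skeleton for a dose-finding design.

    Sets ``alpha_nu = theta`` and recurses outward.  Going up from dose k,
    the next value solves the indifference condition: at the parameter value
    ``a`` where the working model puts dose k at ``theta - delta``, dose
    k+1 sits at ``theta + delta``.  Under the empiric model
    ``alpha^exp(a)`` this gives

    ``alpha_{k+1} = (theta + delta) ** (1/s)`` with
    ``s = log(theta - delta) / log(alpha_k)``,

    and symmetrically downward.  Returned values are full precision;
    round only for display.

    Returns
    -------
    numpy.ndarray
        Strictly increasing vector of K probabilities with
        ``skeleton[req.nu - 1] == req.theta`` exactly.
    """
    delta, theta, nu, K = req.delta, req.theta, req.nu, req.K
    alpha = np.empty(K, dtype=float)
    alpha[nu - 1] = theta
    for k in range(nu - 1, K - 1):  # forward: nu..K-1
        s = np.log(theta - delta) / np.log(alpha[k])
        alpha[k + 1] = (theta + delta) ** (1.0 / s)
    for k in range(nu - 1, 0, -1):  # backward: nu..2
        s = np.log(theta + delta) / np.log(alpha[k])
        alpha[k - 1] = (theta - delta) ** (1.0 / s)
    return alpha


def _validate_skeleton(skeleton: np.ndarray) -> np.ndarray:
    sk = np.asarray(skeleton, dtype=float)
    if sk.ndim != 1 or sk.size < 1:
        raise InvalidDesignError("skeleton must be a non-empty 1-D vector")
    if np.any(sk <= 0.0) or np.any(sk >= 1.0):
        raise InvalidDesignError("skeleton values must lie strictly in (0, 1)")
    if sk.size > 1 and np.any(np.diff(sk) <= 0.0):
        raise InvalidDesignError("skeleton must be strictly increasing")
    return sk


def interval_boundaries(skeleton: np.ndarray, theta: float) -> np.ndarray:
    """Boundaries ``b_1 < ... < b_{K-1}`` between MTD intervals on the a-axis.

    ``b_k`` is the parameter value at which doses k and k+1 are equidistant
    from the target: ``alpha_k^exp(a) + alpha_{k+1}^exp(a) = 2*theta``.
    Found by bisection; the left side is strictly decreasing in ``a``.
    """
    sk = _validate_skeleton(skeleton)
    bounds = np.empty(sk.size - 1, dtype=float)
    for k in range(sk.size - 1):
        lo, hi = sk[k], sk[k + 1]

        def f(a: float, lo: float = lo, hi: float = hi) -> float:
            e = np.exp(a)
            return lo**e + hi**e - 2.0 * theta

        bounds[k] = bisect(f, *_A_BRACKET, xtol=_ROOT_XTOL)
    return bounds


def mtd_intervals(
    skeleton: np.ndarray, theta: float
) -> list[tuple[float, float]]:
    """Partition the parameter axis by which dose the model calls the MTD.

    Returns K intervals ``A_1..A_K`` covering the real line such that for
    ``a`` in ``A_k``, dose k minimizes ``|alpha_k^exp(a) - theta|``.  The
    selected dose index is non-decreasing in ``a`` (every ``alpha^exp(a)``
    is decreasing in ``a``), so ``A_1 = (-inf, b_1]`` and
    ``A_K = [b_{K-1}, inf)``.
    """
    sk = _validate_skeleton(skeleton)
    if sk.size == 1:
        return [(-np.inf, np.inf)]
    b = interval_boundaries(sk, theta)
    edges = np.concatenate(([-np.inf], b, [np.inf]))
    return [(edges[i], edges[i + 1]) for i in range(sk.size)]


def prior_mtd_probs(skeleton: np.ndarray, theta: float, sigma: float) -> np.ndarray:
    """Prior probability that each dose is the MTD under ``a ~ N(0, sigma^2)``.

    ``q_k(sigma) = P(a in A_k)`` with the intervals from
    :func:`mtd_intervals`; the vector sums to 1.
    """
    sk = _validate_skeleton(skeleton)
    if sk.size == 1:
        return np.ones(1)
    cdf = norm.cdf(interval_boundaries(sk, theta) / sigma)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def least_informative_sigma(skeleton: np.ndarray, theta: float) -> float:
    """Calibrate the mean-zero normal prior SD to be least informative.

    Searches ``sigma`` on a grid (0.1 to 3.0, step 0.01) and returns the
    value whose implied prior MTD distribution ``q(sigma)`` is closest to
    uniform in the worst-coordinate sense, ``max_k |q_k - 1/K|``; ties go
    to the smaller sigma.  The resulting prior is vague about which dose
    is the MTD while still anchoring the dose-toxicity model.
    """
    sk = _validate_skeleton(skeleton)
    K = sk.size
    if K == 1:
        raise InvalidDesignError(
            "prior calibration is degenerate with a single dose level"
        )
    b = interval_boundaries(sk, theta)
    target = 1.0 / K
    # vectorized over the sigma grid: q is (n_sigma, K)
    cdf = norm.cdf(b[None, :] / _SIGMA_GRID[:, None])
    q = np.diff(
        np.concatenate(
            (np.zeros((cdf.shape[0], 1)), cdf, np.ones((cdf.shape[0], 1))), axis=1
        ),
        axis=1,
    )
    objective = np.max(np.abs(q - target), axis=1)
    return float(_SIGMA_GRID[int(np.argmin(objective))])  # argmin takes first -> smaller sigma
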