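import numpy as np
import pytest

import crmkit as ck


@pytest.fixture(scope="session")
def default_design() -> ck.DesignSpec:
    """The package's default 5-dose design: target 0.25, delta 0.05, prior
    MTD at the median dose, least-informative prior, cohorts of 2, 24
    patients maximum."""
    return ck.resolve_design(0.25, 5, cohort_size=2, max_n=24, start_dose=1)


@pytest.fixture(scope="session")
def skeleton5(default_design) -> np.ndarray:
    return np.asarray(default_design.skeleton)


def importance_posterior(
    state: ck.TrialState,
    design: ck.DesignSpec,
    n_draws: int = 1_000_000,
    seed: int = 20240401,
):
    """Monte-Carlo oracle for the posterior of the model parameter.

    Draws from the normal prior and weights by the binomial likelihood, so
    it shares no quadrature machinery with the engine.  Returns the
    weighted draws plus the self-normalized mean and its standard error.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, design.sigma_a, size=n_draws)
    logw = ck.log_likelihood(a, state, np.asarray(design.skeleton))
    w = np.exp(logw - logw.max())
    w_sum = w.sum()
    mean = float(np.sum(a * w) / w_sum)
    se = float(np.sqrt(np.sum(w**2 * (a - mean) ** 2)) / w_sum)
    return a, w, mean, se


def weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, x))
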