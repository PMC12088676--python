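"""Frequentist and Bayesian inference on binomial proportions.

Non-noticer forced-choice accuracy is compared with chance (50%) three
ways, mirroring common practice in R (``binom.test`` and the
``BayesFactor`` proportion test):

* exact two-sided binomial test (small-probability-mass rule);
* exact Clopper-Pearson confidence interval;
* a Bayes factor BF10 for the alternative that the log-odds of success
  follow a logistic prior centred at logit(p0) with scale 0.5.

Holm-Bonferroni step-down adjustment is provided for families of tests
(the confidence-bin analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit, roots_legendre

__all__ = [
    "ProportionTestResult",
    "exact_binomial_test",
    "clopper_pearson_ci",
    "proportion_bayes_factor",
    "holm_bonferroni",
]


@dataclass(frozen=True)
class ProportionTestResult:
    successes: int
    trials: int
    null_p: float
    p_value: float
    ci_low: float
    ci_high: float
    confidence_level: float = 0.95
    bf10: Optional[float] = None

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


def _check_counts(successes: int, trials: int) -> None:
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes must lie in [0, trials], got {successes}/{trials}")


def exact_binomial_test(
    successes: int,
    trials: int,
    null_p: float = 0.5,
    level: float = 0.95,
) -> ProportionTestResult:
    """Exact two-sided binomial test with a Clopper-Pearson interval.

    The two-sided p-value sums the probabilities of every outcome whose
    probability does not exceed that of the observed count (the
    "minimum-likelihood" rule used by R's ``binom.test``).
    """
    _check_counts(successes, trials)
    if not 0.0 < null_p < 1.0:
        raise ValueError(f"null proportion must be in (0,1), got {null_p}")
    res = stats.binomtest(successes, trials, null_p, alternative="two-sided")
    lo, hi = clopper_pearson_ci(successes, trials, level)
    return ProportionTestResult(
        successes=successes,
        trials=trials,
        null_p=null_p,
        p_value=float(min(1.0, res.pvalue)),
        ci_low=lo,
        ci_high=hi,
        confidence_level=level,
    )


def clopper_pearson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval from inverting the binomial tail probabilities."""
    _check_counts(successes, trials)
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    ci = stats.binomtest(successes, trials).proportion_ci(
        confidence_level=level, method="exact"
    )
    return float(ci.low), float(ci.high)


@lru_cache(maxsize=16)
def _legendre_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return roots_legendre(n_nodes)


def proportion_bayes_factor(
    successes: int,
    trials: int,
    null_p: float = 0.5,
    prior_scale: float = 0.5,
) -> float:
    """BF10 for a binomial proportion under a logistic log-odds prior.

    Under H1 the log-odds omega of success follow Logistic(logit(p0),
    prior_scale); the marginal likelihood integral

        m1 = int Binom(k; n, expit(omega)) Logistic(omega | logit(p0), r) d omega

    is evaluated by Gauss-Legendre quadrature over +/- 12 prior scales
    around the prior location, in log space to avoid underflow at large n,
    and BF10 = m1 / Binom(k; n, p0).  The node count is doubled until two
    successive evaluations agree to a relative 1e-8 (the likelihood
    narrows like 1/sqrt(n), so large samples need finer grids); failure to
    converge raises an error with diagnostics.
    """
    _check_counts(successes, trials)
    if not 0.0 < null_p < 1.0:
        raise ValueError(f"null proportion must be in (0,1), got {null_p}")
    if prior_scale <= 0:
        raise ValueError(f"prior scale must be positive, got {prior_scale}")

    loc = float(logit(null_p))
    half_width = 12.0 * prior_scale

    def marginal(n_nodes: int) -> float:
        x, w = _legendre_nodes(n_nodes)
        omega = loc + half_width * x
        log_f = stats.binom.logpmf(successes, trials, expit(omega)) + stats.logistic.logpdf(
            omega, loc=loc, scale=prior_scale
        )
        shift = np.max(log_f)
        return float(half_width * np.sum(w * np.exp(log_f - shift)) * math.exp(shift))

    previous = marginal(401)
    n_nodes = 401
    for _ in range(8):
        n_nodes = 2 * n_nodes - 1  # keeps node sets symmetric about loc
        current = marginal(n_nodes)
        if current > 0 and abs(current - previous) <= 1e-8 * abs(current):
            m0 = float(stats.binom.pmf(successes, trials, null_p))
            return current / m0
        previous = current
    raise RuntimeError(
        "Bayes-factor quadrature did not converge: "
        f"k={successes}, n={trials}, p0={null_p}, r={prior_scale}, "
        f"last two marginals {previous!r} at {n_nodes} nodes"
    )


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, returned in input order.

    The i-th smallest p is multiplied by (m - i), running maxima enforce
    monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
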