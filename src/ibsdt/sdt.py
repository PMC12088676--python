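"""Super-subject signal detection estimators.

Group-level ("super subject") sensitivity and response bias for designs in
which every observer contributes a single critical trial.  The decision
matrix pools one yes/no (or binary forced-choice) response per subject;
hit and false-alarm rates are corrected with the log-linear rule (add 0.5
to every cell) so that z-transforms are always finite, and the classic
equal-variance Gaussian statistics follow:

    d'      = z(H) - z(FA)                      (one-interval yes/no)
    d'_2afc = [z(H) - z(FA)] / sqrt(2)          (two-alternative forced choice)
    c       = -[z(H) + z(FA)] / 2               (criterion; >0 is conservative)

Analytic sampling variances follow the standard large-sample expressions
for proportion-based SDT statistics (Gourevitch & Galanter; Macmillan &
Creelman), giving Wald confidence intervals.  The unequal-variance indices
d_a and c_a generalise d' and c through the ROC slope s = 1/sigma, where
sigma is the standard deviation of the signal-plus-noise distribution
relative to the noise distribution.

All functions are pure; no I/O happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from scipy import stats

__all__ = [
    "DecisionMatrix",
    "RatePair",
    "SDTEstimate",
    "UnequalVarianceSpec",
    "log_linear_correct",
    "z_transform",
    "phi_at",
    "dprime_yesno",
    "dprime_2afc",
    "criterion_c",
    "d_a",
    "c_a",
    "var_dprime_yesno",
    "var_dprime_2afc",
    "var_criterion",
    "wald_ci",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DecisionMatrix:
    """Raw pooled counts of the four detection outcomes.

    ``n_present`` (N2) and ``n_absent`` (N1) are derived totals; rates are
    never computed from a matrix with an empty condition.
    """

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_present(self) -> int:
        return self.hits + self.misses

    @property
    def n_absent(self) -> int:
        return self.false_alarms + self.correct_rejections

    def swapped(self) -> "DecisionMatrix":
        """Relabel which condition is 'present', keeping the response coding.

        The old absent trials become the present trials while a "yes"
        still means the same response, so H and FA exchange: d' (and
        d'_2afc) are negated and the criterion c is unchanged.  (A full
        convention swap that also re-codes "yes" to mean the new present
        alternative instead leaves d' identical and negates c.)
        """
        return DecisionMatrix(
            hits=self.false_alarms,
            misses=self.correct_rejections,
            false_alarms=self.hits,
            correct_rejections=self.misses,
        )


@dataclass(frozen=True)
class RatePair:
    """Hit and false-alarm rates, optionally after the log-linear correction."""

    H: float
    FA: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.corrected and not (0.0 < self.H < 1.0 and 0.0 < self.FA < 1.0):
            raise ValueError(
                f"corrected rates must lie strictly in (0,1), got H={self.H}, FA={self.FA}"
            )


@dataclass(frozen=True)
class UnequalVarianceSpec:
    """Relative spread of the signal-plus-noise distribution.

    ``sigma`` is the SD of the signal distribution with the noise SD fixed
    at 1; the ROC slope is ``s = 1/sigma``.  ``sigma = 1`` recovers the
    equal-variance statistics exactly.
    """

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def slope(self) -> float:
        return 1.0 / self.sigma


@dataclass(frozen=True)
class SDTEstimate:
    """A sensitivity or bias statistic with optional variance and Wald CI."""

    statistic_kind: str
    value: float
    variance: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    confidence_level: float = 0.95

    @property
    def se(self) -> Optional[float]:
        return None if self.variance is None else math.sqrt(self.variance)


def log_linear_correct(matrix: DecisionMatrix) -> RatePair:
    """Apply the log-linear (add 0.5 to every cell) correction.

    Returns H = (hits + 0.5)/(N2 + 1) and FA = (FA + 0.5)/(N1 + 1), which
    are strictly inside (0,1) even for perfect or empty cells.
    """
    if matrix.n_present == 0:
        raise ValueError("decision matrix has zero present trials (N2 = 0); cannot form a hit rate")
    if matrix.n_absent == 0:
        raise ValueError(
            "decision matrix has zero absent trials (N1 = 0); cannot form a false-alarm rate"
        )
    H = (matrix.hits + 0.5) / (matrix.n_present + 1)
    FA = (matrix.false_alarms + 0.5) / (matrix.n_absent + 1)
    return RatePair(H=H, FA=FA, corrected=True)


def z_transform(p: float) -> float:
    """Standard-normal quantile of a proportion; defined only on (0,1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"z-transform requires a proportion strictly in (0,1), got {p}")
    return float(stats.norm.ppf(p))


def phi_at(p: float) -> float:
    """Standard-normal density evaluated at z(p): (1/sqrt(2*pi)) exp(-z(p)^2/2)."""
    return float(stats.norm.pdf(z_transform(p)))


def dprime_yesno(rates: RatePair) -> SDTEstimate:
    """One-interval sensitivity d' = z(H) - z(FA)."""
    value = z_transform(rates.H) - z_transform(rates.FA)
    return SDTEstimate(statistic_kind="dprime_yesno", value=value)


def dprime_2afc(rates: RatePair) -> SDTEstimate:
    """2afc sensitivity [z(H) - z(FA)] / sqrt(2).

    The 1/sqrt(2) factor adjusts for two-alternative forced-choice tasks
    being easier than one-interval tasks at the same underlying d'.  One
    of the two alternatives must have been designated 'present' when the
    matrix was built; swapping the designation flips the sign.
    """
    value = (z_transform(rates.H) - z_transform(rates.FA)) / _SQRT2
    return SDTEstimate(statistic_kind="dprime_2afc", value=value)


def criterion_c(rates: RatePair) -> SDTEstimate:
    """Response bias c = -[z(H) + z(FA)]/2; positive means conservative."""
    value = -0.5 * (z_transform(rates.H) + z_transform(rates.FA))
    return SDTEstimate(statistic_kind="criterion", value=value)


def d_a(rates: RatePair, spec: UnequalVarianceSpec) -> SDTEstimate:
    """Unequal-variance sensitivity index.

    With ROC slope s = 1/sigma,

        d_a = sqrt(2/(1+s^2)) * [z(H) - s*z(FA)]

    which reduces to d' when sigma = 1.
    """
    s = spec.slope
    value = math.sqrt(2.0 / (1.0 + s * s)) * (z_transform(rates.H) - s * z_transform(rates.FA))
    return SDTEstimate(statistic_kind="d_a", value=value)


def c_a(rates: RatePair, spec: UnequalVarianceSpec) -> SDTEstimate:
    """Unequal-variance bias index.

    With s = 1/sigma,

        c_a = -[sqrt(2)*s / sqrt(1+s^2)] * [z(H) + z(FA)] / (1+s)

    which reduces to c when sigma = 1.
    """
    s = spec.slope
    value = (
        -(_SQRT2 * s / math.sqrt(1.0 + s * s))
        * (z_transform(rates.H) + z_transform(rates.FA))
        / (1.0 + s)
    )
    return SDTEstimate(statistic_kind="c_a", value=value)


def _var_z_terms(rates: RatePair, matrix: DecisionMatrix) -> tuple[float, float]:
    """Sampling variances of z(H) and z(FA) by the delta method."""
    if matrix.n_present == 0 or matrix.n_absent == 0:
        raise ValueError("variance requires at least one present and one absent trial")
    H, FA = rates.H, rates.FA
    vh = H * (1.0 - H) / (matrix.n_present * phi_at(H) ** 2)
    vf = FA * (1.0 - FA) / (matrix.n_absent * phi_at(FA) ** 2)
    return vh, vf


def var_dprime_yesno(rates: RatePair, matrix: DecisionMatrix) -> float:
    """var(d') = H(1-H)/(N2 phi(H)^2) + FA(1-FA)/(N1 phi(FA)^2)."""
    vh, vf = _var_z_terms(rates, matrix)
    return vh + vf


def var_dprime_2afc(rates: RatePair, matrix: DecisionMatrix) -> float:
    """2afc variant: each term halved, i.e. var(d') / 2 at identical inputs."""
    vh, vf = _var_z_terms(rates, matrix)
    return (vh + vf) / 2.0


def var_criterion(rates: RatePair, matrix: DecisionMatrix) -> float:
    """var(c) = [var(zH) + var(zFA)] / 4 (Gourevitch-Galanter form)."""
    vh, vf = _var_z_terms(rates, matrix)
    return (vh + vf) / 4.0


def wald_ci(estimate: SDTEstimate, level: float = 0.95) -> SDTEstimate:
    """Symmetric normal-theory interval value +/- q(level) * sqrt(variance)."""
    if estimate.variance is None:
        raise ValueError("cannot form a Wald interval without a variance")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    q = float(stats.norm.ppf(0.5 + level / 2.0))
    half = q * math.sqrt(estimate.variance)
    return replace(
        estimate,
        ci_low=estimate.value - half,
        ci_high=estimate.value + half,
        confidence_level=level,
    )


def estimate_from_matrix(
    matrix: DecisionMatrix,
    statistic: str,
    *,
    sigma: float = 1.0,
    level: float = 0.95,
) -> SDTEstimate:
    """Convenience: correct a matrix and return a statistic with its Wald CI.

    ``statistic`` is one of ``dprime_yesno``, ``dprime_2afc``, ``criterion``,
    ``d_a`` or ``c_a``.  For the unequal-variance indices no analytic
    variance is attached (their sampling theory is out of scope); all other
    statistics carry the variance appropriate to their task type.
    """
    rates = log_linear_correct(matrix)
    spec = UnequalVarianceSpec(sigma=sigma)
    if statistic == "dprime_yesno":
        est = replace(dprime_yesno(rates), variance=var_dprime_yesno(rates, matrix))
    elif statistic == "dprime_2afc":
        est = replace(dprime_2afc(rates), variance=var_dprime_2afc(rates, matrix))
    elif statistic == "criterion":
        est = replace(criterion_c(rates), variance=var_criterion(rates, matrix))
    elif statistic == "d_a":
        return d_a(rates, spec)
    elif statistic == "c_a":
        return c_a(rates, spec)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return wald_ci(est, level)
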