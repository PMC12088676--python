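"""From per-subject critical-trial records to a full experiment report.

The analysis treats the pooled responses of all subjects as those of a
single "super subject": each subject contributes exactly one critical
trial, so hit/false-alarm rates, d', and the criterion c are defined at
the group level.  A report contains

* the inattentional-blindness (IB) rate: the fraction of present-condition
  subjects who answered "no" to the noticing question;
* detection sensitivity d' and bias c over all subjects (requires an
  absent condition), with analytic Wald intervals, plus the
  unequal-variance indices d_a / c_a at a chosen ROC spread sigma;
* per-feature sensitivity of the non-noticers (2afc for location,
  one-interval for colour and shape) with intervals, and exact binomial +
  Bayesian tests of their percent-correct against chance;
* for confidence designs, the location sensitivity in every
  (yes/no x confidence 0-3) bin, with Holm-Bonferroni-adjusted p-values;
* for attended-colour designs, the colour-congruency breakdown;
* the absent-condition guess-rate table per feature.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .designs import ExperimentDesign
from .inference import ProportionTestResult, exact_binomial_test, holm_bonferroni, proportion_bayes_factor
from .records import CriticalTrialRecord
from .sdt import (
    DecisionMatrix,
    SDTEstimate,
    UnequalVarianceSpec,
    c_a,
    criterion_c,
    d_a,
    dprime_2afc,
    dprime_yesno,
    log_linear_correct,
    var_criterion,
    var_dprime_2afc,
    var_dprime_yesno,
    wald_ci,
)

__all__ = [
    "detection_matrix",
    "twoafc_matrix",
    "one_interval_matrix",
    "analyze_experiment",
    "congruency_breakdown",
    "FeatureAnalysis",
    "ConfidenceBin",
    "ExperimentReport",
]


def _included(records: Sequence[CriticalTrialRecord]) -> list[CriticalTrialRecord]:
    return [r for r in records if not r.excluded]


def detection_matrix(records: Sequence[CriticalTrialRecord]) -> DecisionMatrix:
    """Pool yes/no noticing responses into the detection decision matrix."""
    recs = _included(records)
    hits = sum(1 for r in recs if r.condition == "present" and r.noticed == "yes")
    misses = sum(1 for r in recs if r.condition == "present" and r.noticed == "no")
    fas = sum(1 for r in recs if r.condition == "absent" and r.noticed == "yes")
    crs = sum(1 for r in recs if r.condition == "absent" and r.noticed == "no")
    if fas + crs == 0:
        raise ValueError(
            "no absent-condition records: detection d' and c require absent trials "
            "to estimate a false-alarm rate"
        )
    if hits + misses == 0:
        raise ValueError("no present-condition records: cannot form a hit rate")
    return DecisionMatrix(hits=hits, misses=misses, false_alarms=fas, correct_rejections=crs)


def twoafc_matrix(
    records: Sequence[CriticalTrialRecord], present_side: str = "left"
) -> DecisionMatrix:
    """2afc location matrix: one side (by convention the left) is 'present'.

    Trials with the stimulus on ``present_side`` count as present trials;
    responding ``present_side`` is a "yes".  d' is invariant (up to sign)
    to which side is designated present.
    """
    if present_side not in {"left", "right"}:
        raise ValueError(f"present_side must be 'left' or 'right', got {present_side!r}")
    recs = [r for r in _included(records) if r.condition == "present"]
    missing = [r.subject_id for r in recs if r.stim_side is None or r.side_response is None]
    if missing:
        raise ValueError(
            f"{len(missing)} records lack a stimulus side or side response "
            f"(e.g. {missing[:3]}); a 2afc matrix needs both"
        )
    hits = sum(1 for r in recs if r.stim_side == present_side and r.side_response == present_side)
    misses = sum(1 for r in recs if r.stim_side == present_side and r.side_response != present_side)
    fas = sum(1 for r in recs if r.stim_side != present_side and r.side_response == present_side)
    crs = sum(1 for r in recs if r.stim_side != present_side and r.side_response != present_side)
    return DecisionMatrix(hits=hits, misses=misses, false_alarms=fas, correct_rejections=crs)


def one_interval_matrix(
    records: Sequence[CriticalTrialRecord],
    feature: str,
    signal_level: Optional[str] = None,
) -> DecisionMatrix:
    """One-interval forced-response matrix for a binary feature.

    Trials whose stimulus carries ``signal_level`` are 'present' and a
    response of ``signal_level`` is a "yes".  d' is invariant to which of
    the two levels is called signal; the sign of c flips.
    """
    if feature not in {"color", "shape"}:
        raise ValueError(f"one-interval features are 'color' and 'shape', got {feature!r}")
    stim_attr = f"stim_{feature}"
    resp_attr = f"{feature}_response"
    recs = [r for r in _included(records) if r.condition == "present"]
    missing = [r.subject_id for r in recs if getattr(r, stim_attr) is None or getattr(r, resp_attr) is None]
    if missing:
        raise ValueError(
            f"{len(missing)} records lack a stimulus {feature} or {feature} response "
            f"(e.g. {missing[:3]})"
        )
    levels = sorted({getattr(r, stim_attr) for r in recs})
    if len(levels) > 2:
        raise ValueError(f"feature {feature!r} has {len(levels)} levels {levels}; binary designs only")
    if signal_level is None:
        signal_level = levels[0]
    hits = misses = fas = crs = 0
    for r in recs:
        is_signal = getattr(r, stim_attr) == signal_level
        said_signal = getattr(r, resp_attr) == signal_level
        if is_signal and said_signal:
            hits += 1
        elif is_signal:
            misses += 1
        elif said_signal:
            fas += 1
        else:
            crs += 1
    return DecisionMatrix(hits=hits, misses=misses, false_alarms=fas, correct_rejections=crs)


@dataclass(frozen=True)
class FeatureAnalysis:
    """Non-noticer analysis of one follow-up question."""

    feature: str
    task: str  # "2afc" or "one_interval"
    matrix: DecisionMatrix
    sensitivity: SDTEstimate
    bias: Optional[SDTEstimate]  # one-interval tasks only; 2afc is criterion-free
    accuracy_test: ProportionTestResult


@dataclass(frozen=True)
class ConfidenceBin:
    noticed: str
    confidence: int
    n: int
    sensitivity: Optional[SDTEstimate]
    p_value: Optional[float]
    p_holm: Optional[float]
    under_powered: bool


@dataclass(frozen=True)
class ExperimentReport:
    experiment_id: str
    confidence_level: float
    sigma: float
    n_records: int
    n_excluded: int
    n_present: int
    n_absent: int
    n_non_noticers: int
    ib_rate: Optional[float]
    detection_dprime: Optional[SDTEstimate]
    detection_criterion: Optional[SDTEstimate]
    detection_d_a: Optional[SDTEstimate]
    detection_c_a: Optional[SDTEstimate]
    features: dict[str, FeatureAnalysis]
    confidence_bins: Optional[list[ConfidenceBin]]
    congruency: Optional[dict]
    absent_guess_rates: Optional[dict[str, dict[str, float]]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=_json_default, **kwargs)

    def to_table(self) -> pd.DataFrame:
        """Human-readable summary table (one statistic per row)."""
        rows: list[dict] = []

        def add(label: str, est: Optional[SDTEstimate], n: int) -> None:
            if est is None:
                return
            rows.append(
                {
                    "statistic": label,
                    "value": est.value,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": n,
                }
            )

        n_all = self.n_present + self.n_absent
        if self.ib_rate is not None:
            rows.append({"statistic": "ib_rate", "value": self.ib_rate, "ci_low": None,
                         "ci_high": None, "n": self.n_present})
        add("detection_dprime", self.detection_dprime, n_all)
        add("detection_criterion", self.detection_criterion, n_all)
        for name, fa in self.features.items():
            add(f"{name}_{'dprime_2afc' if fa.task == '2afc' else 'dprime'}",
                fa.sensitivity, fa.matrix.n_present + fa.matrix.n_absent)
            add(f"{name}_criterion", fa.bias, fa.matrix.n_present + fa.matrix.n_absent)
            t = fa.accuracy_test
            rows.append(
                {
                    "statistic": f"{name}_percent_correct",
                    "value": t.proportion,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "n": t.trials,
                }
            )
        return pd.DataFrame(rows, columns=["statistic", "value", "ci_low", "ci_high", "n"])


def _json_default(obj):
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    raise TypeError(f"not JSON serialisable: {obj!r}")


def _sdt_pair(
    matrix: DecisionMatrix, level: float
) -> tuple[SDTEstimate, SDTEstimate]:
    """Detection d' and c with variances and Wald intervals."""
    rates = log_linear_correct(matrix)
    d = dataclasses.replace(dprime_yesno(rates), variance=var_dprime_yesno(rates, matrix))
    c = dataclasses.replace(criterion_c(rates), variance=var_criterion(rates, matrix))
    return wald_ci(d, level), wald_ci(c, level)


def _feature_analysis(
    records: Sequence[CriticalTrialRecord],
    feature: str,
    level: float,
    null_p: float = 0.5,
) -> FeatureAnalysis:
    if feature == "side":
        matrix = twoafc_matrix(records)
        rates = log_linear_correct(matrix)
        sens = dataclasses.replace(
            dprime_2afc(rates), variance=var_dprime_2afc(rates, matrix)
        )
        bias = None
    else:
        matrix = one_interval_matrix(records, feature)
        rates = log_linear_correct(matrix)
        sens = dataclasses.replace(
            dprime_yesno(rates), variance=var_dprime_yesno(rates, matrix)
        )
        bias = wald_ci(
            dataclasses.replace(criterion_c(rates), variance=var_criterion(rates, matrix)),
            level,
        )
    sens = wald_ci(sens, level)
    correct = matrix.hits + matrix.correct_rejections
    trials = matrix.n_present + matrix.n_absent
    test = exact_binomial_test(correct, trials, null_p, level)
    test = dataclasses.replace(test, bf10=proportion_bayes_factor(correct, trials, null_p))
    return FeatureAnalysis(
        feature=feature,
        task="2afc" if feature == "side" else "one_interval",
        matrix=matrix,
        sensitivity=sens,
        bias=bias,
        accuracy_test=test,
    )


def _wald_p(est: SDTEstimate) -> float:
    se = est.se
    if se is None or se == 0:
        raise ValueError("p-value requires a positive standard error")
    return float(2.0 * stats.norm.sf(abs(est.value) / se))


def _confidence_bins(
    records: Sequence[CriticalTrialRecord], level: float, min_n: int = 20
) -> list[ConfidenceBin]:
    present = [
        r
        for r in _included(records)
        if r.condition == "present" and r.notice_confidence is not None
    ]
    bins: list[ConfidenceBin] = []
    estimates: list[tuple[int, SDTEstimate]] = []
    for noticed in ("no", "yes"):
        for conf in range(4):
            subset = [r for r in present if r.noticed == noticed and r.notice_confidence == conf]
            n = len(subset)
            sides = {r.stim_side for r in subset}
            if n == 0 or sides != {"left", "right"}:
                # bin empty or one-sided: location sensitivity undefined
                bins.append(ConfidenceBin(noticed, conf, n, None, None, None, n < min_n))
                continue
            matrix = twoafc_matrix(subset)
            rates = log_linear_correct(matrix)
            est = wald_ci(
                dataclasses.replace(
                    dprime_2afc(rates), variance=var_dprime_2afc(rates, matrix)
                ),
                level,
            )
            estimates.append((len(bins), est))
            bins.append(ConfidenceBin(noticed, conf, n, est, _wald_p(est), None, n < min_n))
    adjusted = holm_bonferroni([b.p_value for b in bins if b.p_value is not None])
    it = iter(adjusted)
    return [
        dataclasses.replace(b, p_holm=next(it)) if b.p_value is not None else b
        for b in bins
    ]


def congruency_breakdown(records: Sequence[CriticalTrialRecord]) -> dict:
    """Notice rates and colour-response bias by attended-vs-stimulus colour.

    Returns ``notice_rates`` for colour-congruent and -incongruent present
    trials (stimulus colour equal / unequal to the attended colour) and a
    ``response_bias`` table: among present trials, the proportion choosing
    each colour, split by attended colour.
    """
    recs = [r for r in _included(records) if r.condition == "present"]
    if not recs:
        raise ValueError("congruency breakdown requires present-condition records")
    if any(r.attended_color is None for r in recs):
        raise ValueError("congruency breakdown requires attended_color on every record")
    if any(r.stim_color is None for r in recs):
        raise ValueError("congruency breakdown requires a stimulus colour on present records")

    def notice_rate(subset: list[CriticalTrialRecord]) -> Optional[float]:
        return (
            sum(1 for r in subset if r.noticed == "yes") / len(subset) if subset else None
        )

    congruent = [r for r in recs if r.stim_color == r.attended_color]
    incongruent = [r for r in recs if r.stim_color != r.attended_color]
    bias: dict[str, dict[str, float]] = {}
    for attended in sorted({r.attended_color for r in recs}):
        group = [r for r in recs if r.attended_color == attended and r.color_response is not None]
        if group:
            bias[attended] = {
                resp: sum(1 for r in group if r.color_response == resp) / len(group)
                for resp in sorted({g.color_response for g in group})
            }
    return {
        "notice_rates": {
            "congruent": notice_rate(congruent),
            "incongruent": notice_rate(incongruent),
            "n_congruent": len(congruent),
            "n_incongruent": len(incongruent),
        },
        "response_bias": bias,
    }


def _absent_guess_rates(
    records: Sequence[CriticalTrialRecord], features: Sequence[str]
) -> Optional[dict[str, dict[str, float]]]:
    absent = [r for r in _included(records) if r.condition == "absent"]
    if not absent:
        return None
    table: dict[str, dict[str, float]] = {}
    for feature in features:
        attr = f"{feature}_response"
        answered = [getattr(r, attr) for r in absent if getattr(r, attr) is not None]
        if answered:
            table[feature] = {
                level: answered.count(level) / len(answered) for level in sorted(set(answered))
            }
    return table or None


def analyze_experiment(
    records: Sequence[CriticalTrialRecord],
    design: ExperimentDesign,
    confidence_level: float = 0.95,
    sigma: float = 1.0,
) -> ExperimentReport:
    """Run the full super-subject analysis for one experiment."""
    records = list(records)
    if not records:
        raise ValueError("no records to analyze")
    wrong_exp = {r.experiment_id for r in records} - {design.experiment_id}
    if wrong_exp:
        raise ValueError(
            f"records belong to {sorted(wrong_exp)} but the design is "
            f"{design.experiment_id!r}"
        )
    recs = _included(records)
    if not recs:
        raise ValueError("all records are excluded")
    present = [r for r in recs if r.condition == "present"]
    absent = [r for r in recs if r.condition == "absent"]
    if design.has_confidence and all(r.notice_confidence is None for r in present):
        raise ValueError(
            f"design {design.experiment_id!r} collects confidence ratings but no "
            "record carries one"
        )

    ib_rate = (
        sum(1 for r in present if r.noticed == "no") / len(present) if present else None
    )
    non_noticers = [r for r in present if r.noticed == "no"]

    det_d = det_c = det_da = det_ca = None
    if absent and present:
        matrix = detection_matrix(recs)
        det_d, det_c = _sdt_pair(matrix, confidence_level)
        rates = log_linear_correct(matrix)
        spec = UnequalVarianceSpec(sigma=sigma)
        det_da, det_ca = d_a(rates, spec), c_a(rates, spec)

    features = {
        feature: _feature_analysis(non_noticers, feature, confidence_level)
        for feature in design.features
    }

    conf_bins = _confidence_bins(recs, confidence_level) if design.has_confidence else None

    congruency = None
    if (
        design.attended_colors
        and design.colors
        and set(design.attended_colors) & set(design.colors)
    ):
        congruency = congruency_breakdown(recs)

    return ExperimentReport(
        experiment_id=design.experiment_id,
        confidence_level=confidence_level,
        sigma=sigma,
        n_records=len(records),
        n_excluded=len(records) - len(recs),
        n_present=len(present),
        n_absent=len(absent),
        n_non_noticers=len(non_noticers),
        ib_rate=ib_rate,
        detection_dprime=det_d,
        detection_criterion=det_c,
        detection_d_a=det_da,
        detection_c_a=det_ca,
        features=features,
        confidence_bins=conf_bins,
        congruency=congruency,
        absent_guess_rates=_absent_guess_rates(recs, design.features),
    )
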