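"""Observer-model generator: determinism, calibration, model signatures."""

import math

import numpy as np
import pytest
from scipy import stats

from ibsdt import (
    ObserverModelParams,
    SimulationConfig,
    analyze_experiment,
    criterion_jitter_study,
    get_design,
    recover_parameters,
    simulate_experiment,
    simulate_frame,
)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"detection_dprime": -0.1},
            {"signal_sigma": 0.0},
            {"criterion_sd": -1.0},
            {"confidence_criteria": (1.0, 0.5, 1.5)},
            {"confidence_criteria": (0.5, 0.5, 1.5)},
            {"guess_bias_color": 0.0},
            {"feature_detection_correlation": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ObserverModelParams(**kwargs)

    def test_invalid_design(self):
        with pytest.raises(ValueError, match="unknown design"):
            simulate_experiment(ObserverModelParams(), SimulationConfig("exp9", 10))


class TestDeterminism:
    def test_same_seed_same_records(self):
        p, c = ObserverModelParams(), SimulationConfig("exp5", 500, seed=42)
        assert simulate_experiment(p, c) == simulate_experiment(p, c)

    def test_different_seed_differs(self):
        p = ObserverModelParams()
        a = simulate_experiment(p, SimulationConfig("exp5", 500, seed=1))
        b = simulate_experiment(p, SimulationConfig("exp5", 500, seed=2))
        assert a != b


class TestCalibration:
    def test_null_observer_answers_yes_at_chance_in_both_conditions(self):
        params = ObserverModelParams(detection_dprime=0.0, mean_criterion=0.0)
        frame = simulate_frame(params, SimulationConfig("exp5", 10_000, seed=8))
        for condition in ("present", "absent"):
            sub = frame[frame.condition == condition]
            rate = (sub.noticed == "yes").mean()
            se = math.sqrt(0.25 / len(sub))
            assert abs(rate - 0.5) < 3 * se

    def test_gaussian_model_rates_match_closed_form(self):
        # H = Phi(d'/2 - c), FA = Phi(-d'/2 - c) at tau=0, sigma=1
        params = ObserverModelParams(detection_dprime=2.0, mean_criterion=0.45)
        frame = simulate_frame(params, SimulationConfig("exp5", 100_000, seed=13))
        present = frame[frame.condition == "present"]
        absent = frame[frame.condition == "absent"]
        H_true = stats.norm.cdf(1.0 - 0.45)
        FA_true = stats.norm.cdf(-1.0 - 0.45)
        H = (present.noticed == "yes").mean()
        FA = (absent.noticed == "yes").mean()
        assert abs(H - H_true) < 3 * math.sqrt(H_true * (1 - H_true) / len(present))
        assert abs(FA - FA_true) < 3 * math.sqrt(FA_true * (1 - FA_true) / len(absent))

    def test_present_fraction_law_of_large_numbers(self):
        frame = simulate_frame(ObserverModelParams(), SimulationConfig("exp5", 100_000, seed=3))
        frac = (frame.condition == "present").mean()
        se = math.sqrt(0.75 * 0.25 / 100_000)
        assert abs(frac - 0.75) < 3 * se

    def test_feature_channel_independent_of_detection_by_default(self):
        frame = simulate_frame(
            ObserverModelParams(feature_dprime_color=0.3),
            SimulationConfig("exp5", 50_000, seed=21),
        )
        sub = frame[(frame.condition == "present") & (frame.stim_color == "orange")]
        table = np.asarray(
            [
                [
                    ((sub.noticed == yn) & (sub.color_response == resp)).sum()
                    for resp in ("orange", "green")
                ]
                for yn in ("yes", "no")
            ]
        )
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001

    def test_confidence_ratings_span_scale_and_grow_with_distance(self):
        frame = simulate_frame(
            ObserverModelParams(), SimulationConfig("exp3", 20_000, seed=2)
        )
        conf = frame.notice_confidence.astype(int)
        assert set(conf.unique()) == {0, 1, 2, 3}


class TestCongruencySignature:
    def test_suppression_reproduces_congruency_pattern(self):
        on = ObserverModelParams(congruency_suppression=0.6, feature_dprime_color=0.2)
        off = ObserverModelParams(congruency_suppression=0.0, feature_dprime_color=0.2)
        design = get_design("exp4")
        cfg = SimulationConfig("exp4", 30_000, seed=17)
        rep_on = analyze_experiment(simulate_experiment(on, cfg), design)
        rep_off = analyze_experiment(simulate_experiment(off, cfg), design)

        rates_on = rep_on.congruency["notice_rates"]
        assert rates_on["incongruent"] < rates_on["congruent"] - 0.2
        rates_off = rep_off.congruency["notice_rates"]
        n = rates_off["n_congruent"]
        assert abs(rates_off["congruent"] - rates_off["incongruent"]) < 3 * math.sqrt(0.5 / n)
        # apparent colour sensitivity among non-noticers is inflated
        assert (
            rep_on.features["color"].sensitivity.value
            > rep_off.features["color"].sensitivity.value + 0.1
        )


class TestRecovery:
    def test_requires_model_assumptions(self):
        with pytest.raises(ValueError, match="tau = 0"):
            recover_parameters(
                ObserverModelParams(criterion_sd=0.5), SimulationConfig("exp5", 100)
            )
        with pytest.raises(ValueError, match="absent condition"):
            recover_parameters(ObserverModelParams(), SimulationConfig("exp1", 100))

    def test_null_observer_recovered_near_zero(self):
        params = ObserverModelParams(detection_dprime=0.0, mean_criterion=0.0)
        out = recover_parameters(
            params, SimulationConfig("exp5", 50_000, seed=6), n_replicates=3
        )
        assert abs(out["dprime_bias"]) < 0.02
        assert abs(out["criterion_bias"]) < 0.02


class TestJitterStudy:
    def test_empty_grid_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            criterion_jitter_study(ObserverModelParams(), [], SimulationConfig("exp5", 100))

    def test_needs_location_question_and_absent_condition(self):
        with pytest.raises(ValueError, match="absent condition"):
            criterion_jitter_study(
                ObserverModelParams(), [0.0], SimulationConfig("exp1", 100)
            )
        with pytest.raises(ValueError):
            criterion_jitter_study(
                ObserverModelParams(), [0.0], SimulationConfig("exp2", 100)
            )

    def test_known_attenuation_factor(self):
        # pooled one-interval d' shrinks by 1/sqrt(1+tau^2)
        params = ObserverModelParams(detection_dprime=2.0, mean_criterion=0.45)
        table = criterion_jitter_study(
            params, [0.0, 1.0], SimulationConfig("exp5", 50_000, seed=19)
        )
        expected = 2.0 / math.sqrt(2.0)
        row = table[table.tau == 1.0].iloc[0]
        assert row.detection_dprime == pytest.approx(
            expected, abs=4 * row.detection_dprime_se
        )
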