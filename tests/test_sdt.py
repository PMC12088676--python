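"""Unit and property tests for the super-subject SDT estimators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibsdt import (
    DecisionMatrix,
    RatePair,
    SDTEstimate,
    UnequalVarianceSpec,
    c_a,
    criterion_c,
    d_a,
    dprime_2afc,
    dprime_yesno,
    estimate_from_matrix,
    log_linear_correct,
    phi_at,
    var_criterion,
    var_dprime_2afc,
    var_dprime_yesno,
    wald_ci,
    z_transform,
)

rates_strategy = st.builds(
    RatePair,
    H=st.floats(0.01, 0.99),
    FA=st.floats(0.01, 0.99),
    corrected=st.just(True),
)


class TestLogLinearCorrection:
    @pytest.mark.parametrize(
        "matrix, expected_H, expected_FA",
        [
            (DecisionMatrix(10, 0, 0, 10), 10.5 / 11, 0.5 / 11),
            (DecisionMatrix(71, 29, 7, 93), 71.5 / 101, 7.5 / 101),
        ],
    )
    def test_corrected_rates(self, matrix, expected_H, expected_FA):
        rates = log_linear_correct(matrix)
        assert rates.corrected
        assert rates.H == pytest.approx(expected_H, abs=1e-12)
        assert rates.FA == pytest.approx(expected_FA, abs=1e-12)

    @pytest.mark.parametrize(
        "matrix", [DecisionMatrix(0, 0, 0, 0), DecisionMatrix(5, 5, 0, 0), DecisionMatrix(0, 0, 2, 3)]
    )
    def test_empty_condition_is_an_error(self, matrix):
        with pytest.raises(ValueError, match="zero (present|absent) trials"):
            log_linear_correct(matrix)

    @given(
        hits=st.integers(0, 200),
        misses=st.integers(0, 200),
        fas=st.integers(0, 200),
        crs=st.integers(0, 200),
    )
    def test_correction_lands_inside_unit_interval_and_shrinks_to_half(
        self, hits, misses, fas, crs
    ):
        matrix = DecisionMatrix(hits, misses, fas, crs)
        if matrix.n_present == 0 or matrix.n_absent == 0:
            return
        rates = log_linear_correct(matrix)
        assert 0.0 < rates.H < 1.0 and 0.0 < rates.FA < 1.0
        raw_H = hits / matrix.n_present
        assert abs(rates.H - 0.5) <= abs(raw_H - 0.5) + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DecisionMatrix(-1, 2, 3, 4)


class TestTransforms:
    def test_z_of_half_is_zero(self):
        assert z_transform(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p, expected", [(0.71, 0.5534), (0.073, -1.4538)])
    def test_z_known_quantiles(self, p, expected):
        assert z_transform(p) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.7])
    def test_z_domain_error(self, p):
        with pytest.raises(ValueError):
            z_transform(p)

    @pytest.mark.parametrize(
        "p, expected", [(0.5, 1 / math.sqrt(2 * math.pi)), (0.71, 0.3423), (0.073, 0.1387)]
    )
    def test_phi_known_values(self, p, expected):
        assert phi_at(p) == pytest.approx(expected, abs=2e-4)

    @given(p=st.floats(0.001, 0.999))
    def test_phi_symmetric_and_maximal_at_half(self, p):
        assert phi_at(p) == pytest.approx(phi_at(1 - p), rel=1e-9)
        assert phi_at(p) <= phi_at(0.5) + 1e-15


class TestSensitivityAndBias:
    def test_worked_example(self):
        rates = RatePair(0.71, 0.073, corrected=True)
        assert dprime_yesno(rates).value == pytest.approx(2.01, abs=0.005)
        assert criterion_c(rates).value == pytest.approx(0.45, abs=0.005)

    def test_symmetric_rates(self):
        assert dprime_yesno(RatePair(0.3, 0.3, corrected=True)).value == pytest.approx(0, abs=1e-12)
        assert criterion_c(RatePair(0.8, 0.2, corrected=True)).value == pytest.approx(0, abs=1e-12)
        # 2 * z(0.84) by quantile symmetry
        assert dprime_yesno(RatePair(0.84, 0.16, corrected=True)).value == pytest.approx(
            2 * z_transform(0.84), abs=1e-12
        )

    def test_conservative_super_subject_bias(self):
        assert criterion_c(RatePair(0.427, 0.0631, corrected=True)).value == pytest.approx(
            0.857, abs=0.005
        )

    def test_2afc_worked_example(self):
        value = dprime_2afc(RatePair(0.7264, 0.4554, corrected=True)).value
        assert value == pytest.approx(0.505, abs=0.001)

    def test_2afc_quantile_symmetry(self):
        value = dprime_2afc(RatePair(0.75, 0.25, corrected=True)).value
        assert value == pytest.approx(2 * z_transform(0.75) / math.sqrt(2), abs=1e-12)

    @given(rates=rates_strategy)
    def test_2afc_is_yesno_over_sqrt2(self, rates):
        assert dprime_2afc(rates).value == pytest.approx(
            dprime_yesno(rates).value / math.sqrt(2), abs=1e-12
        )

    @given(rates=rates_strategy)
    def test_criterion_zero_iff_mirror_rates(self, rates):
        mirrored = RatePair(rates.H, 1 - rates.H, corrected=True)
        assert criterion_c(mirrored).value == pytest.approx(0.0, abs=1e-9)

    @given(h=st.floats(0.02, 0.98), delta=st.floats(0.001, 0.01))
    def test_monotone_in_rates(self, h, delta):
        fa = 0.3
        low = dprime_yesno(RatePair(h, fa, corrected=True)).value
        high = dprime_yesno(RatePair(min(h + delta, 0.995), fa, corrected=True)).value
        assert high > low


class TestUnequalVariance:
    RATES = RatePair(0.71, 0.073, corrected=True)

    @pytest.mark.parametrize(
        "sigma, expected_d, expected_c",
        [(1.25, 1.898, 0.443), (0.75, 2.118, 0.438)],
    )
    def test_published_robustness_values(self, sigma, expected_d, expected_c):
        spec = UnequalVarianceSpec(sigma=sigma)
        assert d_a(self.RATES, spec).value == pytest.approx(expected_d, abs=0.005)
        assert c_a(self.RATES, spec).value == pytest.approx(expected_c, abs=0.005)

    @given(rates=rates_strategy)
    def test_equal_variance_limit(self, rates):
        spec = UnequalVarianceSpec(sigma=1.0)
        assert d_a(rates, spec).value == pytest.approx(dprime_yesno(rates).value, abs=1e-12)
        assert c_a(rates, spec).value == pytest.approx(criterion_c(rates).value, abs=1e-12)

    @pytest.mark.parametrize("sigma", [0.0, -1.5])
    def test_sigma_domain(self, sigma):
        with pytest.raises(ValueError):
            UnequalVarianceSpec(sigma=sigma)


class TestVariances:
    def test_symmetric_midpoint(self):
        rates = RatePair(0.5, 0.5, corrected=True)
        matrix = DecisionMatrix(50, 50, 50, 50)
        v = var_dprime_yesno(rates, matrix)
        assert v == pytest.approx(2 * 0.25 / (100 * phi_at(0.5) ** 2), abs=1e-12)
        assert var_dprime_2afc(rates, matrix) == pytest.approx(v / 2, abs=1e-15)
        assert var_criterion(rates, matrix) == pytest.approx(v / 4, abs=1e-15)

    def test_exp5_scale_standard_error(self):
        rates = RatePair(0.71, 0.073, corrected=True)
        matrix = DecisionMatrix(4297, 1755, 147, 1870)  # N2=6052, N1=2017
        assert math.sqrt(var_dprime_yesno(rates, matrix)) == pytest.approx(0.045, abs=0.001)
        assert math.sqrt(var_criterion(rates, matrix)) == pytest.approx(0.0226, abs=0.0005)

    def test_one_over_n_scaling(self):
        rates = RatePair(0.7, 0.1, corrected=True)
        small = DecisionMatrix(70, 30, 10, 90)
        big = DecisionMatrix(140, 60, 20, 180)
        assert var_dprime_yesno(rates, big) == pytest.approx(
            var_dprime_yesno(rates, small) / 2, rel=1e-12
        )

    @given(rates=rates_strategy, n2=st.integers(5, 500), n1=st.integers(5, 500))
    def test_algebraic_identities(self, rates, n2, n1):
        matrix = DecisionMatrix(n2, 0, 0, n1)
        v = var_dprime_yesno(rates, matrix)
        assert v > 0
        assert var_dprime_2afc(rates, matrix) == pytest.approx(v / 2, rel=1e-12)
        assert var_criterion(rates, matrix) == pytest.approx(v / 4, rel=1e-12)


class TestWaldCI:
    def test_standard_normal_interval(self):
        est = SDTEstimate("dprime_yesno", 0.0, variance=1.0)
        out = wald_ci(est, 0.95)
        assert out.ci_low == pytest.approx(-1.95996, abs=1e-4)
        assert out.ci_high == pytest.approx(1.95996, abs=1e-4)

    def test_2afc_interval_matches_published(self):
        est = SDTEstimate("dprime_2afc", 0.51, variance=0.178**2)
        out = wald_ci(est, 0.95)
        assert out.ci_low == pytest.approx(0.16, abs=0.01)
        assert out.ci_high == pytest.approx(0.86, abs=0.01)

    def test_wider_at_higher_level(self):
        est = SDTEstimate("criterion", 0.3, variance=0.04)
        assert wald_ci(est, 0.99).ci_high > wald_ci(est, 0.95).ci_high

    def test_missing_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            wald_ci(SDTEstimate("criterion", 0.3))


class TestEstimateFromMatrix:
    def test_swapping_designation_negates_2afc(self):
        matrix = DecisionMatrix(38, 14, 25, 30)
        d = estimate_from_matrix(matrix, "dprime_2afc")
        d_swapped = estimate_from_matrix(matrix.swapped(), "dprime_2afc")
        assert d_swapped.value == pytest.approx(-d.value, abs=1e-12)

    def test_unknown_statistic(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            estimate_from_matrix(DecisionMatrix(5, 5, 5, 5), "beta")
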