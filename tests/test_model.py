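import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leptindrive.errors import ConfigError, DomainError
from leptindrive.model import (ModelParams, alpha_from_eta, beta_from_reference,
                               calories_to_weight, expenditure,
                               gamma_from_halflife, ode_rhs, qss_leptin,
                               weight_closed_form, weight_to_calories)


def round_sig(x, n=3):
    return float(f"{x:.{n}g}")


class TestGammaFromHalflife:
    @pytest.mark.parametrize("halflife_min, expected, sig", [
        (24.9, 40.1, 3),            # renal clearance half-life of plasma leptin
        (1440.0, 0.6931, 4),        # one-day half-life -> ln 2 per day
        (720.0, 1.3863, 5),
    ])
    def test_examples(self, halflife_min, expected, sig):
        assert round_sig(gamma_from_halflife(halflife_min), sig) == expected

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(DomainError):
            gamma_from_halflife(bad)


class TestBetaCalibration:
    def test_subject_b_reference(self):
        beta = beta_from_reference(20.3, 40.1, 3500.0, 0.316, 127.4)
        assert round_sig(beta) == 5.78e-3

    def test_subject_a_reference_within_input_rounding(self):
        # printed 3.68e-3; direct arithmetic from rounded inputs gives ~3.66e-3
        beta = beta_from_reference(20.3, 40.1, 3500.0, 0.405, 157.0)
        assert beta == pytest.approx(3.66e-3, rel=2e-3)
        assert beta == pytest.approx(3.68e-3, rel=7e-3)

    def test_linearity_in_reference_level(self):
        b1 = beta_from_reference(20.3, 40.1, 3500.0, 0.316, 127.4)
        b2 = beta_from_reference(40.6, 40.1, 3500.0, 0.316, 127.4)
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    @pytest.mark.parametrize("delta", [0.0, 1.0, -0.2])
    def test_bad_fat_fraction(self, delta):
        with pytest.raises(DomainError):
            beta_from_reference(20.3, 40.1, 3500.0, delta, 127.4)


class TestAlphaFromEta:
    def test_subject_a(self):
        assert round_sig(alpha_from_eta(2.78e-5, 40.1, 3.68e-3)) == 0.303

    def test_subject_b_within_input_rounding(self):
        assert alpha_from_eta(1.17e-4, 40.1, 5.78e-3) == pytest.approx(0.816, rel=6e-3)

    @given(st.floats(1e-6, 1e-2), st.floats(1.0, 100.0), st.floats(1e-4, 1e-1))
    @settings(deadline=None, max_examples=50)
    def test_algebraic_inverse(self, eta, gamma, beta):
        alpha = alpha_from_eta(eta, gamma, beta)
        assert alpha * beta / gamma == pytest.approx(eta, rel=1e-12)

    def test_table_consistency(self):
        # printed alpha*beta/gamma must reproduce the printed eta
        assert round_sig(0.303 * 3.68e-3 / 40.1) == 2.78e-5
        assert 0.816 * 5.78e-3 / 40.1 == pytest.approx(1.17e-4, rel=1e-2)


class TestQssLeptin:
    def test_zero_store(self):
        assert qss_leptin(0.0, 3.68e-3, 40.1) == 0.0

    def test_calibration_consistency(self):
        C = 3500.0 * 0.405 * 157.0
        assert qss_leptin(C, 3.68e-3, 40.1) == pytest.approx(20.3, abs=0.15)

    def test_linearity(self):
        assert qss_leptin(2e5, 3.68e-3, 40.1) == pytest.approx(
            2 * qss_leptin(1e5, 3.68e-3, 40.1), rel=1e-12)

    def test_negative_store_rejected(self):
        with pytest.raises(DomainError):
            qss_leptin(-1.0, 3.68e-3, 40.1)


class TestExpenditure:
    def test_zero_rate_constant(self):
        t = np.linspace(0, 3000, 7)
        assert np.allclose(expenditure(t, 2571.0, (0.0,)), 2571.0)

    def test_initial_value(self):
        assert expenditure(0.0, 2571.0, (1.00e-7,)) == 2571.0

    def test_continuity_across_transition(self):
        q_lo = expenditure(1000.0 - 1e-7, 2571.0, (1e-5, 3e-6), (1000.0,))
        q_hi = expenditure(1000.0 + 1e-7, 2571.0, (1e-5, 3e-6), (1000.0,))
        assert q_lo == pytest.approx(q_hi, rel=1e-10)

    @given(st.floats(1e-7, 1e-4), st.floats(1e-7, 1e-4),
           st.floats(100.0, 2000.0), st.floats(0.0, 3000.0))
    @settings(deadline=None, max_examples=50)
    def test_continuity_property(self, e1, e2, t_star, t_query):
        args = (2000.0, (e1, e2), (t_star,))
        below = expenditure(np.nextafter(t_star, 0.0), *args)
        above = expenditure(np.nextafter(t_star, np.inf), *args)
        assert below == pytest.approx(above, rel=1e-12)
        assert expenditure(t_query, *args) > 0

    def test_unsorted_schedule_rejected(self):
        with pytest.raises(ConfigError):
            expenditure(1.0, 2000.0, (1e-5, 2e-5, 3e-5), (500.0, 400.0))


class TestWeightClosedForm:
    def test_subject_a_start(self, subject_a_params):
        assert weight_closed_form(0.0, subject_a_params) == pytest.approx(145.1,
                                                                          abs=0.05)

    def test_zero_decay_gives_constant(self, subject_a_params):
        from dataclasses import replace
        p = replace(subject_a_params, epsilons=(0.0,))
        t = np.linspace(0, 2500, 11)
        w = weight_closed_form(t, p)
        expected = (p.D - p.Q0) / (p.eta * p.rho * p.delta)
        assert np.allclose(w, expected, rtol=1e-12)

    def test_nondecreasing_when_expenditure_decays(self, subject_a_params):
        t = np.linspace(0, 2500, 200)
        w = weight_closed_form(t, subject_a_params)
        assert np.all(np.diff(w) >= 0)

    def test_small_decay_limit_matches_zero_decay(self, wellposed_truth):
        from dataclasses import replace
        t = np.linspace(0, 100 * 30.4375, 101)
        w0 = weight_closed_form(t, replace(wellposed_truth, epsilons=(0.0,)))
        w1 = weight_closed_form(t, replace(wellposed_truth, epsilons=(1e-12,)))
        assert np.max(np.abs(w1 - w0) / w0) < 1e-6

    def test_invalid_when_eta_below_eps(self, subject_a_params):
        from dataclasses import replace
        with pytest.raises(DomainError):
            replace(subject_a_params, epsilons=(1e-3,))


class TestUnitConversions:
    def test_one_pound_of_fat(self):
        assert calories_to_weight(3500.0, 3500.0, 0.999999) == pytest.approx(1.0,
                                                                             rel=1e-5)

    def test_reference_store(self):
        assert weight_to_calories(157.0, 3500.0, 0.405) == pytest.approx(222547.5)

    @given(st.floats(50.0, 400.0), st.floats(0.15, 0.5))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, W, delta):
        C = weight_to_calories(W, 3500.0, delta)
        assert calories_to_weight(C, 3500.0, delta) == pytest.approx(W, rel=1e-12)

    def test_zero_scale_rejected(self):
        with pytest.raises(DomainError):
            calories_to_weight(100.0, 0.0, 0.3)


class TestOdeRhs:
    def test_equilibrium(self, subject_a_params):
        p = subject_a_params
        # pick C at the reduced equation's fixed point for a compatible drive
        C = (p.D - p.Q0) / p.eta
        L = p.beta * C / p.gamma
        from dataclasses import replace
        p0 = replace(p, epsilons=(0.0,))
        dC, dL = ode_rhs((C, L), 0.0, p0, lambda t: p.D)
        assert abs(dC) < 1e-8 * p.D
        assert abs(dL) < 1e-8 * p.gamma * max(L, 1.0)

    def test_empty_system_balanced_intake(self, subject_a_params):
        p = subject_a_params
        dC, dL = ode_rhs((0.0, 0.0), 0.0, p, lambda t: p.Q0)
        assert dC == 0.0 and dL == 0.0

    def test_calibration_near_leptin_steady_state(self, subject_a_params):
        p = subject_a_params
        C = p.rho * p.delta * 157.0
        dC, dL = ode_rhs((C, 20.3), 0.0, p, lambda t: p.D)
        assert abs(dL) < 0.01 * p.gamma * 20.3


class TestModelParams:
    def test_eta_consistency_enforced(self):
        with pytest.raises(DomainError):
            ModelParams(alpha=0.3, beta=3.68e-3, gamma=40.1, eta=9.9e-5)

    def test_serialization_round_trip(self, tmp_path, subject_a_params):
        path = tmp_path / "params.yaml"
        subject_a_params.to_file(path)
        back = ModelParams.from_file(path)
        assert back == subject_a_params

    def test_two_section_serialization(self, tmp_path):
        p = ModelParams(gamma=40.1, delta=0.316, eta=1.17e-4, Q0=2100.0,
                        epsilons=(2.06e-6, 8.30e-7), transitions=(1217.5,))
        p.to_file(tmp_path / "p.yaml")
        assert ModelParams.from_file(tmp_path / "p.yaml") == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            ModelParams.from_dict({"D": 2000.0, "zeta": 1.0})
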