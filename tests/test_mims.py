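"""MIMS oxygen budget arithmetic and drift correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photophys import (IonCurrentReading, O2Rates, budget_fractions,
                       cell_normalize, drift_correct, signals_to_rates)
from photophys.exceptions import PhotophysError
from photophys.mims import CalibrationPair, identity_calibration
from photophys.synthetic import budget_to_rates, gen_mims_set


def _reading(treatment, c32, c36, c40=10.0, t=0.0):
    return IonCurrentReading(vial_id="v", treatment=treatment, current_32=c32,
                             current_36=c36, current_40=c40, timestamp=t)


class TestSignalsToRates:
    def test_worked_example(self):
        # 18O2: T0=100, dark=96, light=92; 16O2: T0=50, light=130; 20 min
        rates = signals_to_rates(_reading("T0", 50, 100),
                                 _reading("dark", 60, 96),
                                 _reading("HL", 130, 92), duration_min=20.0)
        assert rates.R_DARK == pytest.approx(12.0)
        assert rates.LDR == pytest.approx(12.0)
        assert rates.GP_O2 == pytest.approx(240.0)
        assert rates.Net_O2 == pytest.approx(216.0)

    def test_no_signal_change_gives_zero_rates(self):
        r0 = _reading("T0", 50, 100)
        rates = signals_to_rates(r0, _reading("dark", 50, 100),
                                 _reading("HL", 50, 100))
        assert (rates.GP_O2, rates.R_DARK, rates.LDR, rates.Net_O2) == (
            0.0, 0.0, 0.0, 0.0)

    def test_equal_light_and_dark_uptake_means_zero_ldr(self):
        rates = signals_to_rates(_reading("T0", 50, 100),
                                 _reading("dark", 50, 96),
                                 _reading("HL", 90, 96))
        assert rates.LDR == pytest.approx(0.0)

    def test_negative_ldr_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="negative LDR"):
            rates = signals_to_rates(_reading("T0", 50, 100),
                                     _reading("dark", 50, 90),
                                     _reading("HL", 90, 96))
        assert rates.LDR < 0

    def test_conservation_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t0 = _reading("T0", rng.uniform(10, 100), rng.uniform(50, 150))
            dark = _reading("dark", t0.current_32,
                            t0.current_36 * rng.uniform(0.8, 1.0))
            light = _reading("HL", t0.current_32 * rng.uniform(1.0, 3.0),
                             t0.current_36 * rng.uniform(0.7, 1.1))
            rates = signals_to_rates(t0, dark, light)
            assert rates.Net_O2 == pytest.approx(
                rates.GP_O2 - rates.R_DARK - rates.LDR, abs=1e-9)


class TestBudgetFractions:
    def test_worked_example_fractions(self):
        b = budget_fractions(O2Rates(GP_O2=240.0, R_DARK=12.0, LDR=12.0))
        assert b.pct_LDR == pytest.approx(5.0)
        assert b.pct_RDARK == pytest.approx(5.0)
        assert b.pct_Net == pytest.approx(90.0)

    def test_no_respiration_is_all_net(self):
        b = budget_fractions(O2Rates(GP_O2=100.0, R_DARK=0.0, LDR=0.0))
        assert b.pct_Net == pytest.approx(100.0)

    @given(gp=st.floats(1.0, 500.0), rd=st.floats(0.0, 100.0),
           ldr=st.floats(-20.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_100(self, gp, rd, ldr):
        b = budget_fractions(O2Rates(GP_O2=gp, R_DARK=rd, LDR=ldr))
        assert b.pct_Net + b.pct_RDARK + b.pct_LDR == pytest.approx(
            100.0, abs=1e-9)

    def test_undefined_for_nonpositive_gp(self):
        with pytest.raises(PhotophysError, match="undefined"):
            budget_fractions(O2Rates(GP_O2=0.0, R_DARK=1.0, LDR=1.0))


class TestDriftCorrection:
    def test_constant_factor_is_pure_scale(self):
        cal = CalibrationPair(0.0, 60.0, {"32": 2.0, "36": 2.0, "40": 2.0},
                              {"32": 2.0, "36": 2.0, "40": 2.0})
        r = drift_correct(_reading("T0", 100, 50, 10, t=30.0), cal,
                          ar_normalize=False)
        assert r.current_32 == pytest.approx(50.0)
        assert r.current_36 == pytest.approx(25.0)

    def test_linear_drift_interpolated_at_midpoint(self):
        # factor drifting 10% over the run: midpoint reading corrected by 5%
        cal = CalibrationPair(0.0, 60.0, {"32": 1.0, "36": 1.0, "40": 1.0},
                              {"32": 1.1, "36": 1.1, "40": 1.1})
        r = drift_correct(_reading("T0", 100, 100, 10, t=30.0), cal,
                          ar_normalize=False)
        assert r.current_32 == pytest.approx(100.0 / 1.05)

    def test_outside_window_warns_and_uses_nearest(self):
        cal = identity_calibration(0.0, 60.0)
        with pytest.warns(UserWarning, match="calibration window"):
            drift_correct(_reading("T0", 100, 100, 10, t=90.0), cal)

    def test_ar_normalization_cancels_common_gain(self):
        cal = identity_calibration()
        a = drift_correct(_reading("T0", 100, 50, 10, t=1.0), cal)
        b = drift_correct(_reading("T0", 200, 100, 20, t=1.0), cal)
        assert a.current_32 == pytest.approx(b.current_32)
        assert a.current_36 == pytest.approx(b.current_36)


class TestRoundTrip:
    def test_generator_is_right_inverse_of_analysis(self):
        truth = (240.0, 12.0, 12.0)
        readings, _ = gen_mims_set(truth)
        cal = identity_calibration()
        corr = {k: drift_correct(v, cal) for k, v in readings.items()}
        rates = signals_to_rates(corr["T0"], corr["dark"], corr["HL"])
        assert rates.GP_O2 == pytest.approx(240.0, rel=1e-12)
        assert rates.R_DARK == pytest.approx(12.0, rel=1e-12)
        assert rates.LDR == pytest.approx(12.0, rel=1e-12)

    def test_budget_reference_round_trip(self):
        # the reported high-light %LDR decline endpoint for T. weissflogii
        triple = budget_to_rates(8.1, 16.6, gp=240.0)
        readings, _ = gen_mims_set(triple)
        corr = {k: drift_correct(v, identity_calibration())
                for k, v in readings.items()}
        b = budget_fractions(signals_to_rates(corr["T0"], corr["dark"],
                                              corr["HL"]))
        assert b.pct_LDR == pytest.approx(8.1, abs=1e-9)

    def test_noise_scales_rate_error(self):
        truth = (240.0, 12.0, 12.0)
        cal = identity_calibration()

        def rmse(cv):
            errs = []
            for seed in range(50):
                readings, _ = gen_mims_set(truth, noise_cv=cv, seed=seed)
                corr = {k: drift_correct(v, cal)
                        for k, v in readings.items()}
                r = signals_to_rates(corr["T0"], corr["dark"], corr["HL"])
                errs.append((r.GP_O2 - 240.0) ** 2)
            return np.sqrt(np.mean(errs))

        assert rmse(0.0) == 0.0
        assert rmse(0.001) < rmse(0.005)


class TestCellNormalize:
    def test_unit_chain(self):
        # 1 nmol mL^-1 h^-1 over 1e6 cells mL^-1 = 1 fmol = 0.001 pmol per cell
        assert cell_normalize(1.0, 1e6) == pytest.approx(0.001)

    def test_proportionality_and_zero(self):
        assert cell_normalize(2.0, 2e6) == pytest.approx(
            cell_normalize(1.0, 1e6))
        assert cell_normalize(0.0, 1e6) == 0.0

    def test_rejects_zero_density(self):
        with pytest.raises(ValueError):
            cell_normalize(1.0, 0.0)
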