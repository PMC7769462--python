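"""Kok damage-repair kinetics: forward model, k_PI / k_REC fits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from photophys import fit_kpi, fit_krec, kok_predict, relaxation_amplitude
from photophys.constants import SPECIES_REFERENCE
from photophys.kok import (LightPhase, default_phases, sigma_i_from_kpi,
                           sigma_i_nm2_per_photon)
from photophys.synthetic import (gen_inactivation_course,
                                 kok_params_for_species)

SPECIES = ["T_oceanica", "T_pseudonana", "T_weissflogii"]


class TestForwardModel:
    def test_pure_decay_closed_form(self):
        # k_REC = 0, k_PI = 4.50e-4 s^-1: A(1000 s) = exp(-0.45)
        phases = (LightPhase(1200.0, 0.0, 60.0),)
        sigma_i = 4.50e-4 / 1200.0
        a = kok_predict(sigma_i, 0.0, phases, 1000.0 / 60.0)
        assert a == pytest.approx(np.exp(-0.45), rel=1e-12)
        assert a == pytest.approx(0.6376, abs=5e-5)

    def test_steady_state_balance(self):
        # A_ss = k_REC/(k_PI + k_REC) with the T. oceanica constants
        phases = (LightPhase(1200.0, 0.0, 1e5),)
        a = kok_predict(4.50e-4 / 1200.0, 5.48e-4, phases, 1e5)
        assert a == pytest.approx(5.48e-4 / (4.50e-4 + 5.48e-4), rel=1e-6)
        assert a == pytest.approx(0.549, abs=5e-4)

    def test_dark_phase_relaxes_toward_one(self):
        phases = (LightPhase(0.0, 0.0, 500.0),)
        t = np.array([0.0, 100.0, 500.0])
        a = kok_predict(1e-6, 1e-3, phases, t, y0=0.5)
        expected = 1.0 + (0.5 - 1.0) * np.exp(-1e-3 * t * 60.0)
        np.testing.assert_allclose(a, expected, rtol=1e-12)

    def test_zero_rates_hold_constant(self):
        phases = (LightPhase(0.0, 0.0, 100.0),)
        a = kok_predict(0.0, 0.0, phases, np.linspace(0, 100, 5), y0=0.8)
        np.testing.assert_allclose(a, 0.8)

    def test_matches_ode_integration(self):
        """Closed-form piecewise solution vs numerical integration of
        dA/dt = -sigma_I E(t) A + k_REC (1 - A) within 1e-8."""
        phases = default_phases()
        sigma_i, k_rec = 3.46e-4 / 1200.0, 1.50e-3

        def irradiance(t_min):
            return 1200.0 if t_min < 120.0 else 15.0

        def rhs(t_s, a):
            e = irradiance(t_s / 60.0)
            return -sigma_i * e * a + k_rec * (1.0 - a)

        t_min = np.array([0.0, 30.0, 60.0, 119.99, 120.0, 150.0, 180.0])
        sol = solve_ivp(rhs, (0.0, 180.0 * 60.0), [1.0], t_eval=t_min * 60.0,
                        rtol=1e-11, atol=1e-13, max_step=30.0)
        np.testing.assert_allclose(kok_predict(sigma_i, k_rec, phases, t_min),
                                   sol.y[0], atol=1e-8)

    def test_continuous_across_phase_boundary(self):
        phases = default_phases()
        before = kok_predict(1e-7, 1e-3, phases, 120.0 - 1e-9)
        after = kok_predict(1e-7, 1e-3, phases, 120.0 + 1e-9)
        assert before == pytest.approx(after, abs=1e-6)

    def test_bounded_and_steady_state_monotonicity(self):
        phases = default_phases()
        t = np.linspace(0, 180, 50)
        a = kok_predict(4e-7, 5e-4, phases, t, y0=1.0)
        assert np.all((a > 0) & (a <= 1.0))
        # A_ss increases with k_REC, decreases with E
        a_ss = lambda k, krec, e: krec / (k * e + krec)
        assert a_ss(4e-7, 1e-3, 1200) > a_ss(4e-7, 5e-4, 1200)
        assert a_ss(4e-7, 5e-4, 1200) < a_ss(4e-7, 5e-4, 85)

    def test_rejects_time_outside_phases(self):
        with pytest.raises(ValueError):
            kok_predict(1e-7, 0.0, default_phases(), 500.0)


class TestSigmaI:
    def test_per_umol_photons(self):
        assert sigma_i_from_kpi(4.50e-4, 1200.0) == pytest.approx(3.75e-7)

    def test_nm2_per_photon(self):
        # 4.50e-4 / (1200 * 6.022e-4 photons nm^-2 s^-1)
        assert sigma_i_nm2_per_photon(4.50e-4, 1200.0) == pytest.approx(
            6.23e-4, rel=1e-3)

    def test_zero_damage_zero_cross_section(self):
        assert sigma_i_from_kpi(0.0, 1200.0) == 0.0

    def test_rejects_zero_irradiance(self):
        with pytest.raises(ValueError):
            sigma_i_from_kpi(4.5e-4, 0.0)


class TestPhotoinactivationFit:
    @pytest.mark.parametrize("species", SPECIES)
    def test_noiseless_recovery_of_reference_constants(self, species):
        truth = kok_params_for_species(species)
        courses = [gen_inactivation_course(truth, lincomycin=True,
                                           replicate_id=f"r{i}")[0]
                   for i in range(3)]
        res = fit_kpi(courses)
        assert res.estimates["k_pi"] == pytest.approx(truth.k_pi, rel=1e-3)

    def test_flat_course_gives_zero_rate(self):
        truth = kok_params_for_species("T_oceanica")
        c, _ = gen_inactivation_course(truth, lincomycin=True)
        c.y = np.full_like(c.y, 0.55)
        res = fit_kpi([c])
        assert res.estimates["k_pi"] == pytest.approx(0.0, abs=1e-10)

    def test_increasing_trace_warns_but_fits(self):
        truth = kok_params_for_species("T_oceanica")
        c, _ = gen_inactivation_course(truth, lincomycin=True)
        c.y = c.y[::-1].copy()
        with pytest.warns(UserWarning, match="increases"):
            fit_kpi([c])

    def test_rejects_control_courses(self):
        truth = kok_params_for_species("T_oceanica")
        c, _ = gen_inactivation_course(truth, lincomycin=False)
        with pytest.raises(ValueError, match="lincomycin"):
            fit_kpi([c])

    def test_median_bias_small_under_noise(self):
        # 5% multiplicative noise at the study's 4-point sampling
        truth = kok_params_for_species("T_pseudonana")
        errs = []
        for seed in range(200):
            c, _ = gen_inactivation_course(truth, lincomycin=True,
                                           noise_cv=0.05, seed=seed)
            res = fit_kpi([c])
            errs.append((res.estimates["k_pi"] - truth.k_pi) / truth.k_pi)
        assert abs(np.median(errs)) < 0.05


class TestRepairFit:
    @pytest.mark.parametrize("species", SPECIES)
    def test_joint_noiseless_recovery(self, species):
        """Both constants recovered within 1% from the two-phase protocol at
        the study's six sampling times."""
        truth = kok_params_for_species(species)
        linco = [gen_inactivation_course(truth, lincomycin=True)[0]
                 for _ in range(3)]
        sigma_i = fit_kpi(linco).estimates["sigma_i"]
        assert sigma_i * 1200.0 == pytest.approx(truth.k_pi, rel=0.01)
        ctrl = [gen_inactivation_course(truth, lincomycin=False,
                                        replicate_id=f"c{i}")[0]
                for i in range(3)]
        res = fit_krec(ctrl, sigma_i)
        assert res.estimates["k_rec"] == pytest.approx(truth.k_rec, rel=0.01)

    def test_zero_repair_nests_to_lincomycin_decay(self):
        truth = kok_params_for_species("T_oceanica")
        zero = type(truth)(k_pi=truth.k_pi, k_rec=0.0)
        c_ctrl, _ = gen_inactivation_course(zero, lincomycin=False,
                                            sample_times_min=(0, 30, 60, 120))
        c_linco, _ = gen_inactivation_course(truth, lincomycin=True)
        np.testing.assert_allclose(c_ctrl.y, c_linco.y, rtol=1e-12)

    def test_missing_recovery_points_warn(self):
        truth = kok_params_for_species("T_pseudonana")
        c, _ = gen_inactivation_course(truth, lincomycin=False,
                                       sample_times_min=(0, 30, 60, 120))
        with pytest.warns(UserWarning, match="recovery"):
            fit_krec([c], truth.sigma_i)

    def test_recovery_across_k_rec_sweep_under_noise(self):
        # 1% noise, k_REC spanning the plausible range, 6-point sampling
        for k_rec in [1e-4, 3e-4, 1e-3, 3e-3]:
            truth = kok_params_for_species("T_pseudonana")
            truth = type(truth)(k_pi=truth.k_pi, k_rec=k_rec)
            errs = []
            for seed in range(10):
                ctrl = [gen_inactivation_course(truth, noise_cv=0.01,
                                                seed=seed * 10 + i,
                                                replicate_id=f"c{i}")[0]
                        for i in range(3)]
                res = fit_krec(ctrl, truth.sigma_i)
                errs.append(abs(res.estimates["k_rec"] - k_rec) / k_rec)
            assert np.median(errs) < 0.10


class TestRelaxationAmplitude:
    def test_amplitude_difference(self):
        pair = relaxation_amplitude(0.50, 0.20)
        assert pair.amplitude == pytest.approx(0.30)
        assert not pair.flagged_negative

    def test_fully_sustained_quenching(self):
        assert relaxation_amplitude(0.45, 0.45).amplitude == 0.0

    def test_ordering_of_relaxing_species(self):
        fast = relaxation_amplitude(0.45, 0.10)
        slow = relaxation_amplitude(0.45, 0.45)
        assert fast.amplitude > slow.amplitude

    def test_negative_amplitude_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="negative"):
            pair = relaxation_amplitude(0.20, 0.30)
        assert pair.amplitude == pytest.approx(-0.10)
        assert pair.flagged_negative
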