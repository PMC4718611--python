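"""Energy-budget fluxes, the integrator and its analytic oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemadeb.deb_core import (DEBParams, OrganismState, compute_fluxes,
                              cumulative_offspring, physical_to_volumetric,
                              simulate, structural_mass,
                              volumetric_to_physical,
                              von_bertalanffy_closed_form)
from nemadeb.environment import TemperatureProfile
from nemadeb.toxstress import EffectiveStress


class TestFluxes:
    def test_hand_evaluated_fluxes_post_puberty(self, const_params):
        # L = 0.1 mm volumetric, well past a (lowered) puberty length
        p = const_params.evolve(L_p_phys=0.30)
        fl = compute_fluxes(OrganismState(t=5.0, L=0.1), p, F_T=1.0)
        assert fl.J_A == pytest.approx(9.4e-4, rel=1e-12)
        assert fl.J_M_flux == pytest.approx(3.86e-4, rel=1e-12)
        assert fl.J_V == pytest.approx(2.43168e-4, rel=1e-9)
        assert fl.J_R == pytest.approx(2.5004e-4, rel=1e-9)

    def test_growth_ceases_at_maximum_size(self, const_params):
        fl = compute_fluxes(OrganismState(t=5.0, L=const_params.L_m_vol),
                            const_params, F_T=1.0)
        assert fl.J_V == pytest.approx(0.0, abs=1e-18)

    def test_no_reproduction_before_puberty(self, const_params):
        L_below = const_params.L_p_vol * 0.9
        fl = compute_fluxes(OrganismState(t=2.0, L=L_below), const_params)
        assert fl.J_R == 0.0

    def test_conservation_identity(self, const_params):
        # J_A = J_M + J_V/y_VA + J_R on unstarved post-puberty states
        p = const_params.evolve(L_p_phys=0.30)
        for L in np.linspace(0.05, p.L_m_vol * 0.999, 17):
            fl = compute_fluxes(OrganismState(t=3.0, L=L), p, F_T=0.7)
            total = fl.J_M_flux + fl.J_V / p.y_VA + fl.J_R
            assert total == pytest.approx(fl.J_A, rel=1e-12)

    def test_rejects_nonfinite_state(self, const_params):
        with pytest.raises(ValueError):
            compute_fluxes(OrganismState(t=0.0, L=np.nan), const_params)

    def test_stress_multipliers_enter_fluxes(self, const_params):
        es = EffectiveStress(maintenance=1.076)
        base = compute_fluxes(OrganismState(t=1.0, L=0.1), const_params)
        stressed = compute_fluxes(OrganismState(t=1.0, L=0.1), const_params,
                                  stress=es)
        assert stressed.J_M_flux == pytest.approx(base.J_M_flux * 1.076)


class TestConversions:
    def test_shape_correction_example(self):
        assert volumetric_to_physical(0.12, 0.12) == pytest.approx(1.0)

    def test_zero_mass_at_zero_length(self):
        assert structural_mass(0.0, 0.25) == 0.0

    def test_rejects_negative_length(self):
        with pytest.raises(ValueError):
            physical_to_volumetric(-1.0, 0.12)

    @settings(max_examples=50, deadline=None)
    @given(L=st.floats(1e-6, 10.0), dm=st.floats(0.01, 1.0))
    def test_round_trip_identity(self, L, dm):
        back = volumetric_to_physical(physical_to_volumetric(L, dm), dm)
        assert back == pytest.approx(L, rel=1e-12)


class TestClosedForm:
    def test_starts_at_hatching_length(self, const_params):
        lag = const_params.growth_start_lag
        assert von_bertalanffy_closed_form(const_params, 1.0, lag) == \
            pytest.approx(const_params.L0_phys)

    def test_asymptote(self, const_params):
        L_inf = 0.734 * 0.094 / (0.386 * 0.12)
        assert von_bertalanffy_closed_form(const_params, 1.0, 1e4) == \
            pytest.approx(L_inf, rel=1e-9)

    def test_hand_evaluated_point(self, const_params):
        # r_B = 0.4117/d, three days after growth starts
        t = const_params.growth_start_lag + 3.0
        assert von_bertalanffy_closed_form(const_params, 1.0, t) == \
            pytest.approx(1.11749, abs=2e-4)

    def test_rejects_nonscalar_factor(self, const_params):
        with pytest.raises(ValueError):
            von_bertalanffy_closed_form(const_params, np.ones(3), 2.0)


class TestSimulate:
    def test_matches_closed_form_oracle(self, const_params, ref_profile, arr):
        traj = simulate(const_params, ref_profile, arr, t_end=25.0, dt=0.01)
        expected = von_bertalanffy_closed_form(const_params, 1.0, traj.t)
        rel = np.abs(traj.L_phys - expected) / expected
        assert np.max(rel) < 1e-3

    def test_converges_to_maximum_length(self, const_params, arr):
        prof = TemperatureProfile(mean_C=20.0)
        traj = simulate(const_params, prof, arr, t_end=60.0, dt=0.02)
        assert traj.L_phys[-1] == pytest.approx(1.4896, abs=2e-3)

    def test_zero_assimilation_never_shrinks(self, const_params, ref_profile, arr):
        p = const_params.evolve(f=0.0)
        traj = simulate(p, ref_profile, arr, t_end=10.0, dt=0.02)
        assert np.all(traj.data["L_vol_mm"] == p.L0_vol)
        assert np.all(traj.data["W_R_mg"] == 0.0)
        assert traj.starved_steps > 0

    def test_self_convergence_on_cycle(self, const_params, cyclic_16pm8, arr):
        a = simulate(const_params, cyclic_16pm8, arr, t_end=15.0, dt=0.02)
        b = simulate(const_params, cyclic_16pm8, arr, t_end=15.0, dt=0.01)
        La = a.at_days(np.arange(1, 15), "L_phys_mm")
        Lb = b.at_days(np.arange(1, 15), "L_phys_mm")
        assert np.allclose(La, Lb, rtol=2e-5)
        Ea = a.at_days(np.arange(1, 15), "eggs_cum")
        Eb = b.at_days(np.arange(1, 15), "eggs_cum")
        assert np.allclose(Ea, Eb, rtol=5e-3, atol=0.5)

    def test_monotone_state_and_size_cap(self, const_params, cyclic_16pm8, arr):
        traj = simulate(const_params, cyclic_16pm8, arr, t_end=30.0, dt=0.02)
        L = traj.data["L_vol_mm"].to_numpy()
        W = traj.data["W_R_mg"].to_numpy()
        assert np.all(np.diff(L) >= -1e-15)
        assert np.all(np.diff(W) >= -1e-15)
        assert np.all(L <= const_params.L_m_vol * (1 + 1e-9))

    def test_no_eggs_before_puberty(self, const_params, ref_profile, arr):
        traj = simulate(const_params, ref_profile, arr, t_end=21.0, dt=0.02)
        pre = traj.data["L_vol_mm"] <= const_params.L_p_vol
        assert np.all(traj.data.loc[pre, "eggs_cum"] == 0.0)

    def test_deterministic_output(self, const_params, cyclic_16pm8, arr):
        a = simulate(const_params, cyclic_16pm8, arr, t_end=10.0, dt=0.05)
        b = simulate(const_params, cyclic_16pm8, arr, t_end=10.0, dt=0.05)
        assert a.data.equals(b.data)

    def test_rejects_bad_step_settings(self, const_params, ref_profile, arr):
        with pytest.raises(ValueError):
            simulate(const_params, ref_profile, arr, t_end=0.0)


class TestCumulativeOffspring:
    def test_egg_conversion_arithmetic(self, const_params, ref_profile, arr):
        traj = simulate(const_params, ref_profile, arr, t_end=21.0, dt=0.02)
        idx = np.argmin(np.abs(traj.data["W_R_mg"].to_numpy() - 1.0e-3))
        w = traj.data["W_R_mg"].iloc[idx]
        assert traj.eggs[idx] == pytest.approx(0.95 * w / 5.67e-6, rel=1e-12)

    def test_pre_puberty_run_has_no_eggs(self, const_params, ref_profile, arr):
        traj = simulate(const_params, ref_profile, arr, t_end=2.0, dt=0.02)
        assert np.all(traj.eggs == 0.0)

    def test_doubling_egg_weight_halves_count(self, const_params, ref_profile,
                                              arr):
        traj = simulate(const_params, ref_profile, arr, t_end=21.0, dt=0.02)
        heavy = cumulative_offspring(
            traj, const_params.evolve(W_B0=2 * const_params.W_B0))
        assert np.allclose(heavy * 2.0, traj.eggs)


class TestDEBParamsValidation:
    @pytest.mark.parametrize("field, value", [
        ("kappa", 1.2), ("kappa", 0.0), ("J_Am", -0.1), ("y_VA", 1.5),
        ("W_B0", 0.0), ("L0_phys", 2.0),
    ])
    def test_invariants_rejected(self, const_params, field, value):
        with pytest.raises(ValueError):
            const_params.evolve(**{field: value})
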