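"""Toxicokinetics and the stress-to-parameter map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemadeb.deb_core import simulate
from nemadeb.environment import TemperatureProfile
from nemadeb.toxstress import (StressSpec, ToxParams, apply_stress,
                               internal_concentration_step,
                               stress_from_internal)
from nemadeb import presets


class TestInternalConcentration:
    def test_zero_exposure_stays_zero(self):
        tox = ToxParams(C_d=0.0)
        c = 0.0
        for _ in range(100):
            c = internal_concentration_step(c, tox, L_m=0.18, L_start=0.1,
                                            L_end=0.1, dt=0.01)
        assert c == 0.0

    def test_no_growth_matches_exponential_solution(self):
        # at L = L_m the surface:volume factor is 1: C_v = C_d(1 - e^-ke t)
        tox = ToxParams(C_d=40.0, k_e=10.0)
        c, dt = 0.0, 0.002
        for i in range(1, 301):
            c = internal_concentration_step(c, tox, L_m=0.18, L_start=0.18,
                                            L_end=0.18, dt=dt)
            expected = 40.0 * (1.0 - np.exp(-10.0 * i * dt))
            assert c == pytest.approx(expected, rel=1e-9)
        # 99% of C_d is reached by t ~ 0.46 d
        assert c / 40.0 > 0.99

    def test_growth_dilution_lowers_concentration(self, const_params, arr):
        prof = TemperatureProfile(mean_C=16.0)
        tox = presets.copper_tox(20.0)
        spec = presets.copper_stress_spec()
        growing = simulate(const_params, prof, arr, tox=tox, stress=spec,
                           t_end=5.0, dt=0.01)
        # comparison ODE: same surface:volume-corrected uptake, dilution
        # switched off -> C_nd = C_d (1 - exp(-int k_e L_m/L dt)).
        # Growth dilution can only lower C_v below that bound.
        L = growing.data["L_vol_mm"].to_numpy()
        rate = tox.k_e * const_params.L_m_vol / L
        A = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1])
                                             * np.diff(growing.t))])
        no_dilution = 20.0 * (1.0 - np.exp(-A))
        assert np.all(growing.data["C_v"].to_numpy()
                      <= no_dilution * (1 + 1e-6) + 1e-9)

    def test_equilibrium_after_growth_stops(self, const_params, arr):
        prof = TemperatureProfile(mean_C=20.0)
        tox = ToxParams(C_d=5.0, C_0=0.001, C_T=89.0, k_e=10.0)
        spec = StressSpec.toxicant(targets=("assimilation",))
        traj = simulate(const_params, prof, arr, tox=tox, stress=spec,
                        t_end=40.0, dt=0.02)
        assert traj.data["C_v"].iloc[-1] == pytest.approx(5.0, rel=1e-3)

    def test_fast_tk_shortcut_tracks_ode(self, const_params, arr):
        # the instantaneous-equilibrium shortcut ignores growth dilution,
        # which matters only during the early rapid-growth phase (< ~3%);
        # once growth slows the two agree to well under 1%.
        prof = TemperatureProfile(mean_C=16.0)
        tox = presets.copper_tox(40.0)
        spec = presets.copper_stress_spec()
        ode = simulate(const_params, prof, arr, tox=tox, stress=spec,
                       t_end=21.0, dt=0.02)
        fast = simulate(const_params, prof, arr, tox=tox, stress=spec,
                        t_end=21.0, dt=0.02, fast_tk=True)
        days = np.arange(1, 22)
        assert np.allclose(ode.at_days(days, "L_phys_mm"),
                           fast.at_days(days, "L_phys_mm"), rtol=0.03)
        late = np.arange(10, 22)
        assert np.allclose(ode.at_days(late, "L_phys_mm"),
                           fast.at_days(late, "L_phys_mm"), rtol=0.01)

    def test_rejects_bad_step(self):
        with pytest.raises(ValueError):
            internal_concentration_step(0.0, ToxParams(C_d=1.0), 0.18, 0.1,
                                        0.1, dt=0.0)


class TestStressFromInternal:
    def test_below_threshold_is_zero(self):
        tox = ToxParams(C_d=0.0, C_0=1.0, C_T=89.0)
        assert stress_from_internal(0.5, tox) == 0.0

    def test_linear_above_threshold(self):
        tox = ToxParams(C_d=0.0, C_0=0.0, C_T=89.0)
        assert stress_from_internal(44.5, tox) == pytest.approx(0.5)
        assert stress_from_internal(89.0, tox) == pytest.approx(1.0)

    def test_full_stress_shuts_down_assimilation(self):
        tox = ToxParams(C_d=0.0, C_0=0.0, C_T=89.0)
        s = stress_from_internal(89.0, tox)
        es = apply_stress(StressSpec.toxicant(targets=("assimilation",)), s)
        assert es.assimilation == 0.0

    def test_monotone_in_external_concentration(self, const_params, arr):
        # monotone dose -> monotone internal dose -> monotone stress,
        # checked across the experimental copper series
        prof = TemperatureProfile(mean_C=16.0)
        spec = presets.copper_stress_spec()
        days = np.arange(1, 21)
        prev = None
        for cd in (0.0, 1.0, 3.0, 8.0, 20.0, 40.0):
            tox = presets.copper_tox(cd)
            traj = simulate(const_params, prof, arr,
                            tox=tox if cd > 0 else None,
                            stress=spec if cd > 0 else None,
                            t_end=21.0, dt=0.02)
            scu = traj.at_days(days, "s_cu")
            if prev is not None:
                assert np.all(scu >= prev - 1e-12)
            prev = scu


class TestApplyStress:
    def test_identity_at_zero(self):
        es = apply_stress(StressSpec.constant(0.0, targets=("maintenance",)), 0.0)
        assert es == apply_stress(
            StressSpec.constant(0.0, targets=("assimilation",)), 0.0)
        assert es.maintenance == 1.0 and es.assimilation == 1.0

    def test_maintenance_stress_value(self):
        es = apply_stress(
            StressSpec.constant(0.076, targets=("maintenance",)), 0.076)
        assert es.maintenance == pytest.approx(1.076)

    def test_assimilation_clamp(self):
        spec = StressSpec.toxicant(targets=("assimilation",))
        assert apply_stress(spec, 0.5).assimilation == pytest.approx(0.5)
        clamped = apply_stress(spec, 1.2)
        assert clamped.assimilation == 0.0 and clamped.clamped

    @pytest.mark.parametrize("direction, s, expected", [
        ("decrease", 0.3, 0.7),
        ("increase", 0.3, 1.3),
    ])
    def test_puberty_length_direction(self, direction, s, expected):
        spec = StressSpec(mode="toxicant",
                          targets=frozenset({"length_at_puberty"}),
                          lp_direction=direction)
        assert apply_stress(spec, s).length_at_puberty == pytest.approx(expected)

    @settings(max_examples=40, deadline=None)
    @given(s=st.floats(0.0, 0.99))
    def test_continuity_and_bounds(self, s):
        spec = StressSpec.toxicant(targets=("assimilation", "maintenance",
                                            "growth_cost", "repro_cost",
                                            "length_at_puberty"))
        es = apply_stress(spec, s)
        es2 = apply_stress(spec, s + 1e-9)
        assert 0.0 <= es.assimilation <= 1.0
        assert es.maintenance >= 1.0
        assert es.growth_cost <= 1.0 and es.repro_cost <= 1.0
        assert es.length_at_puberty > 0.0
        for fld in ("assimilation", "maintenance", "growth_cost",
                    "repro_cost", "length_at_puberty"):
            assert abs(getattr(es2, fld) - getattr(es, fld)) < 1e-6

    def test_rejects_unknown_target(self):
        with pytest.raises(ValueError):
            StressSpec.constant(0.1, targets=("metabolic_rate",))

    def test_rejects_negative_level(self):
        spec = StressSpec.constant(0.1, targets=("maintenance",))
        with pytest.raises(ValueError):
            apply_stress(spec, -0.1)
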