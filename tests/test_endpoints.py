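"""Log-logistic endpoint models, TFE, and trait extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from nemadeb.endpoints import (LogLogistic3, extract_traits, fit_dose_response,
                               fit_time_course, loglogistic3, tfe_from_fit)
from nemadeb.synthetic_data import ObservationSet


class TestLogLogistic3:
    def test_half_maximum_at_inflection(self):
        for b in (-5.0, -1.0, 2.0, 7.0):
            assert loglogistic3(10.0, 200.0, b, 10.0) == pytest.approx(100.0)

    def test_hand_evaluated_point(self):
        assert loglogistic3(20.0, 200.0, -5.0, 10.0) == \
            pytest.approx(193.9394, abs=1e-3)

    def test_limits_at_zero_dose(self):
        assert loglogistic3(0.0, 2.0, 1.5, 40.0) == pytest.approx(2.0)
        assert loglogistic3(0.0, 200.0, -4.0, 6.0) == pytest.approx(0.0)

    def test_decreasing_curve_vanishes_at_high_dose(self):
        assert loglogistic3(1e9, 2.0, 1.5, 40.0) < 1e-6


class TestTimeCourseFit:
    def test_noiseless_recovery(self):
        days = np.arange(1.0, 22.0)
        y = loglogistic3(days, 230.0, -4.0, 6.0)
        fit = fit_time_course(days, y)
        assert fit.d == pytest.approx(230.0, abs=1e-3)
        assert fit.b == pytest.approx(-4.0, abs=1e-3)
        assert fit.e == pytest.approx(6.0, abs=1e-3)

    def test_recovery_under_five_percent_noise(self):
        rng = np.random.default_rng(42)
        days = np.arange(1.0, 22.0)
        truth = loglogistic3(days, 230.0, -4.0, 6.0)
        hits = 0
        for _ in range(30):
            y = truth * (1.0 + rng.normal(0, 0.05, size=truth.shape))
            fit = fit_time_course(days, np.maximum(y, 0.0))
            if (abs(fit.d - 230.0) < 2 * fit.d_se + 1e-9
                    and abs(fit.e - 6.0) < 2 * fit.e_se + 1e-9):
                hits += 1
        assert hits >= 24  # ~2 SE coverage most of the time

    def test_constant_zero_series_rejected(self):
        with pytest.raises(ValueError):
            fit_time_course(np.arange(1.0, 10.0), np.zeros(9))

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            fit_time_course([1, 2, 3], [0, 1, 2])


class TestTFE:
    def test_equals_inflection_when_d_is_two(self):
        fit = LogLogistic3(d=2.0, b=-3.0, e=5.0)
        assert tfe_from_fit(fit) == pytest.approx(5.0)

    def test_closed_form_hand_value(self):
        fit = LogLogistic3(d=200.0, b=-5.0, e=10.0)
        assert tfe_from_fit(fit) == pytest.approx(3.4692, abs=1e-3)

    def test_matches_numeric_root(self):
        # solving y(x) = 1 numerically must agree with the closed form
        for d, b, e in [(230.0, -4.0, 6.0), (50.0, -2.5, 4.0),
                        (200.0, -5.0, 10.0)]:
            fit = LogLogistic3(d=d, b=b, e=e)
            root = brentq(lambda x: loglogistic3(x, d, b, e) - 1.0,
                          1e-9, e * 10, xtol=1e-14)
            assert abs(tfe_from_fit(fit) - root) < 1e-10

    def test_precedes_inflection_for_large_broods(self):
        for d in (3.0, 50.0, 400.0):
            fit = LogLogistic3(d=d, b=-4.0, e=6.0)
            assert tfe_from_fit(fit) < 6.0

    def test_time_shift_equivariance(self):
        # shifting the curve later shifts TFE by the same factor of e
        base = LogLogistic3(d=230.0, b=-4.0, e=6.0)
        shifted = LogLogistic3(d=230.0, b=-4.0, e=9.0)
        assert tfe_from_fit(shifted) / tfe_from_fit(base) == pytest.approx(1.5)

    def test_undefined_below_one_egg(self):
        with pytest.raises(ValueError):
            tfe_from_fit(LogLogistic3(d=0.8, b=-4.0, e=6.0))


class TestDoseResponseFit:
    CONC = np.array([0.0, 1.0, 3.0, 8.0, 20.0, 40.0])

    def test_noiseless_recovery_of_pgr_shaped_curve(self):
        y = loglogistic3(self.CONC, 2.10, 1.59, 41.5)
        fit = fit_dose_response(self.CONC, y)
        assert fit.d == pytest.approx(2.10, abs=1e-4)
        assert fit.b == pytest.approx(1.59, abs=1e-3)
        assert fit.e == pytest.approx(41.5, abs=1e-2)

    def test_ec50_invariant_to_endpoint_units(self):
        y = loglogistic3(self.CONC, 230.0, 1.8, 30.0)
        f1 = fit_dose_response(self.CONC, y)
        f2 = fit_dose_response(self.CONC, y / 230.0)
        assert f1.e == pytest.approx(f2.e, rel=1e-6)

    def test_flat_response_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response(self.CONC, np.full(6, 3.3))

    def test_hormetic_points_can_be_excluded(self):
        y = loglogistic3(self.CONC, 230.0, 1.8, 30.0)
        y[1:3] *= 1.15  # low-dose stimulation
        fit = fit_dose_response(self.CONC, y, exclude=(1.0, 3.0))
        assert fit.e == pytest.approx(30.0, rel=1e-4)


class TestExtractTraits:
    @staticmethod
    def _obs_from_counts(counts, death_day):
        rows = [("w0", "t", d, c, np.nan, d != death_day)
                for d, c in enumerate(counts, start=1)]
        df = pd.DataFrame(rows, columns=["individual_id", "treatment_id",
                                         "day", "eggs", "length_mm", "alive"])
        return ObservationSet(data=df)

    def test_brood_and_lifespan_arithmetic(self):
        counts = [0, 5, 10, 3, 0] + [0] * 15
        obs = self._obs_from_counts(counts, death_day=20)
        tt = extract_traits(obs)
        assert tt.individuals["brood"].iloc[0] == 18
        assert tt.individuals["lifespan_d"].iloc[0] == 20

    def test_empty_individual_is_error_free(self):
        obs = self._obs_from_counts([0, 0, 0, 0], death_day=4)
        tt = extract_traits(obs)
        assert tt.individuals["brood"].iloc[0] == 0
        assert np.isnan(tt.treatments["tfe_d"].iloc[0])

    def test_zero_noise_round_trip(self, noiseless_cohort):
        # traits computed from the records must equal the generator's
        # ground truth exactly when all noise channels are off
        tt = extract_traits(noiseless_cohort)
        truth = noiseless_cohort.truth.set_index("individual_id")
        got = tt.individuals.set_index("individual_id")
        for ind in truth.index:
            assert got.loc[ind, "brood"] == truth.loc[ind, "brood"]
            assert got.loc[ind, "lifespan_d"] == truth.loc[ind, "lifespan_d"]
            assert got.loc[ind, "max_length_mm"] == pytest.approx(
                truth.loc[ind, "max_length_mm"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            extract_traits(ObservationSet(data=pd.DataFrame(
                columns=["individual_id", "treatment_id", "day", "eggs",
                         "length_mm", "alive"])))
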