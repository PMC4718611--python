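"""Shared fixtures: reference parameter sets and small synthetic cohorts.

Cohort fixtures are generated once per session; all randomness is
explicitly seeded so the suite is reproducible run to run.
"""

import pytest
from hypothesis import settings

from nemadeb import presets

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")
from nemadeb.environment import TemperatureProfile
from nemadeb.synthetic_data import CohortDesign, NoiseModel, Treatment, generate


@pytest.fixture(scope="session")
def const_params():
    return presets.params_constant_temperature()


@pytest.fixture(scope="session")
def arr():
    return presets.arrhenius()


@pytest.fixture(scope="session")
def ref_profile():
    """Constant profile at the reference temperature (F_T = 1)."""
    return TemperatureProfile(mean_C=presets.T_REF_STUDY - 273.15)


@pytest.fixture(scope="session")
def cyclic_16pm8():
    return TemperatureProfile(mean_C=16.0, amplitude_C=8.0)


@pytest.fixture(scope="session")
def constant_temp_cohort(const_params, arr):
    """Noisy cohorts at the four constant temperatures used in the joint fit."""
    design = CohortDesign(treatments=tuple(
        Treatment(label=f"{T}C", profile=TemperatureProfile(float(T)), n=12)
        for T in (12, 16, 20, 24)), horizon=21.0)
    return generate(design, const_params, arr, noise=NoiseModel(), seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort(const_params, arr):
    """A deterministic single-treatment cohort at 16 degC."""
    design = CohortDesign(treatments=(
        Treatment(label="16C", profile=TemperatureProfile(16.0), n=3),),
        horizon=21.0)
    return generate(design, const_params, arr, noise=NoiseModel.none(), seed=0)
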