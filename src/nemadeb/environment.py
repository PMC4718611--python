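"""Temperature forcing for energy-budget simulations.

Two profile shapes cover the experimental regimes: constant temperature,
and a trapezoidal diurnal cycle in which temperature ramps between a
night-time minimum plateau (centred on 00:00) and a daytime maximum
plateau (centred on 12:00) at a fixed ramp rate (default 4 degC / h).
Metabolic rate fluxes are scaled by the Arrhenius temperature factor

    F_T = exp(T_A / T_ref - T_A / T_a)

where ``T_A`` is the Arrhenius temperature (activation energy over the gas
constant, in K), ``T_ref`` the reference temperature at which rate
parameters are defined, and ``T_a`` the ambient absolute temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TemperatureProfile",
    "ArrheniusParams",
    "temp_at",
    "arrhenius_factor",
    "factor_series",
]

KELVIN_OFFSET = 273.15

#: Range of Arrhenius temperatures considered typical for ectotherms (K).
TYPICAL_TA_RANGE = (5000.0, 13000.0)


@dataclass(frozen=True)
class TemperatureProfile:
    """Constant or trapezoidal diurnal temperature regime.

    Parameters
    ----------
    mean_C:
        Daily mean temperature (degC).  For a cyclic profile the minimum is
        ``mean_C - amplitude_C`` and the maximum ``mean_C + amplitude_C``.
    amplitude_C:
        Half-range of the cycle (degC); 0 gives a constant profile.
    ramp_rate:
        Rate of temperature change during the ramps (degC per hour).
    start_clock_h:
        Clock time (h) that simulation time ``t = 0`` corresponds to.  The
        minimum plateau is centred on clock 00:00 and the maximum plateau
        on 12:00, so the default starts a run at the nightly minimum.
    """

    mean_C: float
    amplitude_C: float = 0.0
    ramp_rate: float = 4.0
    start_clock_h: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_C):
            raise ValueError("mean_C must be finite")
        if self.amplitude_C < 0:
            raise ValueError("amplitude_C must be >= 0")
        if self.amplitude_C > 0:
            if self.ramp_rate <= 0:
                raise ValueError("ramp_rate must be > 0 for a cyclic profile")
            if 2.0 * self.ramp_hours >= 24.0:
                raise ValueError(
                    "ramps do not fit in a day: need 2 * (2*amplitude/ramp_rate) < 24 h"
                )

    @property
    def kind(self) -> str:
        return "constant" if self.amplitude_C == 0 else "cyclic"

    @property
    def ramp_hours(self) -> float:
        """Duration of one ramp (h): full swing of 2*amplitude at ramp_rate."""
        if self.amplitude_C == 0:
            return 0.0
        return 2.0 * self.amplitude_C / self.ramp_rate

    @property
    def min_C(self) -> float:
        return self.mean_C - self.amplitude_C

    @property
    def max_C(self) -> float:
        return self.mean_C + self.amplitude_C

    def label(self) -> str:
        if self.kind == "constant":
            return f"{self.mean_C:g}C"
        return f"{self.mean_C:g}pm{self.amplitude_C:g}C"


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius temperature and reference temperature (both K).

    ``T_A`` values outside the typical ectotherm range (5000-13000 K)
    trigger a warning but are accepted.
    """

    T_A: float
    T_ref: float = 293.15

    def __post_init__(self) -> None:
        if self.T_A <= 0:
            raise ValueError("T_A must be > 0")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be > 0")
        lo, hi = TYPICAL_TA_RANGE
        if not lo <= self.T_A <= hi:
            warnings.warn(
                f"T_A = {self.T_A:g} K is outside the typical range "
                f"[{lo:g}, {hi:g}] K",
                stacklevel=3,
            )


def temp_at(profile: TemperatureProfile, t):
    """Temperature (degC) at time ``t`` (days since simulation start).

    The cyclic profile is 24 h periodic and piecewise linear: a minimum
    plateau centred on clock 00:00, a linear up-ramp, a maximum plateau
    centred on 12:00 and a symmetric down-ramp.  Plateaus have equal
    length, so the daily mean equals ``mean_C``.
    """
    t = np.asarray(t, dtype=float)
    if profile.kind == "constant":
        out = np.full(t.shape, profile.mean_C)
        return out if out.ndim else float(out)

    clock = (profile.start_clock_h + 24.0 * t) % 24.0
    ramp = profile.ramp_hours
    plateau = 12.0 - ramp  # length of each plateau (h)
    half_p = plateau / 2.0

    # Piecewise segments over one clock day; min plateau wraps around 0.
    out = np.empty(clock.shape, dtype=float)
    lo, hi, rate = profile.min_C, profile.max_C, profile.ramp_rate

    in_min = (clock < half_p) | (clock >= 24.0 - half_p)
    in_up = (clock >= half_p) & (clock < half_p + ramp)
    in_max = (clock >= half_p + ramp) & (clock < half_p + ramp + plateau)
    in_down = ~(in_min | in_up | in_max)

    out[in_min] = lo
    out[in_up] = lo + rate * (clock[in_up] - half_p)
    out[in_max] = hi
    out[in_down] = hi - rate * (clock[in_down] - (12.0 + half_p))
    return out if out.ndim else float(out)


def arrhenius_factor(arr: ArrheniusParams, T_a):
    """Temperature factor F_T = exp(T_A/T_ref - T_A/T_a) for T_a in K."""
    T_a = np.asarray(T_a, dtype=float)
    if np.any(T_a <= 0):
        raise ValueError("absolute temperature T_a must be > 0")
    out = np.exp(arr.T_A / arr.T_ref - arr.T_A / T_a)
    return out if out.ndim else float(out)


def factor_series(profile: TemperatureProfile, arr: ArrheniusParams, grid):
    """Elementwise F_T along a sorted time grid (days).

    Convenience wrapper used to pre-compute the forcing for the fixed-step
    integrator; temperatures are converted to K with +273.15.
    """
    grid = np.asarray(grid, dtype=float)
    return arrhenius_factor(arr, temp_at(profile, grid) + KELVIN_OFFSET)
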