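"""Forward simulation of the DEBkiss energy budget.

DEBkiss is a reserve-less dynamic energy budget: assimilation scales with
structural surface area, a fixed fraction ``kappa`` of it is committed to
the soma (somatic maintenance first, the remainder to growth at yield
``y_VA``), and the complement ``1 - kappa`` flows into a reproduction
buffer once structural length exceeds the length at puberty.  State
equations (dry-weight fluxes, volumetric length ``L``):

    J_A = f * J_Am * F_T * L^2
    J_M = J_Mv * F_T * L^3
    J_V = y_VA * (kappa * J_A - J_M)
    J_R = (1 - kappa) * J_A          for L > L_p, else 0

    dW_V/dt = J_V,   W_V = d_V L^3
    dW_R/dt = J_R,   eggs(t) = y_BA W_R(t) / W_B0

The temperature factor ``F_T`` multiplies the two rate fluxes (J_A, J_M).
Under constant conditions the length trajectory is the von Bertalanffy
curve, which doubles as an analytic oracle for the integrator.

All fluxes operate on volumetric length; measured (physical) length
relates to it through the shape correction, ``L_W = L / delta_M``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernel
from .environment import ArrheniusParams, TemperatureProfile, factor_series, temp_at
from .toxstress import EffectiveStress, StressSpec, ToxParams

__all__ = [
    "DEBParams",
    "OrganismState",
    "FluxSet",
    "Trajectory",
    "compute_fluxes",
    "simulate",
    "cumulative_offspring",
    "von_bertalanffy_closed_form",
    "physical_to_volumetric",
    "volumetric_to_physical",
    "structural_mass",
]

DEFAULT_DT = 0.01


@dataclass(frozen=True)
class DEBParams:
    """DEBkiss parameter set.

    Rates are defined at the reference temperature of the accompanying
    Arrhenius parameters.  Lengths at the interface (``L_p_phys``,
    ``L0_phys``) are physical mm; internally all state is volumetric.

    kappa : allocation fraction to soma (-)
    J_Am : specific maximum assimilation rate (mg dw mm^-2 d^-1)
    J_M : specific somatic maintenance rate (mg dw mm^-3 d^-1)
    L_p_phys : physical length at puberty (mm)
    W_B0 : dry weight of a single egg (mg)
    y_VA, y_BA : yields of structure / egg buffer on assimilates (mg/mg)
    f : scaled functional response (-, food ad libitum = 1)
    L0_phys : physical length at hatching (mm)
    d_V : dry-weight density of structure (mg mm^-3)
    delta_M : shape-correction coefficient (-)
    growth_start_lag : days after hatching before growth/feeding begin
    """

    kappa: float
    J_Am: float
    J_M: float
    L_p_phys: float
    W_B0: float
    y_VA: float = 0.80
    y_BA: float = 0.95
    f: float = 1.0
    L0_phys: float = 0.21
    d_V: float = 0.25
    delta_M: float = 0.12
    growth_start_lag: float = 1.0

    def __post_init__(self) -> None:
        vals = [self.kappa, self.J_Am, self.J_M, self.L_p_phys, self.W_B0,
                self.y_VA, self.y_BA, self.f, self.L0_phys, self.d_V,
                self.delta_M, self.growth_start_lag]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all DEB parameters must be finite")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError("kappa must lie in (0, 1)")
        for name in ("J_Am", "J_M", "L_p_phys", "W_B0", "d_V", "delta_M",
                     "L0_phys"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.y_VA <= 1.0:
            raise ValueError("y_VA must lie in (0, 1]")
        if not 0.0 < self.y_BA <= 1.0:
            raise ValueError("y_BA must lie in (0, 1]")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        if self.growth_start_lag < 0:
            raise ValueError("growth_start_lag must be >= 0")
        if self.L0_phys >= self.L_p_phys:
            raise ValueError("length at hatching must be below length at puberty")

    # -- derived quantities ------------------------------------------------
    @property
    def L0_vol(self) -> float:
        return self.L0_phys * self.delta_M

    @property
    def L_p_vol(self) -> float:
        return self.L_p_phys * self.delta_M

    @property
    def L_m_vol(self) -> float:
        """Maximum volumetric size of the control, kappa*J_Am/J_M."""
        return self.kappa * self.J_Am / self.J_M

    @property
    def L_m_phys(self) -> float:
        return self.L_m_vol / self.delta_M

    def r_B(self, F_T: float = 1.0) -> float:
        """Von Bertalanffy rate constant y_VA*J_M*F_T/(3*d_V) (1/d)."""
        return self.y_VA * self.J_M * F_T / (3.0 * self.d_V)

    def evolve(self, **changes) -> "DEBParams":
        return replace(self, **changes)


@dataclass
class OrganismState:
    """Instantaneous state: volumetric length, buffers, internal dose."""

    t: float
    L: float
    W_R: float = 0.0
    C_v: float = 0.0
    alive: bool = True


@dataclass(frozen=True)
class FluxSet:
    """The four dry-weight fluxes (mg/d) at one state."""

    J_A: float
    J_M_flux: float
    J_V: float
    J_R: float
    starved: bool = False


# -- conversions -----------------------------------------------------------

def physical_to_volumetric(L_phys, delta_M: float):
    """Measured length (mm) to volumetric structural length, L = L_W * delta_M."""
    L_phys = np.asarray(L_phys, dtype=float)
    if np.any(L_phys < 0) or delta_M <= 0:
        raise ValueError("lengths must be >= 0 and delta_M > 0")
    out = L_phys * delta_M
    return out if out.ndim else float(out)


def volumetric_to_physical(L_vol, delta_M: float):
    """Volumetric structural length to measured length, L_W = L / delta_M."""
    L_vol = np.asarray(L_vol, dtype=float)
    if np.any(L_vol < 0) or delta_M <= 0:
        raise ValueError("lengths must be >= 0 and delta_M > 0")
    out = L_vol / delta_M
    return out if out.ndim else float(out)


def structural_mass(L_vol, d_V: float):
    """Structural dry weight W_V = d_V * L^3 (mg)."""
    L_vol = np.asarray(L_vol, dtype=float)
    if np.any(L_vol < 0) or d_V <= 0:
        raise ValueError("lengths must be >= 0 and d_V > 0")
    out = d_V * L_vol**3
    return out if out.ndim else float(out)


# -- fluxes ---------------------------------------------------------------

def compute_fluxes(state: OrganismState, params: DEBParams,
                   F_T: float = 1.0,
                   stress: Optional[EffectiveStress] = None) -> FluxSet:
    """Evaluate the four fluxes at a state.

    ``stress`` supplies effective multipliers (identity when omitted).
    Maintenance has priority: when ``kappa*J_A < J_M`` growth is clamped
    at zero and the residual deficit is paid from the reproduction flux
    (floored at 0); structure never shrinks.
    """
    if not (np.isfinite(state.L) and np.isfinite(state.W_R)):
        raise ValueError("non-finite organism state")
    if not np.isfinite(F_T) or F_T <= 0:
        raise ValueError("temperature factor F_T must be finite and > 0")
    es = stress or EffectiveStress()
    JAm_e = params.J_Am * es.assimilation
    JM_e = params.J_M * es.maintenance
    yVA_e = params.y_VA * es.growth_cost
    Lp_e = params.L_p_vol * es.length_at_puberty

    L = state.L
    J_A = params.f * JAm_e * F_T * L**2
    J_M_flux = JM_e * F_T * L**3
    net = params.kappa * J_A - J_M_flux
    if net >= 0:
        J_V, deficit = yVA_e * net, 0.0
    else:
        J_V, deficit = 0.0, -net
    if L > Lp_e:
        J_R = max(0.0, (1.0 - params.kappa) * J_A - deficit)
    else:
        J_R = 0.0
    return FluxSet(J_A=J_A, J_M_flux=J_M_flux, J_V=J_V, J_R=J_R,
                   starved=deficit > 0)


# -- trajectory container --------------------------------------------------

@dataclass
class Trajectory:
    """Output of :func:`simulate`: a tidy frame plus run metadata.

    ``data`` columns: t_days, temp_C, F_T, L_vol_mm, L_phys_mm, W_R_mg,
    C_v, s_cu, eggs_cum.
    """

    data: pd.DataFrame
    params: DEBParams
    profile: TemperatureProfile
    arr: ArrheniusParams
    dt: float
    starved_steps: int = 0

    @property
    def t(self) -> np.ndarray:
        return self.data["t_days"].to_numpy()

    @property
    def L_phys(self) -> np.ndarray:
        return self.data["L_phys_mm"].to_numpy()

    @property
    def eggs(self) -> np.ndarray:
        return self.data["eggs_cum"].to_numpy()

    def at_days(self, days, column: str) -> np.ndarray:
        """Values of a column at the given times (nearest grid point)."""
        idx = np.rint(np.asarray(days, dtype=float) / self.dt).astype(int)
        idx = np.clip(idx, 0, len(self.data) - 1)
        return self.data[column].to_numpy()[idx]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.8g")


def _split_stress(stress):
    """Normalize the stress argument into one constant + one toxicant channel."""
    if stress is None:
        specs = []
    elif isinstance(stress, StressSpec):
        specs = [stress]
    else:
        specs = list(stress)
    const = [s for s in specs if s.mode == "constant"]
    tox = [s for s in specs if s.mode == "toxicant"]
    if len(const) > 1 or len(tox) > 1:
        raise ValueError("at most one constant and one toxicant stress channel")
    return (const[0] if const else None), (tox[0] if tox else None)


def simulate(params: DEBParams,
             profile: TemperatureProfile,
             arr: Optional[ArrheniusParams] = None,
             tox: Optional[ToxParams] = None,
             stress: Union[StressSpec, Sequence[StressSpec], None] = None,
             t_end: float = 21.0,
             dt: float = DEFAULT_DT,
             fast_tk: bool = False) -> Trajectory:
    """Integrate the energy budget from hatching to ``t_end`` (days).

    The organism starts at the hatching length with empty buffers;
    feeding and growth begin after ``params.growth_start_lag``.  A
    fixed-step RK4 scheme advances length and the reproduction buffer;
    the internal-concentration equation is advanced by an exact
    exponential/dilution splitting, which keeps the fast elimination
    dynamics stable at the growth step size.  ``fast_tk`` replaces the
    toxicokinetic update with its instantaneous-equilibrium limit
    (C_v = C_d).

    When a stress argument carries both a constant and a toxicant channel
    (the mixed-stressor prediction), multipliers targeting the same
    parameter combine multiplicatively.

    Deterministic for fixed inputs; raises on invalid step settings and
    flags (rather than raises on) maintenance-deficit steps via
    ``Trajectory.starved_steps``.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be > 0")
    if arr is None:
        arr = ArrheniusParams(T_A=9109.0)
    const_spec, tox_spec = _split_stress(stress)
    if tox_spec is not None and tox is None:
        raise ValueError("toxicant stress requires ToxParams")
    tox_on = tox is not None and tox_spec is not None

    n_steps = int(np.ceil(t_end / dt - 1e-9))
    half_grid = np.arange(2 * n_steps + 1) * (dt / 2.0)
    ft_half = np.asarray(factor_series(profile, arr, half_grid), dtype=float)
    if not np.all(np.isfinite(ft_half)):
        raise FloatingPointError("non-finite temperature factor on the grid")

    false_mask = np.zeros(5, dtype=np.bool_)
    cmask = const_spec.target_mask() if const_spec else false_mask
    tmask = tox_spec.target_mask() if tox_spec else false_mask
    out = np.empty((n_steps + 1, 4), dtype=float)

    n_starved = _kernel.integrate(
        n_steps, dt, params.growth_start_lag,
        params.f, params.J_Am, params.J_M, params.kappa, params.y_VA,
        params.d_V, params.L0_vol, params.L_p_vol,
        ft_half,
        const_spec.s_value if const_spec else 0.0,
        cmask, bool(const_spec and const_spec.lp_direction == "decrease"),
        tox_on, bool(fast_tk),
        tox.C_d if tox_on else 0.0,
        tox.C_0 if tox_on else 0.0,
        tox.C_T if tox_on else 1.0,
        tox.k_e if tox_on else 0.0,
        params.L_m_vol,
        tmask, bool(tox_spec and tox_spec.lp_direction == "decrease"),
        out,
    )
    if not np.all(np.isfinite(out)):
        bad = np.where(~np.isfinite(out).all(axis=1))[0]
        t_fail = bad[0] * dt if len(bad) else float("nan")
        raise FloatingPointError(f"integration failed near t = {t_fail:.3f} d")

    t = np.arange(n_steps + 1) * dt
    L_vol = out[:, 0]
    W_R = out[:, 1]
    s_cu = out[:, 3]

    # egg-buffer conversion, honouring any reproduction-cost stress
    y_BA_eff = np.full_like(t, params.y_BA)
    if const_spec and "repro_cost" in const_spec.targets:
        y_BA_eff = y_BA_eff / (1.0 + const_spec.s_value)
    if tox_spec and "repro_cost" in tox_spec.targets:
        y_BA_eff = y_BA_eff / (1.0 + s_cu)
    eggs = y_BA_eff * W_R / params.W_B0

    data = pd.DataFrame({
        "t_days": t,
        "temp_C": np.asarray(temp_at(profile, t), dtype=float),
        "F_T": ft_half[::2],
        "L_vol_mm": L_vol,
        "L_phys_mm": L_vol / params.delta_M,
        "W_R_mg": W_R,
        "C_v": out[:, 2],
        "s_cu": s_cu,
        "eggs_cum": eggs,
    })
    return Trajectory(data=data, params=params, profile=profile, arr=arr,
                      dt=dt, starved_steps=int(n_starved))


def cumulative_offspring(trajectory: Trajectory, params: Optional[DEBParams] = None
                         ) -> np.ndarray:
    """Continuous egg count over time, eggs(t) = y_BA * W_R(t) / W_B0.

    Uses the conversion stored on the trajectory (which already reflects
    any reproduction-cost stress); passing ``params`` overrides the egg
    weight and yield, e.g. for sensitivity checks.
    """
    if params is None:
        return trajectory.eggs.copy()
    if params.W_B0 <= 0:
        raise ValueError("W_B0 must be > 0")
    return params.y_BA * trajectory.data["W_R_mg"].to_numpy() / params.W_B0


def von_bertalanffy_closed_form(params: DEBParams, F_T: float, t) -> np.ndarray:
    """Analytic physical-length curve for a constant environment, no stress.

    L_W(t) = L_inf - (L_inf - L0) * exp(-r_B * (t - lag)) for t >= lag,
    with L_inf = f*kappa*J_Am/(J_M*delta_M) and r_B = y_VA*J_M*F_T/(3*d_V).
    This is the exact solution of the growth equation and serves as the
    oracle for the numerical integrator.
    """
    F_T_arr = np.asarray(F_T, dtype=float)
    if F_T_arr.ndim != 0:
        raise ValueError("closed form requires a constant (scalar) F_T")
    if F_T_arr <= 0:
        raise ValueError("F_T must be > 0")
    t = np.asarray(t, dtype=float)
    L_inf = params.f * params.kappa * params.J_Am / (params.J_M * params.delta_M)
    r_B = params.r_B(float(F_T_arr))
    tt = np.maximum(t - params.growth_start_lag, 0.0)
    out = L_inf - (L_inf - params.L0_phys) * np.exp(-r_B * tt)
    return out if out.ndim else float(out)
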