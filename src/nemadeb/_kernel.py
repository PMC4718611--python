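"""Fixed-step RK4 integration kernel for the energy-budget state equations.

Kept free of Python objects so it can be jit-compiled with numba when
available; the pure-Python path runs the identical code.  All lengths in
the kernel are volumetric (mm), masses mg dry weight, time in days.

Stress channels: a constant-level channel and a toxicant-driven channel
(level ``s_Cu`` derived from the internal concentration each step).  When
both channels target the same parameter their multipliers combine
multiplicatively.  Channel masks index the targets in the order
assimilation, maintenance, growth cost, reproduction cost, length at
puberty; the reproduction-cost channel does not enter the state equations
(it acts on the egg-buffer conversion) and is applied by the caller.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap

_LP_FLOOR = 1e-3


@njit(cache=False)
def _deriv(L, ft, f, JAm_e, JM_e, kappa, yVA_e, dV, Lp_e):
    """Time derivatives (dL/dt, dW_R/dt) and a starvation flag at one state.

    Maintenance has priority: if kappa*J_A cannot cover it, growth stops
    (no shrinking) and the deficit is paid from the reproduction flux,
    floored at zero.
    """
    L2 = L * L
    JA = f * JAm_e * ft * L2
    JMf = JM_e * ft * L2 * L
    net = kappa * JA - JMf
    if net >= 0.0:
        JV = yVA_e * net
        deficit = 0.0
    else:
        JV = 0.0
        deficit = -net
    if L > Lp_e:
        JR = (1.0 - kappa) * JA - deficit
        if JR < 0.0:
            JR = 0.0
    else:
        JR = 0.0
    dL = JV / (3.0 * dV * L2) if L2 > 0.0 else 0.0
    starved = deficit > 0.0
    return dL, JR, starved


@njit(cache=False)
def integrate(n_steps, dt, lag,
              f, JAm, JM, kappa, yVA, dV, L0_vol, Lp_vol,
              ft_half,
              s_const, cmask, c_lp_dec,
              tox_on, fast_tk, Cd, C0, CT, ke, Lm_vol,
              tmask, t_lp_dec,
              out):
    """March the state (L, W_R, C_v) over ``n_steps`` steps of size ``dt``.

    ``ft_half`` holds the temperature factor on the half-step grid
    (length ``2*n_steps + 1``).  ``out`` is filled with columns
    (L, W_R, C_v, s_Cu) at each grid point; the return value counts steps
    on which the maintenance deficit rule was active.
    """
    # constant-channel multipliers (hoisted: they never change)
    cm_a = 1.0
    cm_m = 1.0
    cm_g = 1.0
    cm_lp = 1.0
    if cmask[0]:
        cm_a = max(0.0, 1.0 - s_const)
    if cmask[1]:
        cm_m = 1.0 + s_const
    if cmask[2]:
        cm_g = 1.0 / (1.0 + s_const)
    if cmask[4]:
        if c_lp_dec:
            cm_lp = max(_LP_FLOOR, 1.0 - s_const)
        else:
            cm_lp = 1.0 + s_const

    L = L0_vol
    WR = 0.0
    Cv = 0.0
    n_starved = 0

    out[0, 0] = L
    out[0, 1] = WR
    out[0, 2] = Cv
    out[0, 3] = 0.0

    for i in range(n_steps):
        t1 = (i + 1) * dt

        scu = 0.0
        if tox_on:
            if fast_tk:
                Cv = Cd
            scu = max(0.0, Cv - C0) / CT

        # toxicant-channel multipliers at the step's stress level
        JAm_e = JAm * cm_a
        JM_e = JM * cm_m
        yVA_e = yVA * cm_g
        Lp_e = Lp_vol * cm_lp
        if tox_on:
            if tmask[0]:
                JAm_e *= max(0.0, 1.0 - scu)
            if tmask[1]:
                JM_e *= 1.0 + scu
            if tmask[2]:
                yVA_e /= 1.0 + scu
            if tmask[4]:
                if t_lp_dec:
                    Lp_e *= max(_LP_FLOOR, 1.0 - scu)
                else:
                    Lp_e *= 1.0 + scu

        L_new = L
        WR_new = WR
        if t1 > lag + 1e-12:
            ft0 = ft_half[2 * i]
            ftm = ft_half[2 * i + 1]
            ft1 = ft_half[2 * i + 2]

            k1L, k1R, s1 = _deriv(L, ft0, f, JAm_e, JM_e, kappa, yVA_e, dV, Lp_e)
            k2L, k2R, s2 = _deriv(L + 0.5 * dt * k1L, ftm, f, JAm_e, JM_e,
                                  kappa, yVA_e, dV, Lp_e)
            k3L, k3R, s3 = _deriv(L + 0.5 * dt * k2L, ftm, f, JAm_e, JM_e,
                                  kappa, yVA_e, dV, Lp_e)
            k4L, k4R, s4 = _deriv(L + dt * k3L, ft1, f, JAm_e, JM_e,
                                  kappa, yVA_e, dV, Lp_e)
            L_new = L + dt * (k1L + 2.0 * k2L + 2.0 * k3L + k4L) / 6.0
            WR_new = WR + dt * (k1R + 2.0 * k2R + 2.0 * k3R + k4R) / 6.0
            if s1 or s2 or s3 or s4:
                n_starved += 1

        if tox_on and not fast_tk:
            # exact exponential relaxation, then exact growth dilution
            rate = ke * (Lm_vol / L)
            Cv = Cd + (Cv - Cd) * np.exp(-rate * dt)
            Cv *= (L / L_new) ** 3
            if Cv < 0.0:
                Cv = 0.0

        L = L_new
        WR = WR_new

        out[i + 1, 0] = L
        out[i + 1, 1] = WR
        out[i + 1, 2] = Cv
        if tox_on:
            out[i + 1, 3] = max(0.0, Cv - C0) / CT
        else:
            out[i + 1, 3] = 0.0

    return n_starved
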