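"""Reference parameter sets for the C. elegans temperature x copper study.

Three fitted parameter columns exist, one per estimation scenario:

* ``constant_temperature`` - all constant-temperature treatments (minus
  the stressful 8 degC) described jointly with an Arrhenius temperature,
  rates referenced to 20 degC (293 K).
* ``variable_temperature`` - constant 16 degC and the 16+/-8 degC cycle
  described together with a stress factor on somatic maintenance.
* ``copper`` - the 16 degC treatment across the three highest copper
  levels, with copper stress on assimilation and length at puberty.

Egg dry weights (``W_B0``) are stored in mg; the study reports them in ng.
"""

from __future__ import annotations

from .deb_core import DEBParams
from .environment import ArrheniusParams
from .toxstress import StressSpec, ToxParams

__all__ = [
    "params_constant_temperature",
    "params_variable_temperature",
    "params_copper",
    "arrhenius",
    "maintenance_stress",
    "copper_stress_spec",
    "copper_tox",
    "NG_PER_MG",
]

NG_PER_MG = 1.0e6

#: Arrhenius temperature (K) estimated from the constant-temperature fit.
T_A_FITTED = 9109.0
#: Reference temperature (K) at which the rate parameters are defined.
T_REF_STUDY = 293.0
#: Maintenance stress factor fitted for the 16+/-8 degC cycle.
S_MAINTENANCE = 0.076


def params_constant_temperature() -> DEBParams:
    """Joint fit to the 12/16/20/24 degC constant treatments (ref. 20 degC)."""
    return DEBParams(kappa=0.734, J_Am=0.094, J_M=0.386,
                     L_p_phys=0.962, W_B0=5.67e-6)


def params_variable_temperature() -> DEBParams:
    """Joint fit to constant 16 degC and the 16+/-8 degC cycle."""
    return DEBParams(kappa=0.751, J_Am=0.109, J_M=0.531,
                     L_p_phys=1.057, W_B0=10.8e-6)


def params_copper() -> DEBParams:
    """Fit to 16 degC with 8/20/40 mg Cu/L (L_p fixed at the 16 degC value)."""
    return DEBParams(kappa=0.696, J_Am=0.086, J_M=0.352,
                     L_p_phys=1.057, W_B0=7.28e-6)


def arrhenius(T_A: float = T_A_FITTED, T_ref: float = T_REF_STUDY) -> ArrheniusParams:
    return ArrheniusParams(T_A=T_A, T_ref=T_ref)


def maintenance_stress(s: float = S_MAINTENANCE) -> StressSpec:
    """Constant stress on somatic maintenance (variable-temperature hypothesis)."""
    return StressSpec.constant(s, targets=("maintenance",))


def copper_stress_spec() -> StressSpec:
    """Copper stress channel: assimilation down, length at puberty down."""
    return StressSpec.toxicant(targets=("assimilation", "length_at_puberty"),
                               lp_direction="decrease")


def copper_tox(C_d: float = 0.0, C_0: float = 0.001, C_T: float = 89.0,
               k_e: float = 10.0) -> ToxParams:
    """Fitted copper toxicokinetic/threshold parameters at exposure ``C_d``."""
    return ToxParams(C_d=C_d, C_0=C_0, C_T=C_T, k_e=k_e)
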