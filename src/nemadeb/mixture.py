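"""Joint-stressor predictions: independent action and combined simulation.

Independent action predicts that, when each stressor alone leaves an
endpoint at fractions R_s1 and R_s2 of the control, the joint exposure
leaves the fraction

    R_mix = R_s1 * R_s2.

An observed joint response above the prediction (beyond its uncertainty)
indicates antagonism, below it synergism.

The energy-budget counterpart adds the two stress channels to one
forward simulation with no refitting: the constant maintenance stress
estimated from the variable-temperature comparison and the copper stress
channel from the copper fit act simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .deb_core import DEBParams, Trajectory, simulate
from .environment import ArrheniusParams, TemperatureProfile
from .toxstress import StressSpec, ToxParams

__all__ = [
    "ia_predict",
    "ia_classify",
    "combined_debkiss_prediction",
    "IAClassification",
]


@dataclass(frozen=True)
class IAClassification:
    observed: float
    predicted: float
    sem: float
    z: float
    label: str  # antagonistic | consistent | synergistic


def ia_predict(R_s1: float, R_s2: float) -> float:
    """Independent-action joint unaffected fraction, the product R_s1*R_s2."""
    if R_s1 < 0 or R_s2 < 0:
        raise ValueError("endpoint fractions must be >= 0")
    return float(R_s1 * R_s2)


def ia_classify(observed: float, predicted: float, sem: float,
                z: float = 1.96) -> IAClassification:
    """Compare an observed joint fraction with the IA prediction.

    ``sem`` is the standard error of the observed fraction; the
    comparison band is ``z * sem`` (95% by default).  Classification is
    refused (ValueError) without a finite positive uncertainty.
    """
    if not np.isfinite(sem) or sem <= 0:
        raise ValueError("classification requires a finite sem > 0")
    band = z * sem
    if observed > predicted + band:
        label = "antagonistic"
    elif observed < predicted - band:
        label = "synergistic"
    else:
        label = "consistent"
    return IAClassification(observed=float(observed), predicted=float(predicted),
                            sem=float(sem), z=float(z), label=label)


def combined_debkiss_prediction(params: DEBParams,
                                arr: ArrheniusParams,
                                tox: ToxParams,
                                cu_stress: StressSpec,
                                maintenance_s: float,
                                profile: TemperatureProfile,
                                cd_list: Sequence[float],
                                t_end: float = 21.0,
                                dt: float = 0.05) -> Dict[float, Trajectory]:
    """Forward mixed-stressor prediction, one trajectory per Cu level.

    The maintenance stress obtained from the constant-vs-variable
    temperature comparison is simply added to the copper model: both
    channels act in the same simulation under the cyclic profile, with no
    refitting.  With ``maintenance_s = 0`` and ``C_d = 0`` this reduces
    exactly to the plain control simulation.
    """
    if maintenance_s < 0:
        raise ValueError("maintenance stress must be >= 0")
    out: Dict[float, Trajectory] = {}
    for cd in cd_list:
        stresses = []
        if maintenance_s > 0:
            stresses.append(StressSpec.constant(maintenance_s,
                                                targets=("maintenance",)))
        tox_cd = None
        if cd > 0:
            tox_cd = tox.with_exposure(cd)
            stresses.append(cu_stress)
        out[float(cd)] = simulate(params, profile, arr, tox=tox_cd,
                                  stress=stresses or None,
                                  t_end=t_end, dt=dt)
    return out
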