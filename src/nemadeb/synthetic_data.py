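"""Synthetic individual-level life-history observations.

The generator emulates the data-collection design of the temperature x
copper assay: per-individual daily fertile-egg counts, sparse body-length
measurements, and a lifespan that truncates the record.  Expected daily
egg counts equal the energy-budget model's cumulative-offspring
increments for that individual; measured lengths are the model's physical
length plus fractional Gaussian error.  Between-individual variation
enters as a lognormal scatter on the assimilation rate.  Lifespan is not
an energy-budget output and is drawn from a Weibull distribution whose
scale follows the observed pattern of decreasing lifespan with
temperature and copper; it is phenomenological.

Everything is driven by one seeded generator, so an ObservationSet is a
pure function of (design, parameters, noise model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .deb_core import DEBParams, simulate
from .environment import ArrheniusParams, TemperatureProfile
from .toxstress import StressSpec, ToxParams
from . import presets

__all__ = [
    "Treatment",
    "CohortDesign",
    "NoiseModel",
    "ObservationSet",
    "generate",
    "study_design",
    "default_lifespan_mean",
]

#: Mean lifespan (d) at constant temperature, control food, no copper;
#: linearly interpolated between these anchors (degC, days).
_LIFESPAN_ANCHORS = ((8.0, 33.0), (12.0, 36.0), (16.0, 25.0),
                     (20.0, 17.0), (24.0, 16.0))

#: Copper effect on lifespan: log-logistic with these (EC50 mg/L, slope).
_LIFESPAN_CU = (30.0, 1.2)

DEFAULT_LENGTH_DAYS = (1.0, 3.0, 5.0, 7.0, 10.0, 14.0, 21.0)


@dataclass(frozen=True)
class Treatment:
    """One experimental condition: a temperature regime and a Cu level.

    ``stress`` optionally attaches a constant stress channel (the
    variable-temperature stress acting in the cyclic regime); copper
    stress is wired in by the generator whenever ``cu_mg_L > 0``.
    """

    label: str
    profile: TemperatureProfile
    cu_mg_L: float = 0.0
    n: int = 12
    stress: Optional[StressSpec] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.cu_mg_L < 0:
            raise ValueError("cu_mg_L must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    treatments: Tuple[Treatment, ...]
    length_days: Tuple[float, ...] = DEFAULT_LENGTH_DAYS
    horizon: float = 21.0

    def __post_init__(self) -> None:
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("treatment labels must be unique")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(
            self, "length_days",
            tuple(d for d in self.length_days if d <= self.horizon))


@dataclass(frozen=True)
class NoiseModel:
    """Observation and between-individual noise settings.

    ``length_cv`` - fractional Gaussian error on measured length;
    ``egg_poisson`` - daily counts Poisson around model increments (else
    deterministic rounding of the cumulative curve);
    ``individual_scatter`` - lognormal sd on each individual's J_Am;
    ``lifespan_shape`` - Weibull shape for lifespan draws;
    ``random_lifespan`` - when False every individual lives to the mean
    lifespan (rounded), which makes a zero-noise cohort fully
    deterministic.
    """

    length_cv: float = 0.03
    egg_poisson: bool = True
    individual_scatter: float = 0.10
    lifespan_shape: float = 4.0
    random_lifespan: bool = True

    def __post_init__(self) -> None:
        if self.length_cv < 0 or self.individual_scatter < 0:
            raise ValueError("dispersions must be >= 0")
        if self.lifespan_shape <= 0:
            raise ValueError("lifespan_shape must be > 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free configuration: observations equal model output."""
        return cls(length_cv=0.0, egg_poisson=False, individual_scatter=0.0,
                   random_lifespan=False)


@dataclass
class ObservationSet:
    """Tidy per-individual daily records plus generator ground truth.

    ``data`` columns: individual_id, treatment_id, day, eggs, length_mm
    (NaN except on measurement days), alive (False on the day of death).
    ``truth`` columns (generator-only bookkeeping): individual_id,
    treatment_id, lifespan_d, brood, max_length_mm.
    """

    data: pd.DataFrame
    treatments: Dict[str, Treatment] = field(default_factory=dict)
    truth: Optional[pd.DataFrame] = None

    @property
    def treatment_ids(self):
        return list(dict.fromkeys(self.data["treatment_id"]))

    def subset(self, labels) -> "ObservationSet":
        labels = list(labels)
        mask = self.data["treatment_id"].isin(labels)
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["treatment_id"].isin(labels)].copy()
        return ObservationSet(
            data=self.data[mask].copy(),
            treatments={k: v for k, v in self.treatments.items() if k in labels},
            truth=truth)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(data=pd.read_csv(path))


def default_lifespan_mean(mean_temp_C: float, cu_mg_L: float = 0.0) -> float:
    """Phenomenological mean lifespan (d) by mean temperature and copper."""
    temps = np.array([a[0] for a in _LIFESPAN_ANCHORS])
    days = np.array([a[1] for a in _LIFESPAN_ANCHORS])
    base = float(np.interp(mean_temp_C, temps, days))
    e50, slope = _LIFESPAN_CU
    return base / (1.0 + (cu_mg_L / e50) ** slope) if cu_mg_L > 0 else base


def generate(design: CohortDesign,
             params: DEBParams,
             arr: ArrheniusParams,
             tox: Optional[ToxParams] = None,
             cu_stress: Optional[StressSpec] = None,
             noise: Optional[NoiseModel] = None,
             seed: int = 0,
             dt: float = 0.05) -> ObservationSet:
    """Draw a full ObservationSet for a cohort design.

    ``tox`` supplies the toxicological constants (its ``C_d`` is replaced
    by each treatment's copper level); ``cu_stress`` is the toxicant
    stress channel applied in copper treatments.  Both default to the
    study's copper parameterization when any treatment has copper.
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    any_cu = any(t.cu_mg_L > 0 for t in design.treatments)
    if any_cu:
        tox = tox if tox is not None else presets.copper_tox()
        cu_stress = cu_stress if cu_stress is not None else presets.copper_stress_spec()

    days = np.arange(0, int(np.floor(design.horizon)) + 1)
    length_days = np.asarray(design.length_days, dtype=float)

    rows = []
    truth_rows = []
    for tr in design.treatments:
        stresses = []
        if tr.stress is not None:
            stresses.append(tr.stress)
        tox_tr = None
        if tr.cu_mg_L > 0:
            tox_tr = tox.with_exposure(tr.cu_mg_L)
            stresses.append(cu_stress)
        life_mean = default_lifespan_mean(tr.profile.mean_C, tr.cu_mg_L)

        for i in range(tr.n):
            ind = f"{tr.label}_{i:03d}"
            z = (float(rng.lognormal(0.0, noise.individual_scatter))
                 if noise.individual_scatter > 0 else 1.0)
            p_i = params.evolve(J_Am=params.J_Am * z) if z != 1.0 else params
            traj = simulate(p_i, tr.profile, arr, tox=tox_tr,
                            stress=stresses or None,
                            t_end=design.horizon, dt=dt)

            if noise.random_lifespan:
                from math import gamma as _g
                scale = life_mean / _g(1.0 + 1.0 / noise.lifespan_shape)
                life = scale * float(rng.weibull(noise.lifespan_shape))
            else:
                life = life_mean
            death_day = max(1, int(np.ceil(life)))
            last_day = min(death_day, int(days[-1]))

            cum = traj.at_days(days, "eggs_cum")
            if noise.egg_poisson:
                counts = rng.poisson(np.maximum(np.diff(cum), 0.0))
            else:
                counts = np.diff(np.floor(cum)).astype(int)

            lens = traj.at_days(length_days, "L_phys_mm")
            if noise.length_cv > 0:
                lens = lens * (1.0 + rng.normal(0.0, noise.length_cv,
                                                size=lens.shape))
            len_by_day = dict(zip(length_days, lens))

            brood = 0
            max_len = -np.inf
            for d in range(1, last_day + 1):
                lm = len_by_day.get(float(d), np.nan)
                if np.isfinite(lm):
                    max_len = max(max_len, lm)
                brood += int(counts[d - 1])
                rows.append((ind, tr.label, d, int(counts[d - 1]), lm,
                             d != death_day))
            truth_rows.append((ind, tr.label, last_day, brood,
                               max_len if np.isfinite(max_len) else np.nan))

    data = pd.DataFrame(rows, columns=["individual_id", "treatment_id", "day",
                                       "eggs", "length_mm", "alive"])
    truth = pd.DataFrame(truth_rows, columns=["individual_id", "treatment_id",
                                              "lifespan_d", "brood",
                                              "max_length_mm"])
    return ObservationSet(data=data,
                          treatments={t.label: t for t in design.treatments},
                          truth=truth)


def study_design(horizon: float = 40.0) -> CohortDesign:
    """The full study design: 9 temperature regimes x 6 copper levels.

    Regimes: constant 8/12/16/20/24 degC, +/-4 degC cycles around
    12/16/20 degC and a +/-8 degC cycle around 16 degC (4 degC/h ramps).
    Copper at 0, 1, 3, 8, 20 and 40 mg/L agar.  Twelve replicates per
    treatment, 36 for the designated controls (constant 24 degC and the
    three cyclic regimes at zero copper); the 8 degC cohorts, which the
    assay could not always fill, get 9.
    """
    regimes = [
        ("8C", TemperatureProfile(8.0)),
        ("12C", TemperatureProfile(12.0)),
        ("16C", TemperatureProfile(16.0)),
        ("20C", TemperatureProfile(20.0)),
        ("24C", TemperatureProfile(24.0)),
        ("12pm4C", TemperatureProfile(12.0, 4.0)),
        ("16pm4C", TemperatureProfile(16.0, 4.0)),
        ("20pm4C", TemperatureProfile(20.0, 4.0)),
        ("16pm8C", TemperatureProfile(16.0, 8.0)),
    ]
    big_controls = {"24C", "12pm4C", "16pm8C", "20pm4C"}
    cu_levels = (0.0, 1.0, 3.0, 8.0, 20.0, 40.0)
    treatments = []
    for name, prof in regimes:
        for cu in cu_levels:
            label = f"{name}_Cu{cu:g}"
            if name == "8C":
                n = 9
            elif cu == 0.0 and name in big_controls:
                n = 36
            else:
                n = 12
            treatments.append(Treatment(label=label, profile=prof,
                                        cu_mg_L=cu, n=n))
    return CohortDesign(treatments=tuple(treatments), horizon=horizon)
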