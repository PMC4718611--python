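# nemadeb

Energy-budget analysis of temperature and copper stress in the nematode
*Caenorhabditis elegans*: forward DEBkiss simulation under constant and
diurnally fluctuating temperature, one-compartment copper
toxicokinetics with stress linkage, joint MCMC parameter estimation,
log-logistic endpoint analysis (EC50, time to first egg), day-staged
Leslie-matrix population growth rates, and independent-action
mixed-stressor predictions — with a seeded synthetic-data generator
standing in for the assay's individual-level observations.

It is written for ecotoxicologists and modellers who want to test
whether temperature fluctuation sensitises an organism to a chemical
co-stressor, using a process model rather than endpoint statistics
alone.

## The model in brief

DEBkiss splits assimilation `J_A = f J_Am F_T L**2` by the kappa-rule:
a fraction `kappa` pays maintenance `J_M = J_Mv F_T L**3` and builds
structure at yield `y_VA`; the rest fills a reproduction buffer once
length passes `L_p`, converted to eggs of weight `W_B0` at yield
`y_BA`.  Temperature scales both rate fluxes through the Arrhenius
factor `F_T = exp(T_A/T_ref - T_A/T_a)`.  Copper enters as a scaled
internal concentration (`dC_v/dt = k_e (L_m/L)(C_d - C_v)` minus growth
dilution) whose excess over a threshold, `s_Cu = max(0, C_v - C_0)/C_T`,
reduces assimilation and length at puberty.  A fluctuating-temperature
stress is a constant factor `s` on somatic maintenance (or, as rival
hypotheses, on assimilation or the cost of growth).  Full equations and
numerical choices: `docs/methods.md`.

## Worked example

Simulate a control worm at 20 °C, then re-estimate the generating
parameters from synthetic cohorts at four temperatures:

```python
import numpy as np
from nemadeb import presets, inference
from nemadeb.deb_core import simulate
from nemadeb.environment import TemperatureProfile
from nemadeb.synthetic_data import CohortDesign, NoiseModel, Treatment, generate

params = presets.params_constant_temperature()   # kappa=0.734, J_Am=0.094, ...
arr = presets.arrhenius()                        # T_A = 9109 K, T_ref = 293 K

traj = simulate(params, TemperatureProfile(20.0), arr, t_end=21.0)
print(round(traj.L_phys[-1], 3), int(traj.eggs[-1]))
# 1.489 2222        <- physical length (mm) approaches kappa*J_Am/(J_Mv*delta_M)

design = CohortDesign(treatments=tuple(
    Treatment(f"{T}C", TemperatureProfile(float(T)), n=12)
    for T in (12, 16, 20, 24)), horizon=21.0)
obs = generate(design, params, arr, noise=NoiseModel(), seed=1)

fit = inference.fit_mcmc(inference.scenario_constant_temps(obs),
                         steps=400, seed=1)
print(fit.summary().round(4).to_string(index=False))
```

which prints (posterior mean ± sd; generating values in comments):

```
parameter   estimate        sd
    kappa     0.7196    0.0426      # 0.734
     J_Am     0.0941    0.0063      # 0.094  mg mm^-2 d^-1
      J_M     0.3717    0.0110      # 0.386  mg mm^-3 d^-1
      T_A  9131.3775  130.5157      # 9109   K
 L_p_phys     0.9545    0.0221      # 0.962  mm
     W_B0     0.0000    0.0000      # 5.67e-6 mg (= 5.67 ng)
```

Every generating value is recovered within a few percent from 48
synthetic individuals; the joint fit explains R² ≈ 0.98 of the pooled
length and egg-count variation.

## The analysis

Numbered drivers under `analysis/` rebuild the study end to end; each
prints what it found and writes tables to `results/` (large regenerable
raw files go to `scratch/`):

1. `01_simulate_regimes.py` — the nine temperature regimes; shows the
   Arrhenius-convexity rate boost of cycles (16±8 °C has 1.29× the mean
   temperature factor of constant 16 °C).
2. `02_generate_cohorts.py` — the full synthetic assay (9 regimes ×
   6 Cu levels, study replicate counts).
3. `03_fit_constant_temperature.py` — joint 12–24 °C fit, free T_A.
4. `04_fit_variable_temperature.py` — maintenance-stress fit of
   16 °C + 16±8 °C (recovers s = 0.078 ± 0.013 against a generating
   0.076) and the rival stress-target comparison.
5. `05_fit_copper.py` — copper scenario (recovers the tolerance
   concentration C_T ≈ 98 vs generating 89 mg/L) and the shrinking size
   at first egg (1.06 → 0.59 mm from 0 to 40 mg Cu/L).
6. `06_endpoints_population.py` — trait table, dose–response EC50s,
   Leslie-matrix growth rates with bootstrap CIs.
7. `07_mixture_prediction.py` — independent-action classification and
   the combined maintenance+copper forward prediction (pooled R² ≈ 0.97
   against joint-exposure cohorts).

A thin CLI wraps the same library for shell use
(`nemadeb simulate|synth|fit-temp|fit-variable|fit-cu|endpoints|pgr|mixture`,
YAML config in, CSV out; every output gets a `.config.json` sidecar with
the resolved configuration and seed).

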