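#!/usr/bin/env python
"""Forward-simulate the nine temperature regimes at control conditions.

Writes one tidy trajectory per regime and a summary table (final body
length, cumulative eggs at day 21, temperature-factor statistics).  The
cyclic regimes illustrate the rate-boosting convexity of the Arrhenius
factor: a +/-8 degC cycle around 16 degC has a higher mean temperature
factor than constant 16 degC, so unstressed simulations grow *faster*
under fluctuation - the observed slowdown is what the maintenance-stress
analysis (04) quantifies.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nemadeb import presets
from nemadeb.deb_core import simulate
from nemadeb.environment import TemperatureProfile, factor_series

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
# per-regime trajectories are large and fully regenerable: keep them out
# of the results tables
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SCRATCH.mkdir(exist_ok=True)

REGIMES = {
    "8C": TemperatureProfile(8.0), "12C": TemperatureProfile(12.0),
    "16C": TemperatureProfile(16.0), "20C": TemperatureProfile(20.0),
    "24C": TemperatureProfile(24.0),
    "12pm4C": TemperatureProfile(12.0, 4.0),
    "16pm4C": TemperatureProfile(16.0, 4.0),
    "20pm4C": TemperatureProfile(20.0, 4.0),
    "16pm8C": TemperatureProfile(16.0, 8.0),
}


def main() -> None:
    params = presets.params_constant_temperature()
    arr = presets.arrhenius()
    rows = []
    traj_dir = SCRATCH / "trajectories"
    traj_dir.mkdir(exist_ok=True)
    day_grid = np.linspace(0, 1, 241)
    for name, profile in REGIMES.items():
        traj = simulate(params, profile, arr, t_end=21.0, dt=0.01)
        traj.to_csv(traj_dir / f"trajectory_{name}.csv")
        ft = factor_series(profile, arr, day_grid)
        rows.append({
            "regime": name,
            "mean_T_C": profile.mean_C,
            "amplitude_C": profile.amplitude_C,
            "F_T_daily_mean": float(np.trapezoid(ft, day_grid)),
            "final_length_mm": float(traj.L_phys[-1]),
            "eggs_day21": float(traj.eggs[-1]),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "regime_summary.csv", index=False,
                   float_format="%.5g")
    print(summary.to_string(index=False))
    cyc = summary.set_index("regime")
    boost = cyc.loc["16pm8C", "F_T_daily_mean"] / cyc.loc["16C", "F_T_daily_mean"]
    print(f"\nMean temperature factor of the 16+/-8C cycle is {boost:.3f}x "
          "the constant-16C factor (Arrhenius convexity): without an added "
          "stress the model predicts faster life histories under fluctuation.")


if __name__ == "__main__":
    main()
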