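"""Trait extraction and three-parameter log-logistic endpoint models.

The same sigmoid,

    y = d / (1 + (x/e)**b),

serves two roles.  Fitted to mean cumulative egg production against time
(with b < 0, an increasing curve), ``d`` is the maximum egg number and
``e`` the time at which half of it is produced; the time to first egg
(TFE) follows in closed form by solving y(x) = 1 egg:

    TFE = e * (d - 1)**(1/b).

Fitted to a treatment-level endpoint against copper concentration (with
b > 0, a decreasing curve), ``d`` is the control level and ``e`` the
EC50.  Standard errors come from the asymptotic covariance of the
least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic_data import ObservationSet

__all__ = [
    "LogLogistic3",
    "TraitTable",
    "loglogistic3",
    "fit_time_course",
    "tfe_from_fit",
    "fit_dose_response",
    "extract_traits",
]


@dataclass(frozen=True)
class LogLogistic3:
    """Fitted three-parameter log-logistic curve with standard errors."""

    d: float
    b: float
    e: float
    d_se: float = np.nan
    b_se: float = np.nan
    e_se: float = np.nan
    converged: bool = True

    def __call__(self, x):
        return loglogistic3(x, self.d, self.b, self.e)


@dataclass
class TraitTable:
    """Per-individual traits and per-treatment summaries.

    ``individuals``: individual_id, treatment_id, brood, lifespan_d,
    max_length_mm.  ``treatments``: mean +/- sem of each trait plus the
    fitted time to first egg (TFE, days).
    """

    individuals: pd.DataFrame
    treatments: pd.DataFrame


def loglogistic3(x, d: float, b: float, e: float):
    """y = d / (1 + (x/e)**b), with the x = 0 limit handled by sign of b."""
    if e <= 0:
        raise ValueError("e must be > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    ratio = x / e
    with np.errstate(divide="ignore", over="ignore"):
        powed = np.where(ratio > 0, ratio, 1.0) ** b
        powed = np.where(ratio > 0, powed, 0.0 if b > 0 else np.inf)
        out = d / (1.0 + powed)
    return out if out.ndim else float(out)


def _ll3_least_squares(x, y, x0, lower, upper):
    def resid(theta):
        return loglogistic3(x, *theta) - y

    res = least_squares(resid, x0, bounds=(lower, upper), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    dof = max(len(x) - 3, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(3, np.nan)
    return LogLogistic3(d=res.x[0], b=res.x[1], e=res.x[2],
                        d_se=ses[0], b_se=ses[1], e_se=ses[2],
                        converged=bool(res.success))


def fit_time_course(days, cum_eggs) -> LogLogistic3:
    """Fit the increasing sigmoid (b < 0) to mean cumulative eggs vs time."""
    x = np.asarray(days, dtype=float)
    y = np.asarray(cum_eggs, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 time points")
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("no egg production: time-course fit undefined")
    # inflection guess: first crossing of half maximum
    above = np.nonzero(y >= ymax / 2.0)[0]
    e0 = float(x[above[0]]) if len(above) and x[above[0]] > 0 else float(np.median(x[x > 0]))
    x0 = np.array([ymax * 1.05, -4.0, e0])
    return _ll3_least_squares(x, y, x0,
                              lower=[ymax * 0.2, -60.0, np.min(x[x > 0])* 0.1],
                              upper=[ymax * 10.0, -0.05, np.max(x) * 10.0])


def tfe_from_fit(fit: LogLogistic3) -> float:
    """Time to first egg: solve y(x) = 1 for the fitted increasing curve."""
    if fit.d <= 1.0:
        raise ValueError("TFE undefined for maximum egg number d <= 1")
    if fit.b >= 0:
        raise ValueError("TFE requires an increasing time course (b < 0)")
    return float(fit.e * (fit.d - 1.0) ** (1.0 / fit.b))


def fit_dose_response(concentrations, response,
                      exclude: Sequence[float] = ()) -> LogLogistic3:
    """Fit the decreasing sigmoid (b > 0): ``e`` is the EC50.

    ``exclude`` drops listed concentrations before fitting (used to omit
    hormetic low-dose points, which the monotone model cannot represent).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if exclude:
        keep = ~np.isin(x, np.asarray(exclude, dtype=float))
        x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 concentrations (incl. control)")
    if np.ptp(y) <= 0 or np.all(y == y[0]):
        raise ValueError("response has no variation: EC50 unidentifiable")
    d0 = float(np.max(y))
    pos = x[x > 0]
    x0 = np.array([d0, 1.5, float(np.median(pos))])
    fit = _ll3_least_squares(x, y, x0,
                             lower=[d0 * 0.2, 0.05, np.min(pos) * 1e-2],
                             upper=[d0 * 5.0, 60.0, np.max(pos) * 1e3])
    if not fit.converged:
        raise RuntimeError("dose-response fit did not converge")
    return fit


def extract_traits(obs: ObservationSet) -> TraitTable:
    """Individual brood size, lifespan and maximal length; treatment TFE.

    Brood is the sum of daily fertile-egg counts, lifespan the last
    recorded day, maximal length the largest measurement.  TFE is
    estimated per treatment from the sigmoid fit to the mean cumulative
    egg curve (NaN where the fit is undefined, e.g. no reproduction).
    """
    df = obs.data
    if df.empty:
        raise ValueError("empty observation set")
    g = df.groupby(["treatment_id", "individual_id"], sort=False)
    ind = g.agg(brood=("eggs", "sum"), lifespan_d=("day", "max"),
                max_length_mm=("length_mm", "max")).reset_index()

    rows = []
    for trt, sub in df.groupby("treatment_id", sort=False):
        pivot = (sub.pivot_table(index="day", columns="individual_id",
                                 values="eggs", aggfunc="sum")
                 .sort_index())
        # cohort-mean cumulative production: individuals keep their final
        # total after death, so the average plateaus as the cohort dies
        # off (the convention behind reported mean egg-production curves)
        ind_cum = pivot.cumsum(axis=0, skipna=True).ffill(axis=0).fillna(0.0)
        mean_curve = ind_cum.mean(axis=1)
        days = mean_curve.index.to_numpy(dtype=float)
        cum = mean_curve.to_numpy(dtype=float)
        tfe = np.nan
        if len(days) >= 4 and np.max(cum) > 1:
            try:
                tfe = tfe_from_fit(fit_time_course(days, cum))
            except (ValueError, RuntimeError):
                tfe = np.nan
        sub_ind = ind[ind["treatment_id"] == trt]
        n = len(sub_ind)
        rows.append({
            "treatment_id": trt,
            "n": n,
            "brood_mean": sub_ind["brood"].mean(),
            "brood_sem": sub_ind["brood"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "lifespan_mean": sub_ind["lifespan_d"].mean(),
            "lifespan_sem": sub_ind["lifespan_d"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "max_length_mean": sub_ind["max_length_mm"].mean(),
            "max_length_sem": sub_ind["max_length_mm"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "tfe_d": tfe,
        })
    return TraitTable(individuals=ind, treatments=pd.DataFrame(rows))
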