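"""Developmental-milestone extraction from fitted normative charts.

Milestones are inflection landmarks of the median (50th-centile)
trajectory: the age of peak value (argmax of the median curve), the age of
peak growth rate (argmax of its first derivative), and the grey/white
differentiation epoch (postnatal crossing of the two median curves to the
age of their maximal absolute difference).  Headline milestones average
the female and male median curves pointwise; per-sex results are also
reported.  Ages are reported in years relative to birth (280-day gestation
convention), so prenatal milestones are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import BIRTH_DAYS, DAYS_PER_YEAR
from .scoring import trajectory, velocity

__all__ = [
    "MilestoneSet",
    "DifferentiationResult",
    "daily_grid",
    "find_milestones",
    "gmv_wmv_differentiation",
    "milestone_ci",
]

_BIRTH_YEARS = BIRTH_DAYS / DAYS_PER_YEAR


def daily_grid(lo: float, hi: float) -> np.ndarray:
    """Daily-resolution age grid in years post-conception."""
    step = 1.0 / DAYS_PER_YEAR
    return np.arange(lo, hi + step / 2, step)


@dataclass
class MilestoneSet:
    """Peak and velocity-peak landmarks for one phenotype.

    Ages are years relative to birth; ``peak_value`` is in phenotype
    units.  ``*_interior`` flags are False when the argmax fell on a grid
    endpoint (monotone curve), in which case the endpoint is reported.
    """

    phenotype: str
    peak_age: float
    peak_value: float
    velocity_peak_age: float
    velocity_peak_value: float
    peak_interior: bool
    velocity_peak_interior: bool
    by_sex: dict = field(default_factory=dict)
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)


def _median_curve(model, sex, age_grid, mode):
    if sex == "average":
        f = trajectory(model, "F", age_grid, levels=(0.5,), mode=mode)["c0.5"]
        m = trajectory(model, "M", age_grid, levels=(0.5,), mode=mode)["c0.5"]
        return 0.5 * (f.to_numpy() + m.to_numpy())
    return trajectory(model, sex, age_grid, levels=(0.5,),
                      mode=mode)["c0.5"].to_numpy()


def _argmax_info(age_grid, values):
    i = int(np.nanargmax(values))
    interior = 0 < i < len(values) - 1
    return age_grid[i] - _BIRTH_YEARS, float(values[i]), interior


def find_milestones(model, sex: str = "average", age_grid=None,
                    mode="population") -> MilestoneSet:
    """Peak age/value and velocity-peak age of the median trajectory.

    ``sex`` may be "F", "M" or "average" (pointwise mean of the two
    median curves, the default for headline milestones).  The grid should
    span the fitted support at daily resolution; monotone curves give an
    endpoint result with the interior flag False rather than an error.
    """
    if age_grid is None:
        lo, hi = model.age_support_
        age_grid = daily_grid(lo, hi)
    age_grid = np.asarray(age_grid, dtype=float)
    med = _median_curve(model, sex, age_grid, mode)
    peak_age, peak_value, peak_int = _argmax_info(age_grid, med)
    vel = velocity(age_grid, med)
    v_age, v_val, v_int = _argmax_info(age_grid, vel)
    by_sex = {}
    if sex == "average":
        for s in ("F", "M"):
            ms = find_milestones(model, sex=s, age_grid=age_grid, mode=mode)
            by_sex[s] = {"peak_age": ms.peak_age,
                         "velocity_peak_age": ms.velocity_peak_age}
    return MilestoneSet(
        phenotype=model.spec_.phenotype,
        peak_age=float(peak_age), peak_value=peak_value,
        velocity_peak_age=float(v_age), velocity_peak_value=v_val,
        peak_interior=peak_int, velocity_peak_interior=v_int,
        by_sex=by_sex,
    )


@dataclass
class DifferentiationResult:
    """Grey/white differentiation epoch landmarks (years relative to birth).

    ``crossed`` is False when the two median curves never change order on
    the grid; ``direction`` is +1 when the first model's curve crosses
    above the second's, -1 for the reverse.
    """

    crossed: bool
    direction: int = 0
    crossing_age: float = float("nan")
    max_abs_diff_age: float = float("nan")
    max_abs_diff: float = float("nan")


def gmv_wmv_differentiation(model_a, model_b, age_grid, sex: str = "average",
                            mode="population") -> DifferentiationResult:
    """Crossing age and maximal-absolute-difference age of two median curves.

    The crossing is the first grid age where curve A exceeds curve B after
    having been below it (sign change of A - B); the second landmark is the
    argmax of |A - B| restricted to ages at or after the crossing.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    a = _median_curve(model_a, sex, age_grid, mode)
    b = _median_curve(model_b, sex, age_grid, mode)
    diff = a - b
    sign = np.sign(diff)
    nz = sign != 0
    if not np.any(nz) or np.all(sign[nz] == sign[nz][0]):
        return DifferentiationResult(crossed=False)
    s0 = sign[nz][0]
    flip = np.where(nz & (sign == -s0))[0]
    i_cross = int(flip[0])
    after = diff[i_cross:]
    j = int(np.argmax(np.abs(after))) + i_cross
    return DifferentiationResult(
        crossed=True,
        direction=int(-s0),
        crossing_age=float(age_grid[i_cross] - _BIRTH_YEARS),
        max_abs_diff_age=float(age_grid[j] - _BIRTH_YEARS),
        max_abs_diff=float(abs(diff[j])),
    )


def milestone_ci(bootstrap_models, age_grid=None, sex: str = "average",
                 mode="population"):
    """Percentile bootstrap CIs for milestone ages and the peak value.

    Replicates whose peak fell on a grid endpoint are excluded and counted
    in the returned diagnostics.  Needs >= 20 replicates for stable
    2.5/97.5 percentiles.
    """
    if len(bootstrap_models) < 20:
        raise ValueError("at least 20 bootstrap replicates are required")
    peak_ages, vel_ages, peak_vals = [], [], []
    n_endpoint = 0
    for m in bootstrap_models:
        ms = find_milestones(m, sex=sex, age_grid=age_grid, mode=mode)
        if not (ms.peak_interior and ms.velocity_peak_interior):
            n_endpoint += 1
            continue
        peak_ages.append(ms.peak_age)
        vel_ages.append(ms.velocity_peak_age)
        peak_vals.append(ms.peak_value)
    cis = {}
    for name, vals in (("peak_age", peak_ages),
                       ("velocity_peak_age", vel_ages),
                       ("peak_value", peak_vals)):
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            cis[name] = (float(lo), float(hi))
    return {"ci": cis, "n_excluded_endpoint": n_endpoint,
            "n_used": len(peak_ages)}
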