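"""Centile scoring, out-of-sample study offsets and trajectory curves.

A centile score is the fitted outcome distribution's CDF evaluated at a
subject's observed phenotype — their rank within the age- and sex-matched
normative population.  New studies absent from the reference fit are
aligned by maximum-likelihood estimation of link-scale offsets
``(d_mu, d_sigma[, d_nu])`` with all population parameters frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from . import ggamma
from .design import BIRTH_DAYS, DAYS_PER_YEAR, validate_table
from .model import GeneralizedGammaChart, _gg_ll_vec

__all__ = [
    "StudyOffset",
    "StudyOffsetEstimator",
    "fit_new_study_offsets",
    "centile_score",
    "trajectory",
    "variability_trajectory",
    "velocity",
    "SMALL_STUDY_N",
    "CENTILE_CLAMP",
]

#: below this many scans, out-of-sample offsets are flagged as unstable
SMALL_STUDY_N = 100
#: centiles are clamped into [CENTILE_CLAMP, 1 - CENTILE_CLAMP]
CENTILE_CLAMP = 1e-6


@dataclass
class StudyOffset:
    """Link-scale shifts aligning a new study to the reference charts."""

    d_mu: float
    d_sigma: float
    d_nu: float | None
    n_scans: int
    small_sample_warning: bool
    study: str = ""
    loglik: float = float("nan")

    @classmethod
    def make(cls, d_mu, d_sigma, d_nu, n_scans, **kw):
        return cls(d_mu=float(d_mu), d_sigma=float(d_sigma),
                   d_nu=None if d_nu is None else float(d_nu),
                   n_scans=int(n_scans),
                   small_sample_warning=int(n_scans) < SMALL_STUDY_N, **kw)


class StudyOffsetEstimator(BaseEstimator):
    """ML estimator of per-study offsets for out-of-sample data.

    Parameters
    ----------
    model : fitted GeneralizedGammaChart
        Population parameters are frozen; only the offsets move.
    estimate_nu : bool
        Also estimate an identity-scale shape shift ``d_nu``, bounded to
        ``|d_nu| <= nu_abs_bound`` to prevent degeneracy on small studies.
    ridge : bool
        Optionally shrink (d_mu, d_sigma) toward 0 with weights given by
        the model's fitted random-effect variances; default off (plain ML).

    After ``fit``, ``offsets_`` maps study label -> :class:`StudyOffset`.
    """

    def __init__(self, model: GeneralizedGammaChart, *, estimate_nu: bool = True,
                 nu_abs_bound: float = 2.0, ridge: bool = False):
        self.model = model
        self.estimate_nu = estimate_nu
        self.nu_abs_bound = nu_abs_bound
        self.ridge = ridge

    def fit(self, new_data: pd.DataFrame, y=None):
        model = self.model
        phen = model.spec_.phenotype
        validate_table(new_data, phenotype=phen, age_floor=model.age_floor)
        overlap = set(new_data["study"].astype(str)) & set(
            model.registry_.study_levels)
        if overlap:
            raise ValueError(
                f"studies {sorted(overlap)} are already in the model registry; "
                "use known-study mode instead"
            )
        offsets = {}
        for study, grp in new_data.groupby(new_data["study"].astype(str),
                                           sort=True):
            offsets[study] = self._fit_one(grp, study)
        self.offsets_ = offsets
        return self

    def _fit_one(self, grp: pd.DataFrame, study: str) -> StudyOffset:
        model = self.model
        y_log = np.log(grp[model.spec_.phenotype].to_numpy(dtype=float))
        base = model.predict_moments(grp, mode="population")
        eta_mu0 = np.log(base["mu"].to_numpy())
        eta_si0 = np.log(base["sigma"].to_numpy())
        nu0 = model.alpha_nu_
        est_nu = self.estimate_nu
        b = self.nu_abs_bound
        d2m = model.delta2_mu_ if model.delta2_mu_ else None
        d2s = model.delta2_sigma_ if model.delta2_sigma_ else None

        def neg(v):
            d_mu, d_si = v[0], v[1]
            nu = nu0 + (v[2] if est_nu else 0.0)
            if abs(nu) < 1e-8:
                nu = 1e-8
            ll = float(np.sum(_gg_ll_vec(y_log, eta_mu0 + d_mu,
                                         eta_si0 + d_si, nu)))
            if self.ridge:
                if d2m:
                    ll -= d_mu ** 2 / (2.0 * d2m)
                if d2s:
                    ll -= d_si ** 2 / (2.0 * d2s)
            return -ll

        x0 = np.zeros(3 if est_nu else 2)
        bounds = [(-5, 5), (-5, 5)] + ([(-b, b)] if est_nu else [])
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(
                f"offset optimizer failed for study {study!r}: {res.message}; "
                f"best point {res.x}, |grad| {np.linalg.norm(res.jac):.3g}"
            )
        off = StudyOffset.make(
            res.x[0], res.x[1], res.x[2] if est_nu else None,
            n_scans=len(grp), study=study, loglik=-float(res.fun))
        return off


def fit_new_study_offsets(model: GeneralizedGammaChart,
                          new_data: pd.DataFrame, **options):
    """ML study offsets for out-of-sample data (thin estimator wrapper).

    Returns a single :class:`StudyOffset` when the new data holds one
    study, else a dict keyed by study label.
    """
    est = StudyOffsetEstimator(model, **options).fit(new_data)
    if len(est.offsets_) == 1:
        return next(iter(est.offsets_.values()))
    return est.offsets_


def centile_score(model: GeneralizedGammaChart, data: pd.DataFrame,
                  mode="population") -> pd.DataFrame:
    """Per-scan centiles = F(y; predicted mu, sigma, nu), one row per input.

    Centiles are clamped into [1e-6, 1 - 1e-6] to keep downstream
    transforms finite.  The returned frame carries the parameters used and
    the prediction mode.
    """
    phen = model.spec_.phenotype
    validate_table(data, phenotype=phen, age_floor=model.age_floor)
    params = model.predict_moments(data, mode=mode)
    y = data[phen].to_numpy(dtype=float)
    cent = ggamma.cdf_arrays(y, params["mu"].to_numpy(),
                             params["sigma"].to_numpy(),
                             params["nu"].to_numpy())
    cent = np.clip(cent, CENTILE_CLAMP, 1.0 - CENTILE_CLAMP)
    out = params.copy()
    out.insert(0, "centile", cent)
    out["mode"] = mode if isinstance(mode, str) else "offset"
    return out


def _grid_rows(age_years_pc, sex, model) -> pd.DataFrame:
    reg = model.registry_
    version = reg.version_levels[0] if reg.version_levels else "v1"
    study = reg.study_levels[0] if reg.study_levels else "S00"
    return pd.DataFrame({
        "participant_id": [f"grid{i}" for i in range(len(age_years_pc))],
        "study": study,
        "age_days": np.asarray(age_years_pc, float) * DAYS_PER_YEAR,
        "sex": sex,
        "version": version,
    })


def trajectory(model: GeneralizedGammaChart, sex: str, age_grid,
               levels=(0.025, 0.5, 0.975), mode="population") -> pd.DataFrame:
    """Centile curves over an age grid (years post-conception).

    Returns a frame with ``age`` (years post-conception), ``age_rel_birth``
    and one column ``c<level>`` per requested level.  Grid points outside
    the fitted age support are flagged in an ``extrapolated`` column.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0:
        raise ValueError("age grid must be non-empty")
    rows = _grid_rows(age_grid, sex, model)
    params = model.predict_moments(rows, mode=mode)
    out = pd.DataFrame({
        "age": age_grid,
        "age_rel_birth": age_grid - BIRTH_DAYS / DAYS_PER_YEAR,
    })
    for lev in levels:
        out[f"c{lev:g}"] = ggamma.quantile_arrays(
            lev, params["mu"].to_numpy(), params["sigma"].to_numpy(),
            params["nu"].to_numpy())
    lo, hi = getattr(model, "age_support_", (-np.inf, np.inf))
    out["extrapolated"] = (age_grid < lo) | (age_grid > hi)
    return out


def variability_trajectory(model: GeneralizedGammaChart, sex: str, age_grid,
                           bootstrap_models=None, mode="population"
                           ) -> pd.DataFrame:
    """Between-subject SD of the outcome distribution across age.

    The point curve is the analytic SD of the generalized gamma at the
    predicted (population-mode by default) parameters; percentile CI bands
    come from ≥ 20 bootstrap refits.  Ages where the second moment is
    undefined (strongly negative shape) yield NaN, not an exception.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    rows = _grid_rows(age_grid, sex, model)

    def sd_curve(m):
        params = m.predict_moments(rows, mode=mode)
        with np.errstate(all="ignore"):
            _, sd = ggamma.moments_arrays(
                params["mu"].to_numpy(), params["sigma"].to_numpy(),
                params["nu"].to_numpy())
        return np.asarray(sd, dtype=float)

    out = pd.DataFrame({"age": age_grid, "sd": sd_curve(model)})
    if bootstrap_models:
        if len(bootstrap_models) < 20:
            warnings.warn(
                "fewer than 20 bootstrap replicates; CI bands omitted")
        else:
            curves = np.vstack([sd_curve(m) for m in bootstrap_models])
            out["sd_lo"] = np.nanpercentile(curves, 2.5, axis=0)
            out["sd_hi"] = np.nanpercentile(curves, 97.5, axis=0)
    return out


def velocity(age_grid, values) -> np.ndarray:
    """First derivative of a sampled curve, units per year.

    Central differences in the interior, one-sided at the ends; the grid
    must be strictly increasing with at least 3 points.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if age_grid.size < 3:
        raise ValueError("velocity needs at least 3 grid points")
    if np.any(np.diff(age_grid) <= 0):
        raise ValueError("age grid must be strictly increasing (no duplicates)")
    return np.gradient(values, age_grid, edge_order=1)
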