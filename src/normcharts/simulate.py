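"""Synthetic multi-study lifespan cohorts with the structure the charts assume.

Generators draw ages log-uniformly over the lifespan (mimicking the dense
early-life / sparse late-life sampling of aggregated MRI cohorts), apply a
known three-moment generalized-gamma model with per-study Gaussian
intercepts on the location and scale links, and emit the standard per-scan
phenotype table.  Presets ("gmv_like", "wmv_like", "ct_like") are
log-quadratic in log-age — a second-order fractional polynomial with the
repeated power 0 — tuned so the median trajectory has a single interior
peak at a configurable age; they are fixtures with realistic magnitudes,
not fitted reference values.

All generators are pure functions of (truth, knobs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from . import ggamma
from .design import (
    DAYS_PER_YEAR,
    FractionalPolynomial,
    ModelSpec,
    MomentFormula,
    fp_basis,
)

__all__ = [
    "TrueModel",
    "preset",
    "make_reference_cohort",
    "make_new_study",
    "make_clinical_group",
    "make_longitudinal",
    "make_twins",
    "chart_from_truth",
    "z_shift_for_cohens_d",
]


@dataclass(frozen=True)
class TrueModel:
    """A ModelSpec plus its known generating coefficients.

    Coefficient vectors follow the design-matrix order (intercept, sex[M],
    version indicators, fractional-polynomial age columns).  ``delta_mu``
    and ``delta_sigma`` are random-intercept SDs on the link scale.
    Scenario knobs: ``clinical_shift_d`` (target case-group effect),
    ``drift_per_year`` (longitudinal centile drift) and the twin ACE
    variance components (must sum to 1).
    """

    spec: ModelSpec
    beta_mu: tuple
    beta_sigma: tuple
    alpha_nu: float
    delta_mu: float = 0.0
    delta_sigma: float = 0.0
    version_levels: tuple = ("v1",)
    clinical_shift_d: float = 0.8
    drift_per_year: float = 0.05
    ace: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if self.delta_mu < 0 or self.delta_sigma < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if abs(sum(self.ace) - 1.0) > 1e-9:
            raise ValueError("ACE variance components must sum to 1")

    # ---- linear predictors ------------------------------------------------

    def _eta(self, formula: MomentFormula, beta, x_years, male, version_idx):
        beta = np.asarray(beta, dtype=float)
        k = 0
        eta = np.full(np.shape(x_years), beta[k])
        k += 1
        if "sex" in formula.fixed_covariates:
            eta = eta + beta[k] * male
            k += 1
        if "version" in formula.fixed_covariates:
            for j in range(1, len(self.version_levels)):
                eta = eta + beta[k] * (version_idx == j)
                k += 1
        if formula.fp.order:
            B = fp_basis(np.asarray(x_years, dtype=float), formula.fp)
            eta = eta + B @ beta[k:k + formula.fp.order]
            k += formula.fp.order
        if k != beta.size:
            raise ValueError(
                f"coefficient vector length {beta.size} does not match the "
                f"formula (expected {k})")
        return eta

    def moments(self, x_years, male=0.0, version_idx=0,
                g_mu=0.0, g_sigma=0.0, d_nu=0.0):
        """True (mu, sigma, nu) at ages ``x_years`` post-conception."""
        eta_mu = self._eta(self.spec.mu, self.beta_mu, x_years, male,
                           version_idx) + g_mu
        eta_si = self._eta(self.spec.sigma, self.beta_sigma, x_years, male,
                           version_idx) + g_sigma
        return np.exp(eta_mu), np.exp(eta_si), self.alpha_nu + d_nu


def _log_quadratic_truth(phenotype, peak_age_years_pc, peak_value, curvature,
                         sex_effect, sigma0, nu, delta_mu, delta_sigma):
    """Second-order FP (repeated power 0): log mu = a + b1*L + b2*L^2."""
    Lp = np.log(peak_age_years_pc)
    b2 = -abs(curvature)
    b1 = -2.0 * b2 * Lp
    # sex-averaged peak equals peak_value
    a = np.log(peak_value) - (b1 * Lp + b2 * Lp ** 2) - sex_effect / 2.0
    spec = ModelSpec(
        phenotype=phenotype,
        mu=MomentFormula(fixed_covariates=("sex",),
                         fp=FractionalPolynomial((0.0, 0.0)),
                         random_study_intercept=True),
        sigma=MomentFormula(fixed_covariates=(),
                            fp=FractionalPolynomial(()),
                            random_study_intercept=True),
    )
    return TrueModel(
        spec=spec,
        beta_mu=(a, sex_effect, b1, b2),
        beta_sigma=(np.log(sigma0),),
        alpha_nu=nu,
        delta_mu=delta_mu,
        delta_sigma=delta_sigma,
    )


_PRESETS = {
    # peak ages in years post-conception (birth = 0.7666 y)
    "gmv_like": dict(phenotype="GMV", peak_age_years_pc=6.67,
                     peak_value=7.6e5, curvature=0.35, sex_effect=0.08,
                     sigma0=0.12, nu=0.7, delta_mu=0.08, delta_sigma=0.05),
    "wmv_like": dict(phenotype="WMV", peak_age_years_pc=29.5,
                     peak_value=5.2e5, curvature=0.22, sex_effect=0.10,
                     sigma0=0.10, nu=0.5, delta_mu=0.08, delta_sigma=0.05),
    "ct_like": dict(phenotype="CT", peak_age_years_pc=2.45,
                    peak_value=3.4, curvature=0.10, sex_effect=0.01,
                    sigma0=0.04, nu=0.3, delta_mu=0.03, delta_sigma=0.04),
}


def preset(name: str, **overrides) -> TrueModel:
    """A named true model ('gmv_like', 'wmv_like', 'ct_like')."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return _log_quadratic_truth(**kw)


def _rng(seed, *spawn):
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(spawn))
    return np.random.Generator(np.random.Philox(ss))


def _draw_ages(rng, n, age_range):
    lo, hi = age_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid age range {age_range}")
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def _assemble(truth, study, x_years, male, version_idx, g_mu, g_sigma, d_nu,
              rng, pid_prefix, dx="CN", session=1):
    mu, sigma, nu = truth.moments(x_years, male, version_idx, g_mu, g_sigma,
                                  d_nu)
    y = ggamma.sample_arrays(mu, sigma, np.full_like(mu, nu), rng)
    n = len(x_years)
    return pd.DataFrame({
        "participant_id": [f"{pid_prefix}{i:05d}" for i in range(n)],
        "study": study,
        "age_days": x_years * DAYS_PER_YEAR,
        "sex": np.where(male > 0, "M", "F"),
        "version": np.asarray(truth.version_levels)[version_idx],
        "dx": dx,
        "session": session,
        truth.spec.phenotype: y,
    })


def make_reference_cohort(truth: TrueModel, n_studies: int, n_per_study,
                          age_range=(0.315, 100.0), sex_ratio: float = 0.5,
                          seed=0) -> pd.DataFrame:
    """Multi-study cross-sectional reference cohort.

    Ages are log-uniform over ``age_range`` (years post-conception);
    per-study intercepts are drawn N(0, delta^2) on each link scale;
    ``n_per_study`` may be an int or a per-study sequence (unequal study
    sizes).  Fully reproducible from ``seed``.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    sizes = (np.full(n_studies, int(n_per_study))
             if np.isscalar(n_per_study) else np.asarray(n_per_study, int))
    if len(sizes) != n_studies or np.any(sizes < 1):
        raise ValueError("n_per_study must give a positive size per study")
    rng = _rng(seed)
    g_mu = rng.normal(0.0, truth.delta_mu, n_studies)
    g_sigma = rng.normal(0.0, truth.delta_sigma, n_studies)
    tables = []
    for s in range(n_studies):
        n = int(sizes[s])
        x = _draw_ages(rng, n, age_range)
        male = (rng.random(n) < (1.0 - sex_ratio)).astype(float)
        vidx = rng.integers(0, len(truth.version_levels), n)
        tables.append(_assemble(
            truth, f"S{s:03d}", x, male, vidx, g_mu[s], g_sigma[s], 0.0,
            rng, pid_prefix=f"S{s:03d}_"))
    return pd.concat(tables, ignore_index=True)


def make_new_study(truth: TrueModel, offsets, n: int, seed=0,
                   study: str = "NEW", age_range=(0.315, 100.0),
                   sex_ratio: float = 0.5, dx: str = "CN") -> pd.DataFrame:
    """A single out-of-sample study with *fixed* supplied offsets
    (d_mu, d_sigma, d_nu on the link scales) instead of sampled
    intercepts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    off = offsets if isinstance(offsets, dict) else {
        "d_mu": offsets.d_mu, "d_sigma": offsets.d_sigma,
        "d_nu": offsets.d_nu or 0.0}
    rng = _rng(seed)
    x = _draw_ages(rng, int(n), age_range)
    male = (rng.random(int(n)) < (1.0 - sex_ratio)).astype(float)
    vidx = np.zeros(int(n), dtype=int)
    return _assemble(truth, study, x, male, vidx,
                     float(off.get("d_mu", 0.0)),
                     float(off.get("d_sigma", 0.0)),
                     float(off.get("d_nu", 0.0) or 0.0),
                     rng, pid_prefix=f"{study}_", dx=dx)


def mu_shift_for_median_centile(truth: TrueModel, target: float) -> float:
    """Location-link shift that moves the median subject to the target
    centile of the unshifted population (inverts the outcome CDF)."""
    sigma0 = float(np.exp(truth.beta_sigma[0]))
    q_t = ggamma.quantile_arrays(target, 1.0, sigma0, truth.alpha_nu)
    q_m = ggamma.quantile_arrays(0.5, 1.0, sigma0, truth.alpha_nu)
    return float(np.log(q_t) - np.log(q_m))


def make_clinical_group(truth: TrueModel, n: int, target_median_centile: float,
                        seed=0, study: str = "CLIN", dx: str = "CASE",
                        age_range=(0.315, 100.0)) -> pd.DataFrame:
    """Cases whose location predictor is shifted so their median lands at
    the requested centile of the reference distribution."""
    d_mu = mu_shift_for_median_centile(truth, target_median_centile)
    return make_new_study(truth, {"d_mu": d_mu}, n, seed=seed, study=study,
                          dx=dx, age_range=age_range)


def make_longitudinal(truth: TrueModel, n_subjects: int, sessions: int,
                      drift_per_year: float = 0.0, seed=0,
                      study: str = "LONG", interval_years: float = 1.0,
                      noise_z: float = 0.05,
                      age_range=(5.0, 70.0)) -> pd.DataFrame:
    """Longitudinal cohort: each subject keeps a latent normative rank that
    drifts ``drift_per_year`` centile points per year (random direction per
    subject) plus small Gaussian jitter on the z scale; session ages are
    strictly increasing."""
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    rng = _rng(seed)
    rows = []
    for i in range(int(n_subjects)):
        x0 = float(_draw_ages(rng, 1, age_range)[0])
        male = float(rng.random() < 0.5)
        u0 = float(rng.uniform(0.02, 0.98))
        direction = 1.0 if rng.random() < 0.5 else -1.0
        for t in range(int(sessions)):
            x = x0 + t * interval_years
            u = np.clip(u0 + direction * drift_per_year * t * interval_years,
                        1e-4, 1 - 1e-4)
            z = special.ndtri(u) + rng.normal(0.0, noise_z)
            u_obs = float(special.ndtr(z))
            mu, sigma, nu = truth.moments(np.array([x]), male)
            y = float(ggamma.quantile_arrays(
                np.clip(u_obs, 1e-6, 1 - 1e-6), mu, sigma, nu)[0])
            rows.append({
                "participant_id": f"{study}_{i:05d}", "study": study,
                "age_days": x * DAYS_PER_YEAR,
                "sex": "M" if male else "F",
                "version": truth.version_levels[0], "dx": "CN",
                "session": t + 1, truth.spec.phenotype: y,
            })
    return pd.DataFrame(rows)


def make_twins(truth: TrueModel, n_pairs: int, ace=None, seed=0,
               age_years_pc: float = 10.0) -> pd.DataFrame:
    """Twin pairs for both zygosities under an ACE model.

    Latent standardized liabilities are bivariate normal with correlation
    a2 + c2 (MZ) and a2/2 + c2 (DZ); phenotypes are the generalized-gamma
    quantiles of the corresponding normal ranks at a fixed age, and the
    generating centiles are returned alongside.
    """
    a2, c2, e2 = ace if ace is not None else truth.ace
    if min(a2, c2, e2) < 0 or abs(a2 + c2 + e2 - 1.0) > 1e-9:
        raise ValueError("need nonnegative a2, c2, e2 summing to 1")
    rng = _rng(seed)
    rows = []
    for zyg, r in (("MZ", a2 + c2), ("DZ", 0.5 * a2 + c2)):
        e = rng.standard_normal((int(n_pairs), 2))
        # explicit bivariate-normal construction (valid at r = 1 exactly)
        z = np.column_stack(
            [e[:, 0], r * e[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * e[:, 1]])
        u = special.ndtr(z)
        male = (rng.random(int(n_pairs)) < 0.5).astype(float)
        mu, sigma, nu = truth.moments(np.array([age_years_pc]), 0.0)
        for i in range(int(n_pairs)):
            mu_i, sigma_i, nu_i = truth.moments(
                np.array([age_years_pc]), male[i])
            vals = ggamma.quantile_arrays(
                np.clip(u[i], 1e-6, 1 - 1e-6), mu_i, sigma_i, nu_i)
            rows.append({
                "pair_id": f"{zyg}_{i:05d}", "zygosity": zyg,
                "sex": "M" if male[i] else "F",
                "age_days": age_years_pc * DAYS_PER_YEAR,
                "value_1": float(vals[0]), "value_2": float(vals[1]),
                "centile_1": float(u[i, 0]), "centile_2": float(u[i, 1]),
            })
    return pd.DataFrame(rows)


def chart_from_truth(truth: TrueModel, age_support=(0.315, 100.0),
                     studies=("S000",)):
    """A GeneralizedGammaChart whose parameters equal the truth exactly
    (no fitting) — handy as an analytic oracle for trajectories and
    milestones."""
    from .design import CategoricalRegistry
    from .model import GeneralizedGammaChart

    est = GeneralizedGammaChart(spec=truth.spec)
    est.spec_ = truth.spec
    est.registry_ = CategoricalRegistry(
        sex_levels=("F", "M"),
        version_levels=tuple(truth.version_levels),
        study_levels=tuple(studies),
    )
    est.beta_mu_ = np.asarray(truth.beta_mu, dtype=float)
    est.beta_sigma_ = np.asarray(truth.beta_sigma, dtype=float)
    est.alpha_nu_ = float(truth.alpha_nu)
    est.gamma_mu_ = pd.Series(0.0, index=list(studies)) \
        if truth.spec.mu.random_study_intercept else pd.Series(dtype=float)
    est.gamma_sigma_ = pd.Series(0.0, index=list(studies)) \
        if truth.spec.sigma.random_study_intercept else pd.Series(dtype=float)
    est.delta2_mu_ = truth.delta_mu ** 2 or None
    est.delta2_sigma_ = truth.delta_sigma ** 2 or None
    est.age_support_ = tuple(age_support)
    est.converged_ = True
    return est


def z_shift_for_cohens_d(target_d: float) -> float:
    """Probit-scale shift delta such that centiles Phi(Z + delta) differ
    from Phi(Z) by Cohen's d = target_d (pooled SD), Z ~ N(0,1).

    Solved by quadrature + root finding; used to calibrate simulated
    case groups on the centile scale.
    """

    def moments(delta):
        f = lambda z: special.ndtr(z + delta) * np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
        f2 = lambda z: special.ndtr(z + delta) ** 2 * np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
        m = integrate.quad(f, -10, 10)[0]
        v = integrate.quad(f2, -10, 10)[0] - m ** 2
        return m, v

    m0, v0 = 0.5, 1.0 / 12.0

    def gap(delta):
        m, v = moments(delta)
        pooled = np.sqrt((v + v0) / 2.0)
        return (m - m0) / pooled - target_d

    return float(optimize.brentq(gap, 0.0, 6.0))
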