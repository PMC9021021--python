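"""Three-moment generalized-gamma chart estimator.

``GeneralizedGammaChart`` fits, by penalized maximum likelihood, a
distributional regression where the outcome follows a generalized gamma
whose location ``mu`` and scale ``sigma`` (log links) each get their own
linear predictor — fixed covariates, a fractional-polynomial age basis and
an optional per-study Gaussian random intercept — while the shape ``nu``
(identity link) is a free intercept.

Estimation cycles per-moment block updates (mu, then sigma, then nu),
treating random intercepts as ridge-penalized coefficients with penalty
``1/(2*delta2) * sum(gamma**2)``; the random-effect variance ``delta2`` is
refreshed each cycle by a Schall-type fixed point
``delta2 = sum(gamma**2) / sum(h_j)`` where ``h_j`` is the expected-
information leverage of study ``j``.  The outer loop stops when the
relative change of the penalized log-likelihood falls below ``tol``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator

from .design import (
    CategoricalRegistry,
    FractionalPolynomial,
    ModelSpec,
    MomentFormula,
    encode_design,
    fp_power_sets,
    validate_table,
)

__all__ = ["GeneralizedGammaChart", "fit", "select_model", "bootstrap_fit"]

_NU_TINY = 1e-12


def _gg_ll_vec(y_log, eta_mu, eta_sigma, nu):
    """Per-observation log-likelihood, cancellation-free for small ``nu``.

    Uses ll = log|nu| + C(theta) - theta*(expm1(u) - u) - log(y) with
    C(theta) = theta*log(theta) - theta - lgamma(theta) and u = nu * r,
    r = log(y) - eta_mu, theta = exp(-2*eta_sigma)/nu**2.
    """
    r = y_log - eta_mu
    sigma2 = np.exp(2.0 * eta_sigma)
    if abs(nu) < _NU_TINY:  # exact log-normal limit
        return (
            -y_log - eta_sigma - 0.5 * np.log(2 * np.pi) - 0.5 * r * r / sigma2
        )
    theta = 1.0 / (sigma2 * nu * nu)
    # cap the exponent argument: keeps wildly wrong trial points (seen only
    # inside line searches) finite without touching any realistic optimum
    u = np.clip(nu * r, -200.0, 200.0)
    big = theta >= 1e8
    c = np.empty_like(theta)
    if np.any(~big):
        t = theta[~big]
        c[~big] = t * np.log(t) - t - special.gammaln(t)
    if np.any(big):  # Stirling series, avoids catastrophic cancellation
        t = theta[big]
        c[big] = (
            -0.5 * np.log(2 * np.pi) + 0.5 * np.log(t) - 1.0 / (12.0 * t)
            + 1.0 / (360.0 * t ** 3)
        )
    return np.log(abs(nu)) + c - theta * (np.expm1(u) - u) - y_log


def _gg_grad_eta_mu(y_log, eta_mu, eta_sigma, nu):
    """d ll / d eta_mu  =  expm1(nu*r) / (sigma^2 * nu)."""
    r = y_log - eta_mu
    sigma2 = np.exp(2.0 * eta_sigma)
    if abs(nu) < _NU_TINY:
        return r / sigma2
    return np.expm1(np.clip(nu * r, -200.0, 200.0)) / (sigma2 * nu)


def _gg_grad_eta_sigma(y_log, eta_mu, eta_sigma, nu):
    """d ll / d eta_sigma = -2*theta*[(log theta - psi(theta)) - (expm1(u)-u)]."""
    r = y_log - eta_mu
    sigma2 = np.exp(2.0 * eta_sigma)
    if abs(nu) < _NU_TINY:
        return r * r / sigma2 - 1.0
    theta = 1.0 / (sigma2 * nu * nu)
    u = np.clip(nu * r, -200.0, 200.0)
    big = theta >= 1e8
    dpsi = np.empty_like(theta)
    if np.any(~big):
        t = theta[~big]
        dpsi[~big] = np.log(t) - special.digamma(t)
    if np.any(big):
        t = theta[big]
        dpsi[big] = 1.0 / (2.0 * t) + 1.0 / (12.0 * t * t)
    return -2.0 * theta * (dpsi - (np.expm1(u) - u))


def _fisher_w_mu(eta_sigma, nu):
    """Expected information per observation on the eta_mu scale: 1/sigma^2."""
    return np.exp(-2.0 * eta_sigma)


def _fisher_w_sigma(eta_sigma, nu):
    """Expected information on the eta_sigma scale: 4*theta^2*(psi'(theta)-1/theta)."""
    sigma2 = np.exp(2.0 * eta_sigma)
    if abs(nu) < _NU_TINY:
        return np.full_like(sigma2, 2.0)
    theta = 1.0 / (sigma2 * nu * nu)
    big = theta >= 1e7
    w = np.empty_like(theta)
    if np.any(~big):
        t = theta[~big]
        w[~big] = 4.0 * t * t * (special.polygamma(1, t) - 1.0 / t)
    if np.any(big):
        t = theta[big]
        w[big] = 2.0 + 2.0 / (3.0 * t)
    return w


def _check_full_rank(X, names):
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design matrix; collinear column(s): {bad}")


class GeneralizedGammaChart(BaseEstimator):
    """Normative growth-chart estimator for one positive phenotype.

    Parameters
    ----------
    spec : ModelSpec
        Per-moment formulas (covariates, fractional-polynomial powers,
        random study intercepts).
    tol : float
        Relative penalized log-likelihood change for outer convergence.
    max_iter : int
        Maximum outer cycles.
    inner_maxiter : int
        L-BFGS iteration cap per block update.
    nu_bounds : tuple
        Box for the shape intercept.
    age_floor : float
        Minimum accepted age in days post-conception.

    Fitted attributes (trailing underscore) follow scikit-learn
    conventions: ``beta_mu_``, ``se_mu_``, ``gamma_mu_`` (pandas Series
    indexed by study), ``delta2_mu_``, the sigma equivalents, ``alpha_nu_``,
    ``loglik_``, ``bic_``, ``converged_`` and the categorical
    ``registry_``.
    """

    def __init__(self, spec: ModelSpec | None = None, *, tol: float = 1e-6,
                 max_iter: int = 200, inner_maxiter: int = 200,
                 inner_gtol: float = 1e-8, nu_bounds: tuple = (-5.0, 5.0),
                 age_floor: float = 80.0):
        self.spec = spec
        self.tol = tol
        self.max_iter = max_iter
        self.inner_maxiter = inner_maxiter
        self.inner_gtol = inner_gtol
        self.nu_bounds = nu_bounds
        self.age_floor = age_floor

    # -- internal -----------------------------------------------------------

    def _penalized_ll(self, y_log, eta_mu, eta_sigma, nu, g_mu, g_sigma,
                      d2_mu, d2_sigma):
        ll = float(np.sum(_gg_ll_vec(y_log, eta_mu, eta_sigma, nu)))
        pen = 0.0
        if g_mu.size and d2_mu is not None:
            pen += float(np.sum(g_mu ** 2)) / (2.0 * d2_mu)
        if g_sigma.size and d2_sigma is not None:
            pen += float(np.sum(g_sigma ** 2)) / (2.0 * d2_sigma)
        return ll - pen

    def _solve_block(self, y_log, X, Z, b0, g0, eta_other, nu, delta2,
                     which):
        """Maximize the penalized ll over one moment's [beta, gamma]."""
        p, m = X.shape[1], Z.shape[1]
        grad_fn = _gg_grad_eta_mu if which == "mu" else _gg_grad_eta_sigma

        def negobj(v):
            beta, gamma = v[:p], v[p:]
            eta = X @ beta
            if m:
                eta = eta + Z @ gamma
            if which == "mu":
                ll = _gg_ll_vec(y_log, eta, eta_other, nu)
                d = grad_fn(y_log, eta, eta_other, nu)
            else:
                ll = _gg_ll_vec(y_log, eta_other, eta, nu)
                d = grad_fn(y_log, eta_other, eta, nu)
            f = -float(np.sum(ll))
            g = np.empty_like(v)
            g[:p] = -(X.T @ d)
            if m:
                g[p:] = -(Z.T @ d) + gamma / delta2
                f += float(np.sum(gamma ** 2)) / (2.0 * delta2)
            if not np.isfinite(f):  # wildly wrong trial point in line search
                f = 1e300
                g = np.nan_to_num(g, nan=0.0, posinf=1e150, neginf=-1e150)
            return f, g

        v0 = np.concatenate([b0, g0])
        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.minimize(
                negobj, v0, jac=True, method="L-BFGS-B",
                options={"maxiter": self.inner_maxiter, "ftol": 1e-13,
                         "gtol": self.inner_gtol},
            )
        v = res.x
        beta, gamma = v[:p].copy(), v[p:].copy()
        if m:  # re-center random intercepts into the (first) intercept column
            mean_g = gamma.mean()
            gamma -= mean_g
            beta[0] += mean_g
        return beta, gamma

    # -- API ----------------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None):
        """Fit the chart to a per-scan phenotype table."""
        if self.spec is None:
            raise ValueError("a ModelSpec is required")
        spec = self.spec
        validate_table(data, phenotype=spec.phenotype, age_floor=self.age_floor)
        registry = CategoricalRegistry.from_table(data)
        X_mu, Z_mu, names_mu = encode_design(data, spec.mu, registry,
                                             age_floor=self.age_floor)
        X_si, Z_si, names_si = encode_design(data, spec.sigma, registry,
                                             age_floor=self.age_floor)
        _check_full_rank(X_mu, names_mu)
        _check_full_rank(X_si, names_si)
        n_studies = len(registry.study_levels)
        if (Z_mu.shape[1] or Z_si.shape[1]) and n_studies < 2:
            raise ValueError(
                "at least 2 studies are required to fit a random study intercept"
            )

        yv = data[spec.phenotype].to_numpy(dtype=float)
        y_log = np.log(yv)
        study_codes = (
            pd.Categorical(data["study"].astype(str),
                           categories=registry.study_levels).codes
        )

        # deterministic scale-aware starting values
        b_mu = np.zeros(X_mu.shape[1])
        b_mu[0] = float(np.log(np.median(yv)))
        b_si = np.zeros(X_si.shape[1])
        mad = float(np.median(np.abs(y_log - np.median(y_log)))) * 1.4826
        b_si[0] = float(np.log(max(mad, 1e-3)))
        nu = 1.0
        g_mu = np.zeros(Z_mu.shape[1])
        g_si = np.zeros(Z_si.shape[1])
        d2_mu = 0.01 if Z_mu.shape[1] else None
        d2_si = 0.01 if Z_si.shape[1] else None

        def etas():
            em = X_mu @ b_mu + (Z_mu @ g_mu if g_mu.size else 0.0)
            es = X_si @ b_si + (Z_si @ g_si if g_si.size else 0.0)
            return em, es

        history = []
        prev = -np.inf
        converged = False
        n_iter = 0
        for it in range(self.max_iter):
            n_iter = it + 1
            em, es = etas()
            pre = self._penalized_ll(y_log, em, es, nu, g_mu, g_si, d2_mu, d2_si)

            b_mu, g_mu = self._solve_block(
                y_log, X_mu, Z_mu, b_mu, g_mu, es, nu, d2_mu, "mu")
            em = X_mu @ b_mu + (Z_mu @ g_mu if g_mu.size else 0.0)
            b_si, g_si = self._solve_block(
                y_log, X_si, Z_si, b_si, g_si, em, nu, d2_si, "sigma")
            es = X_si @ b_si + (Z_si @ g_si if g_si.size else 0.0)

            res = optimize.minimize_scalar(
                lambda v: -float(np.sum(_gg_ll_vec(y_log, em, es, v))),
                bounds=self.nu_bounds, method="bounded",
                options={"xatol": 1e-8},
            )
            nu = float(res.x)

            post = self._penalized_ll(y_log, em, es, nu, g_mu, g_si, d2_mu, d2_si)
            history.append((pre, post))

            # Schall fixed-point update of the random-effect variances
            if g_mu.size:
                w = _fisher_w_mu(es, nu)
                S = np.bincount(study_codes, weights=w, minlength=n_studies)
                h = S * d2_mu / (S * d2_mu + 1.0)
                d2_mu = float(np.clip(np.sum(g_mu ** 2) / max(np.sum(h), 1e-12),
                                      1e-8, 25.0))
            if g_si.size:
                w = _fisher_w_sigma(es, nu)
                S = np.bincount(study_codes, weights=w, minlength=n_studies)
                h = S * d2_si / (S * d2_si + 1.0)
                d2_si = float(np.clip(np.sum(g_si ** 2) / max(np.sum(h), 1e-12),
                                      1e-8, 25.0))

            if np.isfinite(prev) and abs(post - prev) <= self.tol * (
                    abs(prev) + 1e-8):
                converged = True
                break
            prev = post

        em, es = etas()
        ll = float(np.sum(_gg_ll_vec(y_log, em, es, nu)))
        n_params = (X_mu.shape[1] + X_si.shape[1] + 1
                    + int(bool(g_mu.size)) + int(bool(g_si.size)))
        n_obs = len(yv)

        # information-based standard errors for the fixed effects
        self.se_mu_ = self._block_se(X_mu, Z_mu, _fisher_w_mu(es, nu), d2_mu)
        self.se_sigma_ = self._block_se(X_si, Z_si, _fisher_w_sigma(es, nu),
                                        d2_si)

        self.spec_ = spec
        self.registry_ = registry
        self.beta_mu_ = b_mu
        self.beta_sigma_ = b_si
        self.coef_names_mu_ = names_mu
        self.coef_names_sigma_ = names_si
        self.alpha_nu_ = float(nu)
        self.gamma_mu_ = pd.Series(g_mu, index=list(registry.study_levels)) \
            if g_mu.size else pd.Series(dtype=float)
        self.gamma_sigma_ = pd.Series(g_si, index=list(registry.study_levels)) \
            if g_si.size else pd.Series(dtype=float)
        self.delta2_mu_ = d2_mu
        self.delta2_sigma_ = d2_si
        self.loglik_ = ll
        self.n_obs_ = n_obs
        self.n_params_ = n_params
        self.bic_ = -2.0 * ll + n_params * np.log(n_obs)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.history_ = history
        x_years = data["age_days"].to_numpy(dtype=float) / 365.25
        self.age_support_ = (float(x_years.min()), float(x_years.max()))
        return self

    @staticmethod
    def _block_se(X, Z, w, delta2):
        p, m = X.shape[1], Z.shape[1]
        D = np.column_stack([X, Z]) if m else X
        A = D.T @ (D * w[:, None])
        if m:
            A[p:, p:] += np.eye(m) / delta2
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(A)
        return np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))

    # -- prediction ---------------------------------------------------------

    def _linear_predictors(self, rows: pd.DataFrame, mode):
        from .scoring import StudyOffset  # local import to avoid a cycle

        X_mu, _, _ = encode_design(rows, MomentFormula(
            fixed_covariates=self.spec_.mu.fixed_covariates,
            fp=self.spec_.mu.fp, random_study_intercept=False, link="log"),
            self.registry_, age_floor=self.age_floor)
        X_si, _, _ = encode_design(rows, MomentFormula(
            fixed_covariates=self.spec_.sigma.fixed_covariates,
            fp=self.spec_.sigma.fp, random_study_intercept=False, link="log"),
            self.registry_, age_floor=self.age_floor)
        eta_mu = X_mu @ self.beta_mu_
        eta_si = X_si @ self.beta_sigma_
        nu = np.full(len(rows), self.alpha_nu_)

        if mode == "population":
            pass
        elif mode == "study":
            studies = rows["study"].astype(str)
            unknown = set(studies) - set(self.registry_.study_levels)
            if unknown:
                raise ValueError(
                    f"unknown study level(s) {sorted(unknown)} in known-study "
                    "mode; use offset mode (fit_new_study_offsets) for "
                    "out-of-sample studies"
                )
            if len(self.gamma_mu_):
                eta_mu = eta_mu + self.gamma_mu_.reindex(studies).to_numpy()
            if len(self.gamma_sigma_):
                eta_si = eta_si + self.gamma_sigma_.reindex(studies).to_numpy()
        elif isinstance(mode, StudyOffset) or isinstance(mode, dict):
            off = mode if isinstance(mode, dict) else {
                "d_mu": mode.d_mu, "d_sigma": mode.d_sigma, "d_nu": mode.d_nu}
            eta_mu = eta_mu + float(off.get("d_mu", 0.0))
            eta_si = eta_si + float(off.get("d_sigma", 0.0))
            d_nu = off.get("d_nu", 0.0)
            if d_nu is not None:
                nu = nu + float(d_nu)
        else:
            raise ValueError(f"unknown prediction mode {mode!r}")
        return eta_mu, eta_si, nu

    def predict_moments(self, rows: pd.DataFrame, mode="population"):
        """Per-row (mu, sigma, nu) under population / known-study / offset
        mode; returns a DataFrame with columns mu, sigma, nu."""
        eta_mu, eta_si, nu = self._linear_predictors(rows, mode)
        return pd.DataFrame(
            {"mu": np.exp(eta_mu), "sigma": np.exp(eta_si), "nu": nu},
            index=rows.index,
        )

    def transform(self, data: pd.DataFrame, mode="population"):
        """Centile scores (see :func:`normcharts.scoring.centile_score`)."""
        from .scoring import centile_score

        return centile_score(self, data, mode=mode)


# ---------------------------------------------------------------------------
# module-level wrappers (thin, sklearn-style estimator underneath)


def fit(data: pd.DataFrame, spec: ModelSpec, **options) -> GeneralizedGammaChart:
    """Fit a generalized-gamma chart; thin wrapper over the estimator."""
    return GeneralizedGammaChart(spec=spec, **options).fit(data)


def _rank_key(item):
    spec, bic, n_params, ok = item
    return (
        not ok,                      # failures last
        round(bic, 9),
        n_params,
        spec.mu.fp.powers,
        spec.sigma.fp.powers,
    )


def select_model(data: pd.DataFrame, candidate_space, options=None):
    """Staged BIC search over fractional-polynomial power multisets.

    ``candidate_space`` is a dict with keys ``phenotype``, optional
    ``mu_powers`` / ``sigma_powers`` (iterables of power tuples; default
    the full order-0..3 space), optional ``mu_covariates`` /
    ``sigma_covariates`` and ``random_mu`` / ``random_sigma`` booleans.

    Stage 1 searches mu powers with sigma intercept-only; stage 2 searches
    sigma powers at the best mu.  Returns a list of (ModelSpec, bic) ranked
    ascending by BIC, ties broken by fewer parameters then lexicographic
    powers; candidates that fail to converge rank last.
    """
    options = dict(options or {})
    phen = candidate_space["phenotype"]
    mu_pows = list(candidate_space.get("mu_powers", fp_power_sets()))
    si_pows = list(candidate_space.get("sigma_powers", [()]))
    mu_cov = tuple(candidate_space.get("mu_covariates", ("sex",)))
    si_cov = tuple(candidate_space.get("sigma_covariates", ()))
    rand_mu = bool(candidate_space.get("random_mu", False))
    rand_si = bool(candidate_space.get("random_sigma", False))
    if not mu_pows:
        raise ValueError("candidate space is empty")

    def make_spec(mp, sp):
        return ModelSpec(
            phenotype=phen,
            mu=MomentFormula(fixed_covariates=mu_cov,
                             fp=FractionalPolynomial(mp),
                             random_study_intercept=rand_mu),
            sigma=MomentFormula(fixed_covariates=si_cov,
                                fp=FractionalPolynomial(sp),
                                random_study_intercept=rand_si),
        )

    def fit_one(spec):
        try:
            est = GeneralizedGammaChart(spec=spec, **options).fit(data)
            return est.bic_, est.n_params_, est.converged_
        except Exception:
            return np.inf, np.inf, False

    stage1 = []
    for mp in mu_pows:
        spec = make_spec(mp, ())
        bic, npar, ok = fit_one(spec)
        stage1.append((spec, bic, npar, ok))
    stage1.sort(key=_rank_key)
    best_mu = stage1[0][0].mu.fp.powers

    results = list(stage1)
    for sp in si_pows:
        if sp == ():
            continue
        spec = make_spec(best_mu, sp)
        bic, npar, ok = fit_one(spec)
        results.append((spec, bic, npar, ok))
    results.sort(key=_rank_key)
    return [(spec, bic) for spec, bic, _, _ in results]


def bootstrap_fit(data: pd.DataFrame, spec: ModelSpec, B: int, seed,
                  **options) -> list:
    """Sex- and study-stratified participant bootstrap refits.

    Each replicate resamples participants with replacement within every
    (study, sex) stratum, then refits; replicate ``b`` is reproducible
    from ``(seed, b)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fits = []
    for b in range(int(B)):
        resampled = resample_participants(data, seed, b)
        est = GeneralizedGammaChart(spec=spec, **options).fit(resampled)
        fits.append(est)
    return fits


def resample_participants(data: pd.DataFrame, seed, index: int) -> pd.DataFrame:
    """One stratified bootstrap resample, deterministic in (seed, index)."""
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=int(seed),
                                                spawn_key=(int(index),)))
    )
    pieces = []
    for (_, _), grp in data.groupby(["study", "sex"], sort=True):
        pids = grp["participant_id"].unique()
        chosen = rng.choice(pids, size=len(pids), replace=True)
        by_pid = dict(tuple(grp.groupby("participant_id", sort=False)))
        pieces.extend(by_pid[p] for p in chosen)
    return pd.concat(pieces, ignore_index=True)
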