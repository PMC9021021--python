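"""Downstream cohort statistics on centile scores.

* Centile Mahalanobis distance (CMD): a scan's aggregate multivariate
  atypicality — the sum of its absolute SD-standardized distances from the
  control-group mean along the control group's principal axes.  A
  Euclidean (classical Mahalanobis) variant is available behind a flag.
* Case-control tests: pairwise Monte Carlo permutation tests on group
  medians with Benjamini-Hochberg FDR across pairs, Cohen's d from the
  pooled SD, and a bootstrapped Welch-type omnibus statistic.
* Longitudinal stability: subject-level IQR of centiles across timepoints.
* Twin heritability: Falconer's h2 = 2 (r_MZ - r_DZ) from double-entered
  pair correlations, with a pair-bootstrap percentile CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CMDReference",
    "CMDResult",
    "CentileDeviation",
    "cmd_reference",
    "cmd_score",
    "permutation_median_test",
    "welch_f",
    "welch_anova_bootstrap",
    "case_control_tests",
    "cohens_d",
    "longitudinal_iqr",
    "twin_correlation",
    "twin_h2",
]


# ---------------------------------------------------------------------------
# centile Mahalanobis distance


@dataclass
class CMDReference:
    """Control-group summary: mean vector, principal axes (rows), axis SDs."""

    mean: np.ndarray
    axes: np.ndarray
    sds: np.ndarray
    n_dropped: int = 0


@dataclass
class CMDResult:
    cmd: float
    component_scores: np.ndarray


def cmd_reference(cn_centiles) -> CMDReference:
    """Principal axes of the control-group centile covariance.

    Axes are ordered by decreasing variance with the sign fixed so the
    largest-magnitude loading is positive; near-zero-variance axes are
    dropped with a warning.
    """
    X = np.asarray(cn_centiles, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a subjects x phenotypes matrix with >= 2 phenotypes")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 control subjects")
    if np.any(~np.isfinite(X)):
        raise ValueError("control centile matrix contains missing values")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(evals.max(), 0.0) * 1e-10 + 1e-15
    keep = evals > tol
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} near-zero-variance principal axis/axes")
    evals, evecs = evals[keep], evecs[:, keep]
    axes = evecs.T
    for k in range(axes.shape[0]):  # largest-loading-positive sign convention
        j = np.argmax(np.abs(axes[k]))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    return CMDReference(mean=mean, axes=axes, sds=np.sqrt(evals),
                        n_dropped=n_dropped)


def cmd_score(reference: CMDReference, subject_centiles,
              euclidean: bool = False) -> CMDResult:
    """CMD of one subject: sum over axes of |projection| / axis SD.

    With ``euclidean=True`` the classical Mahalanobis form
    sqrt(sum of squared components) is returned instead of the absolute
    sum.
    """
    x = np.asarray(subject_centiles, dtype=float)
    if x.shape != reference.mean.shape:
        raise ValueError(
            f"subject vector has dimension {x.shape}, reference expects "
            f"{reference.mean.shape}")
    proj = reference.axes @ (x - reference.mean)
    comps = np.abs(proj) / reference.sds
    cmd = float(np.sqrt(np.sum(comps ** 2))) if euclidean \
        else float(np.sum(comps))
    return CMDResult(cmd=cmd, component_scores=comps)


class CentileDeviation(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: fit on control centiles, transform scans
    to CMD values."""

    def __init__(self, euclidean: bool = False):
        self.euclidean = euclidean

    def fit(self, X, y=None):
        self.reference_ = cmd_reference(X)
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([
            cmd_score(self.reference_, row, euclidean=self.euclidean).cmd
            for row in X
        ])


# ---------------------------------------------------------------------------
# case-control inference


def permutation_median_test(x, y, n_perm: int, rng) -> tuple:
    """Two-sided Monte Carlo permutation test on the difference in medians.

    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_obs = float(np.median(x) - np.median(y))
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    idx = np.tile(np.arange(n), (int(n_perm), 1))
    idx = rng.permuted(idx, axis=1)
    perm = pooled[idx]
    t_perm = np.median(perm[:, :nx], axis=1) - np.median(perm[:, nx:], axis=1)
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs))) / (1.0 + n_perm)
    return t_obs, float(p)


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2)
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2))


def welch_f(groups) -> float:
    """Welch's heteroscedastic one-way F statistic."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = 1.0 + (2.0 * (k - 2) / (k ** 2 - 1)) * np.sum(
        (1 - w / np.sum(w)) ** 2 / (n - 1))
    return float(a / b)


def welch_anova_bootstrap(values, labels, n_boot: int = 500, seed=0) -> dict:
    """Welch-type omnibus test with a bootstrap null (documented stand-in).

    Groups are centred to a common mean to impose the null, then resampled
    within group with replacement ``n_boot`` times;
    p = (1 + #{F* >= F_obs}) / (1 + n_boot).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    f_obs = welch_f(groups)
    rng = np.random.Generator(np.random.Philox(seed))
    centred = [g - g.mean() for g in groups]
    count = 0
    for _ in range(int(n_boot)):
        boot = [g[rng.integers(0, g.size, g.size)] for g in centred]
        if any(b.var(ddof=1) == 0 for b in boot):
            count += 1  # degenerate resample counts against rejection
            continue
        if welch_f(boot) >= f_obs:
            count += 1
    return {"F": f_obs, "p": (1.0 + count) / (1.0 + n_boot),
            "n_boot": int(n_boot)}


def case_control_tests(centiles: pd.DataFrame, *, phenotype: str = "centile",
                       group_col: str = "dx", sex_col: str = "sex",
                       reference: str = "CN", n_perm: int = 10_000,
                       n_boot: int = 500, seed=0) -> pd.DataFrame:
    """Sex-stratified case-control comparisons of centile scores.

    For every (sex, case group) pair against the reference group:
    difference in medians, Cohen's d (pooled SD), two-sided Monte Carlo
    permutation p and Benjamini-Hochberg q across all pairs within the
    phenotype x sex stratum; plus one omnibus bootstrapped Welch-type row
    per sex.  Groups with fewer than 2 scans are excluded with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.Generator(np.random.Philox(seed))
    rows = []
    for sex, sub in centiles.groupby(sex_col, sort=True):
        vals = sub[phenotype].to_numpy(dtype=float)
        labels = sub[group_col].to_numpy()
        cn = vals[labels == reference]
        if cn.size < 2:
            warnings.warn(f"reference group {reference!r} too small for sex {sex}")
            continue
        pair_rows = []
        for grp in sorted(set(labels) - {reference}):
            case = vals[labels == grp]
            if case.size < 2:
                warnings.warn(f"group {grp!r} (sex {sex}) has n < 2; excluded")
                continue
            t_obs, p = permutation_median_test(case, cn, n_perm, rng)
            pair_rows.append({
                "sex": sex, "group": grp, "reference": reference,
                "n_case": case.size, "n_ref": cn.size,
                "median_diff": t_obs, "cohens_d": cohens_d(case, cn),
                "p": p,
            })
        if pair_rows:
            q = multipletests([r["p"] for r in pair_rows],
                              method="fdr_bh")[1]
            for r, qi in zip(pair_rows, q):
                r["q"] = float(qi)
            rows.extend(pair_rows)
            groups_here = [g for g in pd.unique(labels)
                           if (labels == g).sum() >= 2]
            if len(groups_here) >= 2:
                om = welch_anova_bootstrap(
                    vals[np.isin(labels, groups_here)],
                    labels[np.isin(labels, groups_here)],
                    n_boot=n_boot, seed=rng.integers(0, 2 ** 31 - 1))
                rows.append({
                    "sex": sex, "group": "(omnibus)", "reference": "all",
                    "n_case": int(np.isin(labels, groups_here).sum()),
                    "n_ref": cn.size, "median_diff": np.nan,
                    "cohens_d": np.nan, "p": om["p"], "q": np.nan,
                    "welch_F": om["F"],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# longitudinal stability


def longitudinal_iqr(centiles: pd.DataFrame, *, subject_col: str = "participant_id",
                     value_col: str = "centile") -> tuple:
    """Per-subject IQR (Q3 - Q1, linear-interpolation quantiles) of
    centiles across timepoints; subjects with a single session are
    excluded and counted."""
    counts = centiles.groupby(subject_col)[value_col].count()
    keep = counts[counts >= 2].index
    n_excluded = int((counts < 2).sum())
    sub = centiles[centiles[subject_col].isin(keep)]
    iqr = sub.groupby(subject_col)[value_col].agg(
        lambda v: np.percentile(v, 75) - np.percentile(v, 25))
    iqr.name = "iqr"
    return iqr, n_excluded


# ---------------------------------------------------------------------------
# twin heritability


def twin_correlation(pairs) -> float:
    """Double-entered (intraclass-style) Pearson correlation of twin pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    a = np.concatenate([pairs[:, 0], pairs[:, 1]])
    b = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate (zero-variance) twin data")
    return float(np.corrcoef(a, b)[0, 1])


def twin_h2(mz_pairs, dz_pairs, B: int = 1000, seed=0) -> dict:
    """Falconer heritability h2 = clamp(2 (r_MZ - r_DZ), 0, 1) with a
    pair-bootstrap percentile CI."""
    mz = np.asarray(mz_pairs, dtype=float)
    dz = np.asarray(dz_pairs, dtype=float)
    if len(mz) < 10 or len(dz) < 10:
        raise ValueError("need at least 10 pairs per zygosity")
    r_mz = twin_correlation(mz)
    r_dz = twin_correlation(dz)
    h2 = float(np.clip(2.0 * (r_mz - r_dz), 0.0, 1.0))
    rng = np.random.Generator(np.random.Philox(seed))
    boots = []
    for _ in range(int(B)):
        bm = mz[rng.integers(0, len(mz), len(mz))]
        bd = dz[rng.integers(0, len(dz), len(dz))]
        try:
            boots.append(np.clip(
                2.0 * (twin_correlation(bm) - twin_correlation(bd)), 0.0, 1.0))
        except ValueError:
            continue
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots
              else (np.nan, np.nan))
    return {"h2": h2, "r_mz": r_mz, "r_dz": r_dz,
            "ci_low": float(lo), "ci_high": float(hi), "B": int(B)}
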