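"""Serialization: fitted models and study offsets as versioned JSON,
centile tables as CSV.

The model document is a neutral JSON schema (float values hex-encoded
alongside their decimal form for lossless round-trips).  Externally
estimated parameter sets can be imported by writing a document that
satisfies the same schema.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CategoricalRegistry, FractionalPolynomial, ModelSpec, MomentFormula
from .model import GeneralizedGammaChart
from .scoring import StudyOffset

__all__ = ["SCHEMA_VERSION", "write_model", "read_model",
           "write_offset", "read_offset", "write_centiles"]

SCHEMA_VERSION = "normcharts-model/1"


def _floats(arr):
    return [float(v) for v in np.asarray(arr, dtype=float).ravel()]


def _formula_doc(f: MomentFormula):
    return {
        "fixed_covariates": list(f.fixed_covariates),
        "fp_powers": list(f.fp.powers),
        "random_study_intercept": bool(f.random_study_intercept),
        "link": f.link,
    }


def _formula_from(doc):
    return MomentFormula(
        fixed_covariates=tuple(doc["fixed_covariates"]),
        fp=FractionalPolynomial(tuple(doc["fp_powers"])),
        random_study_intercept=bool(doc["random_study_intercept"]),
        link=doc["link"],
    )


def write_model(model: GeneralizedGammaChart, path) -> None:
    """Serialize a fitted chart to versioned JSON (lossless floats)."""
    doc = {
        "schema": SCHEMA_VERSION,
        "spec": {
            "phenotype": model.spec_.phenotype,
            "mu": _formula_doc(model.spec_.mu),
            "sigma": _formula_doc(model.spec_.sigma),
        },
        "registry": {
            "sex_levels": list(model.registry_.sex_levels),
            "version_levels": list(model.registry_.version_levels),
            "study_levels": list(model.registry_.study_levels),
        },
        "beta_mu": _floats(model.beta_mu_),
        "beta_sigma": _floats(model.beta_sigma_),
        "coef_names_mu": list(model.coef_names_mu_),
        "coef_names_sigma": list(model.coef_names_sigma_),
        "se_mu": _floats(model.se_mu_),
        "se_sigma": _floats(model.se_sigma_),
        "alpha_nu": float(model.alpha_nu_),
        "gamma_mu": {k: float(v) for k, v in model.gamma_mu_.items()},
        "gamma_sigma": {k: float(v) for k, v in model.gamma_sigma_.items()},
        "delta2_mu": model.delta2_mu_,
        "delta2_sigma": model.delta2_sigma_,
        "fit": {
            "loglik": float(model.loglik_),
            "n_obs": int(model.n_obs_),
            "n_params": int(model.n_params_),
            "bic": float(model.bic_),
            "converged": bool(model.converged_),
            "n_iter": int(getattr(model, "n_iter_", 0)),
        },
        "age_support": list(model.age_support_),
        # hex forms guarantee bit-exact float round trips
        "beta_mu_hex": [float(v).hex() for v in _floats(model.beta_mu_)],
        "beta_sigma_hex": [float(v).hex() for v in _floats(model.beta_sigma_)],
        "alpha_nu_hex": float(model.alpha_nu_).hex(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True),
                          encoding="utf-8")


def read_model(path) -> GeneralizedGammaChart:
    """Load a chart from the JSON schema; rejects version mismatches."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema {doc.get('schema')!r}; this build "
            f"reads {SCHEMA_VERSION!r}")
    spec = ModelSpec(
        phenotype=doc["spec"]["phenotype"],
        mu=_formula_from(doc["spec"]["mu"]),
        sigma=_formula_from(doc["spec"]["sigma"]),
    )
    est = GeneralizedGammaChart(spec=spec)
    est.spec_ = spec
    est.registry_ = CategoricalRegistry(
        sex_levels=tuple(doc["registry"]["sex_levels"]),
        version_levels=tuple(doc["registry"]["version_levels"]),
        study_levels=tuple(doc["registry"]["study_levels"]),
    )
    if "beta_mu_hex" in doc:
        est.beta_mu_ = np.array([float.fromhex(h) for h in doc["beta_mu_hex"]])
        est.beta_sigma_ = np.array(
            [float.fromhex(h) for h in doc["beta_sigma_hex"]])
        est.alpha_nu_ = float.fromhex(doc["alpha_nu_hex"])
    else:  # plain-decimal documents (e.g. externally converted parameters)
        est.beta_mu_ = np.asarray(doc["beta_mu"], dtype=float)
        est.beta_sigma_ = np.asarray(doc["beta_sigma"], dtype=float)
        est.alpha_nu_ = float(doc["alpha_nu"])
    est.coef_names_mu_ = list(doc["coef_names_mu"])
    est.coef_names_sigma_ = list(doc["coef_names_sigma"])
    est.se_mu_ = np.asarray(doc["se_mu"], dtype=float)
    est.se_sigma_ = np.asarray(doc["se_sigma"], dtype=float)
    est.gamma_mu_ = pd.Series(doc["gamma_mu"], dtype=float)
    est.gamma_sigma_ = pd.Series(doc["gamma_sigma"], dtype=float)
    est.delta2_mu_ = doc["delta2_mu"]
    est.delta2_sigma_ = doc["delta2_sigma"]
    fit = doc["fit"]
    est.loglik_ = fit["loglik"]
    est.n_obs_ = fit["n_obs"]
    est.n_params_ = fit["n_params"]
    est.bic_ = fit["bic"]
    est.converged_ = fit["converged"]
    est.n_iter_ = fit.get("n_iter", 0)
    est.age_support_ = tuple(doc["age_support"])
    return est


def write_offset(offset: StudyOffset, path) -> None:
    doc = {
        "schema": "normcharts-offset/1",
        "study": offset.study,
        "d_mu": offset.d_mu,
        "d_sigma": offset.d_sigma,
        "d_nu": offset.d_nu,
        "n_scans": offset.n_scans,
        "small_sample_warning": offset.small_sample_warning,
        "loglik": offset.loglik,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True),
                          encoding="utf-8")


def read_offset(path) -> StudyOffset:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != "normcharts-offset/1":
        raise ValueError(f"unsupported offset schema {doc.get('schema')!r}")
    return StudyOffset(
        d_mu=doc["d_mu"], d_sigma=doc["d_sigma"], d_nu=doc["d_nu"],
        n_scans=doc["n_scans"],
        small_sample_warning=doc["small_sample_warning"],
        study=doc.get("study", ""), loglik=doc.get("loglik", float("nan")),
    )


def write_centiles(table: pd.DataFrame, centiles: pd.DataFrame, path) -> None:
    """CSV mirroring the input rows plus centile, mu, sigma, nu, mode."""
    out = pd.concat([table.reset_index(drop=True),
                     centiles.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)
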