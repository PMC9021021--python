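"""Covariate encoding and fractional-polynomial age bases.

Age convention: the internal age covariate ``x`` is *years post-conception*
(``age_days / 365.25``), strictly positive so logs and negative powers are
defined for foetal scans; ages are *reported* relative to birth using a
280-day (40-week) gestation convention.  Fractional-polynomial bases use the
standard power set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}, power 0 denoting
``log(x)``, and a power repeated k times contributing log-augmented columns
``x^p, x^p*log(x), ..., x^p*log(x)^(k-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FP_POWERS",
    "DAYS_PER_YEAR",
    "BIRTH_DAYS",
    "FractionalPolynomial",
    "MomentFormula",
    "ModelSpec",
    "CategoricalRegistry",
    "fp_basis",
    "fp_power_sets",
    "encode_design",
    "transform_age",
    "read_phenotype_table",
    "validate_table",
]

#: the standard fractional-polynomial power set
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)
DAYS_PER_YEAR = 365.25
#: birth at 40 gestational weeks
BIRTH_DAYS = 280.0
#: hard floor on age in days post-conception
DEFAULT_AGE_FLOOR = 80.0

REQUIRED_COLUMNS = ("participant_id", "study", "age_days", "sex", "version")


@dataclass(frozen=True)
class FractionalPolynomial:
    """An ordered multiset of powers from the standard set, length 0-3."""

    powers: tuple = ()

    def __post_init__(self):
        powers = tuple(float(p) for p in self.powers)
        if len(powers) > 3:
            raise ValueError(f"at most 3 fractional-polynomial powers, got {powers}")
        for p in powers:
            if p not in FP_POWERS:
                raise ValueError(
                    f"power {p} not in the standard set {FP_POWERS}"
                )
        if tuple(sorted(powers)) != powers:
            powers = tuple(sorted(powers))
        object.__setattr__(self, "powers", tuple(sorted(powers)))

    @property
    def order(self) -> int:
        return len(self.powers)

    def column_names(self, var: str = "age") -> list:
        names = []
        counts: dict = {}
        for p in self.powers:
            k = counts.get(p, 0)
            counts[p] = k + 1
            if p == 0.0:
                names.append(f"log({var})" + (f"^{k + 1}" if k else ""))
            else:
                base = f"{var}^{p:g}"
                names.append(base + (f"*log({var})^{k}" if k else ""))
        return names


@dataclass(frozen=True)
class MomentFormula:
    """Linear-predictor recipe for one distribution moment."""

    fixed_covariates: tuple = ()
    fp: FractionalPolynomial = field(default_factory=FractionalPolynomial)
    random_study_intercept: bool = False
    link: str = "log"

    def __post_init__(self):
        object.__setattr__(self, "fixed_covariates", tuple(self.fixed_covariates))
        if self.link not in ("log", "identity"):
            raise ValueError(f"link must be 'log' or 'identity', got {self.link!r}")
        for c in self.fixed_covariates:
            if c not in ("sex", "version"):
                raise ValueError(f"unsupported fixed covariate {c!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Per-phenotype three-moment model specification.

    mu and sigma use a log link; nu uses the identity link and is always
    intercept-only (no covariates, no age terms, no random term).
    """

    phenotype: str
    mu: MomentFormula = field(
        default_factory=lambda: MomentFormula(random_study_intercept=True)
    )
    sigma: MomentFormula = field(
        default_factory=lambda: MomentFormula(random_study_intercept=True)
    )
    nu: MomentFormula = field(default_factory=lambda: MomentFormula(link="identity"))

    def __post_init__(self):
        if self.mu.link != "log" or self.sigma.link != "log":
            raise ValueError("mu and sigma must use the log link")
        if self.nu.link != "identity":
            raise ValueError("nu must use the identity link")
        if (
            self.nu.fixed_covariates
            or self.nu.fp.order
            or self.nu.random_study_intercept
        ):
            raise ValueError("nu formula must be intercept-only")
        if "version" in self.sigma.fixed_covariates:
            raise ValueError("version covariate may appear only in the mu formula")


@dataclass
class CategoricalRegistry:
    """Categorical levels recorded at fit time; first level is the reference."""

    sex_levels: tuple = ("F", "M")
    version_levels: tuple = ()
    study_levels: tuple = ()

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CategoricalRegistry":
        return cls(
            sex_levels=("F", "M"),
            version_levels=tuple(sorted(table["version"].astype(str).unique())),
            study_levels=tuple(sorted(table["study"].astype(str).unique())),
        )


def fp_basis(x, fp: FractionalPolynomial) -> np.ndarray:
    """Fractional-polynomial basis matrix, one column per term.

    Column j is ``x**p_j`` (power 0 meaning ``log x``); a power repeated k
    times contributes ``x^p, x^p*log x, ..., x^p*(log x)^(k-1)``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("fractional-polynomial covariate x must be positive")
    lx = np.log(x)
    cols = []
    counts: dict = {}
    for p in fp.powers:
        k = counts.get(p, 0)
        counts[p] = k + 1
        if p == 0.0:
            cols.append(lx ** (k + 1))
        else:
            col = x ** p
            if k:
                col = col * lx ** k
            cols.append(col)
    if not cols:
        return np.empty((x.size, 0))
    return np.column_stack(cols)


def fp_power_sets(max_order: int = 3, powers: Sequence[float] = FP_POWERS):
    """All power multisets of order 0..max_order (sorted, with repetition).

    Orders 1-3 over the 8 standard powers give 8 + 36 + 120 = 164 candidate
    bases, plus the empty (intercept-only) basis.
    """
    from itertools import combinations_with_replacement

    out = [()]
    for order in range(1, max_order + 1):
        out.extend(tuple(c) for c in combinations_with_replacement(sorted(powers), order))
    return out


def transform_age(age_days, floor: float = DEFAULT_AGE_FLOOR):
    """Days post-conception -> (x in years post-conception, reporting age
    in years relative to birth)."""
    age_days = np.asarray(age_days, dtype=float)
    if np.any(~np.isfinite(age_days)) or np.any(age_days < floor):
        raise ValueError(
            f"age_days must be finite and >= {floor} days post-conception"
        )
    x = age_days / DAYS_PER_YEAR
    reporting = (age_days - BIRTH_DAYS) / DAYS_PER_YEAR
    return x, reporting


def years_pc_to_reporting(x):
    """Years post-conception -> years relative to birth."""
    return np.asarray(x, dtype=float) - BIRTH_DAYS / DAYS_PER_YEAR


def _encode_categorical(values, levels, name):
    values = np.asarray(values).astype(str)
    unknown = set(values) - set(levels)
    if unknown:
        raise ValueError(
            f"unseen {name} level(s) {sorted(unknown)}; known levels: {list(levels)}"
        )
    # one indicator per non-reference level
    return np.column_stack(
        [(values == lev).astype(float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(values), 0))


def encode_design(table: pd.DataFrame, formula: MomentFormula,
                  registry: CategoricalRegistry | None = None,
                  age_floor: float = DEFAULT_AGE_FLOOR):
    """Build (fixed-effect matrix X, study-indicator matrix Z, column names).

    The intercept column comes first, then covariate indicators (sex coded
    as one male indicator, reference female; version one-hot against its
    first recorded level), then the fractional-polynomial age columns.  Z
    has one column per registered study when the formula carries a random
    study intercept, else zero columns.
    """
    if registry is None:
        registry = CategoricalRegistry.from_table(table)
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in formula.fixed_covariates:
        if cov == "sex":
            block = _encode_categorical(table["sex"], registry.sex_levels, "sex")
            cols.append(block)
            names.extend(f"sex[{lev}]" for lev in registry.sex_levels[1:])
        elif cov == "version":
            block = _encode_categorical(
                table["version"], registry.version_levels, "version"
            )
            cols.append(block)
            names.extend(f"version[{lev}]" for lev in registry.version_levels[1:])
    if formula.fp.order:
        x, _ = transform_age(table["age_days"].to_numpy(), floor=age_floor)
        cols.append(fp_basis(x, formula.fp))
        names.extend(formula.fp.column_names("age"))
    X = np.column_stack(cols) if len(cols) > 1 else cols[0][:, None]
    if formula.random_study_intercept:
        study = table["study"].astype(str).to_numpy()
        unknown = set(study) - set(registry.study_levels)
        if unknown:
            raise ValueError(
                f"unseen study level(s) {sorted(unknown)}; "
                f"known levels: {list(registry.study_levels)}"
            )
        Z = np.column_stack(
            [(study == s).astype(float) for s in registry.study_levels]
        )
    else:
        Z = np.empty((n, 0))
    return X, Z, names


def validate_table(table: pd.DataFrame, phenotype: str | None = None,
                   age_floor: float = DEFAULT_AGE_FLOOR) -> pd.DataFrame:
    """Validate a phenotype table; returns it unchanged on success."""
    problems = []
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise ValueError("invalid phenotype table: " + "; ".join(problems))
    bad_sex = set(table["sex"].astype(str)) - {"F", "M"}
    if bad_sex:
        problems.append(f"sex must be F or M, found {sorted(bad_sex)}")
    age = pd.to_numeric(table["age_days"], errors="coerce")
    bad = table.index[age.isna() | (age < age_floor)]
    for i in list(bad[:5]):
        problems.append(f"row {i}: age_days must be a number >= {age_floor}")
    if phenotype is not None:
        if phenotype not in table.columns:
            problems.append(f"missing phenotype column {phenotype!r}")
        else:
            vals = pd.to_numeric(table[phenotype], errors="coerce")
            bad = table.index[vals.isna() | (vals <= 0)]
            for i in list(bad[:5]):
                problems.append(f"row {i}: {phenotype} must be a positive number")
    if problems:
        raise ValueError("invalid phenotype table: " + "; ".join(problems))
    return table


def read_phenotype_table(path, phenotype: str | None = None) -> pd.DataFrame:
    """Read a per-scan phenotype CSV/TSV (UTF-8, '.' decimal separator)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep, encoding="utf-8")
    return validate_table(table, phenotype=phenotype)
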