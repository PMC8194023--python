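"""Patient-cohort schema, CSV I/O, encoding and a parametric fixture generator.

A cohort is a table of heart-failure patients with ten covariates (sex, age,
creatinine phosphokinase, ejection fraction, high blood pressure, platelets,
serum creatinine, serum sodium, smoking, anemia), two outcomes — therapy time
in days (``time``, within a six-month observation window) and a binary
treatment key (``treatment_key``: 1 = ACE inhibitor / ARB / beta-blocker
class, 0 = aspirin-type alternative) — and an optional ``death`` flag.

The fixture generator draws structurally realistic cohorts with a planted
treatment mechanism: patients with reduced ejection fraction (< 40%, systolic
heart failure) receive the ACEi/ARB/beta-blocker class with probability 0.9,
patients with preserved ejection fraction with a lower probability; death
follows a logistic model in ejection fraction, serum creatinine and age, and
therapy time is short for deaths.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from math import ceil
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import InvalidParameterError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "BINARY_VARS",
    "CONTINUOUS_VARS",
    "Cohort",
    "FixtureParams",
    "INPUT_VARS",
    "NormalizationSpec",
    "OUTCOME_VARS",
    "encode_and_normalize",
    "filter_positive",
    "generate_fixture_cohort",
    "read_cohort",
    "split_train_test",
    "write_cohort",
]

# Canonical column names, in table order (V1..V10, O1, O2, optional death).
INPUT_VARS = [
    "sex",
    "age",
    "creatinine_phosphokinase",
    "ejection_fraction",
    "high_blood_pressure",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "smoking",
    "anemia",
]
OUTCOME_VARS = ["time", "treatment_key"]
BINARY_VARS = {"sex", "high_blood_pressure", "smoking", "anemia", "treatment_key", "death"}
CONTINUOUS_VARS = [
    "age",
    "creatinine_phosphokinase",
    "ejection_fraction",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "time",
]
ALL_COLUMNS = ["ID"] + INPUT_VARS + OUTCOME_VARS

_ALIASES = {
    "id": "ID",
    "v1": "sex",
    "v2": "age",
    "v3": "creatinine_phosphokinase",
    "v4": "ejection_fraction",
    "v5": "high_blood_pressure",
    "v6": "platelets",
    "v7": "serum_creatinine",
    "v8": "serum_sodium",
    "v9": "smoking",
    "v10": "anemia",
    "o1": "time",
    "o2": "treatment_key",
    "high blood pressure": "high_blood_pressure",
    "treatment key": "treatment_key",
}


def _canonical(col: str) -> str:
    key = col.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for canon in ALL_COLUMNS + ["death"]:
        if key == canon.lower():
            return canon
    return col  # unknown columns pass through untouched


@dataclass
class Cohort:
    """A validated patient table; unknown columns are preserved as extras.

    ``partial=True`` relaxes the mandatory-column check (used for synthetic
    tables built over a subset of the variables); present columns are still
    validated.
    """

    df: pd.DataFrame
    partial: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in ALL_COLUMNS if c not in df.columns]
        if missing and not self.partial:
            raise SchemaError(f"cohort is missing mandatory column(s): {missing}")
        if "ID" in df.columns and df["ID"].duplicated().any():
            dup = df["ID"][df["ID"].duplicated()].iloc[0]
            raise SchemaError(f"duplicated patient ID: {dup!r}")
        for col in INPUT_VARS + OUTCOME_VARS + ["death"]:
            if col not in df.columns:
                continue
            vals = df[col]
            if col in BINARY_VARS:
                bad = ~vals.isin([0, 1])
                if bad.any():
                    raise SchemaError(
                        f"binary column {col!r} has non-0/1 value at row "
                        f"{int(np.argmax(bad.to_numpy()))}"
                    )
            else:
                if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                    raise SchemaError(f"column {col!r} contains non-finite values")
        if len(df) and "time" in df.columns and (df["time"].to_numpy(dtype=float) < 0).any():
            raise SchemaError("therapy time must be non-negative")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_death(self) -> bool:
        return "death" in self.df.columns


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (case-insensitive column aliases accepted)."""
    df = pd.read_csv(path, dtype={"ID": str})
    df = df.rename(columns={c: _canonical(c) for c in df.columns})
    if "ID" in df.columns:
        df["ID"] = df["ID"].astype(str)
    for col in df.columns:
        if col == "ID" or col not in ALL_COLUMNS + ["death"]:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SchemaError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    return Cohort(df)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as UTF-8 CSV ('.' decimal separator, canonical order)."""
    known = [c for c in ALL_COLUMNS + ["death"] if c in cohort.df.columns]
    extras = [c for c in cohort.df.columns if c not in known]
    cohort.df[known + extras].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Encoding / normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationSpec:
    """Per-variable (min, max) used for the affine map ``(x - min)/(max - min)``."""

    ranges: Dict[str, Tuple[float, float]]

    def transform_column(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.ranges[name]
        if hi == lo:
            return np.zeros_like(values, dtype=float)
        return np.clip((values - lo) / (hi - lo), 0.0, 1.0)

    def inverse_transform(self, name: str, value: float) -> float:
        lo, hi = self.ranges[name]
        return lo + float(value) * (hi - lo)


def fit_normalization(cohort: Cohort) -> NormalizationSpec:
    ranges = {}
    for col in CONTINUOUS_VARS:
        vals = cohort.df[col].to_numpy(dtype=float)
        lo, hi = float(np.min(vals)), float(np.max(vals))
        if hi == lo:
            logger.warning("variable %r is constant; it will normalize to 0", col)
        ranges[col] = (lo, hi)
    return NormalizationSpec(ranges)


def encode_and_normalize(
    cohort: Cohort, spec: Optional[NormalizationSpec] = None
) -> Tuple[np.ndarray, np.ndarray, NormalizationSpec]:
    """Binary columns pass through as 0/1; continuous columns map affinely to [0, 1].

    When ``spec`` is given it is reused (serving/test data), with values
    outside the fitted range clamped; otherwise the spec is fitted from this
    cohort.  Returns ``(X, Y, spec)`` with X of shape (n, 10) in table order
    and Y = (normalised time, treatment key).
    """
    if len(cohort) == 0:
        raise SchemaError("cannot encode an empty cohort")
    if spec is None:
        spec = fit_normalization(cohort)
    cols = []
    for col in INPUT_VARS:
        vals = cohort.df[col].to_numpy(dtype=float)
        cols.append(vals if col in BINARY_VARS else spec.transform_column(col, vals))
    X = np.column_stack(cols)
    Y = np.column_stack(
        [
            spec.transform_column("time", cohort.df["time"].to_numpy(dtype=float)),
            cohort.df["treatment_key"].to_numpy(dtype=float),
        ]
    )
    return X, Y, spec


def split_train_test(
    cohort: Cohort, train_fraction: float = 0.8, seed: int = 0
) -> Tuple[Cohort, Cohort]:
    """Uniformly shuffled split; training size ``ceil(fraction * n)``."""
    if not 0.0 < train_fraction < 1.0:
        raise InvalidParameterError("train_fraction must lie in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise SchemaError("need at least 2 records to split")
    perm = np.random.default_rng(seed).permutation(n)
    k = ceil(train_fraction * n)
    train = cohort.df.iloc[perm[:k]].reset_index(drop=True)
    test = cohort.df.iloc[perm[k:]].reset_index(drop=True)
    return Cohort(train), Cohort(test)


def filter_positive(cohort: Cohort, min_time_days: float = 60.0) -> Cohort:
    """Positive-outcome subset: survivors (death = 0) with time >= ``min_time_days``."""
    if not cohort.has_death:
        raise SchemaError(
            "cohort has no 'death' column; regenerate the fixture with outcome "
            "flags or add the column before filtering"
        )
    df = cohort.df
    keep = (df["death"] == 0) & (df["time"] >= min_time_days)
    return Cohort(df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


@dataclass
class FixtureParams:
    """Generative laws of the fixture cohort (all configurable).

    Continuous labs use plausible heart-failure-like shapes; ejection fraction
    is a two-component normal mixture (reduced vs preserved); serum sodium
    declines mildly with age (the one planted continuous-continuous link);
    the treatment key follows the ejection-fraction mechanism; death follows a
    logistic model in (EF, serum creatinine, age); therapy time is short for
    deaths and long for survivors, inside a six-month (183-day) window.
    """

    p_sex: float = 0.65
    p_hbp: float = 0.35
    p_smoking: float = 0.32
    p_anemia: float = 0.43
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_range: Tuple[float, float] = (40.0, 95.0)
    cpk_log_mean: float = 5.5  # median ~245 U/L
    cpk_log_sd: float = 0.9
    platelets_mean: float = 2.6e5
    platelets_sd: float = 9.5e4
    creatinine_log_mean: float = 0.0953  # ln(1.1) -> median 1.1 mg/dL
    creatinine_log_sd: float = 0.35
    sodium_intercept: float = 137.0
    sodium_age_slope: float = -0.1  # mEq/L per year, about age_mean
    sodium_noise_sd: float = 3.82  # keeps the marginal SD near 4
    ef_reduced_mean: float = 30.0
    ef_reduced_sd: float = 5.0
    ef_preserved_mean: float = 55.0
    ef_preserved_sd: float = 5.0
    p_reduced: float = 0.6
    ef_threshold: float = 40.0
    ef_range: Tuple[float, float] = (0.0, 80.0)
    tk_prob_reduced: float = 0.9
    tk_prob_preserved: float = 0.6
    death_intercept: float = -1.2
    death_coef_ef: float = -0.07  # per % point about the threshold
    death_coef_creatinine: float = 0.8  # per mg/dL about 1.4
    death_coef_age: float = 0.035  # per year about 60
    time_death_range: Tuple[float, float] = (4.0, 120.0)
    time_survivor_range: Tuple[float, float] = (60.0, 183.0)

    def validate(self) -> None:
        for name in (
            "p_sex",
            "p_hbp",
            "p_smoking",
            "p_anemia",
            "p_reduced",
            "tk_prob_reduced",
            "tk_prob_preserved",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")

    def with_overrides(self, **kwargs) -> "FixtureParams":
        return replace(self, **kwargs)

    def death_probability(
        self, ef: np.ndarray, creatinine: np.ndarray, age: np.ndarray
    ) -> np.ndarray:
        eta = (
            self.death_intercept
            + self.death_coef_ef * (ef - self.ef_threshold)
            + self.death_coef_creatinine * (creatinine - 1.4)
            + self.death_coef_age * (age - 60.0)
        )
        return expit(eta)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _random_ids(rng: np.random.Generator, n: int) -> np.ndarray:
    ids = set()
    out = []
    while len(out) < n:
        cand = f"P{rng.integers(0, 16**8):08x}"
        if cand not in ids:
            ids.add(cand)
            out.append(cand)
    return np.array(out)


def generate_fixture_cohort(
    n: int, seed: int = 0, params: Optional[FixtureParams] = None
) -> Cohort:
    """Draw a reproducible synthetic-structure cohort of ``n`` patients."""
    if n < 0:
        raise InvalidParameterError("n must be non-negative")
    params = params or FixtureParams()
    params.validate()
    rng = np.random.default_rng(seed)

    sex = rng.binomial(1, params.p_sex, n)
    hbp = rng.binomial(1, params.p_hbp, n)
    smoking = rng.binomial(1, params.p_smoking, n)
    anemia = rng.binomial(1, params.p_anemia, n)
    age = _truncated_normal(
        rng, params.age_mean, params.age_sd, *params.age_range, n
    )
    cpk = rng.lognormal(params.cpk_log_mean, params.cpk_log_sd, n)
    platelets = _truncated_normal(
        rng, params.platelets_mean, params.platelets_sd, 1.0, np.inf, n
    )
    creatinine = rng.lognormal(params.creatinine_log_mean, params.creatinine_log_sd, n)
    sodium = (
        params.sodium_intercept
        + params.sodium_age_slope * (age - params.age_mean)
        + rng.normal(0.0, params.sodium_noise_sd, n)
    )
    reduced = rng.random(n) < params.p_reduced
    ef = np.where(
        reduced,
        rng.normal(params.ef_reduced_mean, params.ef_reduced_sd, n),
        rng.normal(params.ef_preserved_mean, params.ef_preserved_sd, n),
    )
    ef = np.clip(ef, *params.ef_range)

    below = ef < params.ef_threshold
    tk_prob = np.where(below, params.tk_prob_reduced, params.tk_prob_preserved)
    treatment_key = rng.binomial(1, tk_prob)

    p_death = params.death_probability(ef, creatinine, age)
    death = rng.binomial(1, p_death)
    time = np.where(
        death == 1,
        rng.uniform(*params.time_death_range, n),
        rng.uniform(*params.time_survivor_range, n),
    )

    df = pd.DataFrame(
        {
            "ID": _random_ids(rng, n),
            "sex": sex,
            "age": age,
            "creatinine_phosphokinase": cpk,
            "ejection_fraction": ef,
            "high_blood_pressure": hbp,
            "platelets": platelets,
            "serum_creatinine": creatinine,
            "serum_sodium": sodium,
            "smoking": smoking,
            "anemia": anemia,
            "time": time,
            "treatment_key": treatment_key,
            "death": death,
        }
    )
    return Cohort(df)
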