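"""Sequential-regression cohort synthesis and distribution-distance QA.

The synthesizer visits the variables in a fixed order and fits, for each one,
a model conditioned only on the variables visited earlier:

* the first variable uses its empirical marginal;
* binary variables use a logistic regression on their predecessors;
* continuous variables use an ordinary least-squares regression on their
  predecessors, with the residual spread recorded.

Synthesis then walks the same order, drawing each variable from its predictive
distribution.  Continuous draws from the normal predictive distribution are
mapped back onto the fitting cohort's empirical marginal by rank (*norm-rank*):
the i-th smallest draw is replaced by the i-th empirical quantile, so synthetic
values never leave the observed range and the marginal shape is preserved
while the regression preserves the dependence structure.

Quality is scored as the mean absolute difference of relative bin frequencies
between original and synthetic cohorts (x100, in percent), per variable and
averaged over variables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import BINARY_VARS, Cohort, INPUT_VARS, OUTCOME_VARS
from .exceptions import InvalidParameterError, SchemaError
from .cohort import _random_ids  # fresh random IDs for synthetic patients

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_VISIT_ORDER",
    "DistanceReport",
    "SynthesizerModel",
    "distribution_distance",
    "fit_synthesizer",
    "synthesize",
    "synthesis_report",
]

DEFAULT_VISIT_ORDER = INPUT_VARS + OUTCOME_VARS + ["death"]


@dataclass
class _VariableModel:
    kind: str  # "marginal-binary" | "marginal-continuous" | "constant" | "logistic" | "linear"
    # marginals
    p: Optional[float] = None
    sorted_values: Optional[np.ndarray] = None
    constant: Optional[float] = None
    # regression pieces
    coef: Optional[np.ndarray] = None  # includes intercept at position 0
    resid_sd: Optional[float] = None
    clf: Optional[LogisticRegression] = None


@dataclass
class SynthesizerModel:
    """Fitted per-variable sequential models, in visit order."""

    visit_order: List[str]
    models: Dict[str, _VariableModel]
    n_fit: int

    @property
    def fitted(self) -> bool:
        return bool(self.models)


def _design(df: pd.DataFrame, predecessors: List[str]) -> np.ndarray:
    X = df[predecessors].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def fit_synthesizer(
    cohort: Cohort, visit_order: Optional[List[str]] = None
) -> SynthesizerModel:
    """Fit the sequence of regressions on ``cohort`` in ``visit_order``.

    Binary variables get a logistic regression (unpenalised MLE), continuous
    variables an OLS fit plus their sorted empirical values for the norm-rank
    back-transform.  A variable whose fit degenerates (constant column,
    perfect separation, singular design) falls back to its marginal, logged.
    """
    if len(cohort) == 0:
        raise SchemaError("cannot fit a synthesizer on an empty cohort")
    if visit_order is None:
        visit_order = [c for c in DEFAULT_VISIT_ORDER if c in cohort.df.columns]
    missing = [c for c in visit_order if c not in cohort.df.columns]
    if missing:
        raise SchemaError(f"visit order names absent column(s): {missing}")
    df = cohort.df
    models: Dict[str, _VariableModel] = {}
    for i, var in enumerate(visit_order):
        y = df[var].to_numpy(dtype=float)
        binary = var in BINARY_VARS
        if np.all(y == y[0]):
            models[var] = _VariableModel(kind="constant", constant=float(y[0]))
            continue
        predecessors = visit_order[:i]
        if not predecessors:
            if binary:
                models[var] = _VariableModel(kind="marginal-binary", p=float(y.mean()))
            else:
                models[var] = _VariableModel(
                    kind="marginal-continuous", sorted_values=np.sort(y)
                )
            continue
        if binary:
            try:
                import warnings

                clf = LogisticRegression(C=np.inf, max_iter=2000, solver="lbfgs")
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    clf.fit(df[predecessors].to_numpy(dtype=float), y.astype(int))
                models[var] = _VariableModel(kind="logistic", clf=clf)
            except Exception as exc:  # separation or degenerate design
                logger.warning("logistic fit for %r failed (%s); using marginal", var, exc)
                models[var] = _VariableModel(kind="marginal-binary", p=float(y.mean()))
        else:
            X = _design(df, predecessors)
            coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                logger.warning("singular design for %r; using marginal", var)
                models[var] = _VariableModel(
                    kind="marginal-continuous", sorted_values=np.sort(y)
                )
                continue
            resid = y - X @ coef
            dof = max(len(y) - X.shape[1], 1)
            models[var] = _VariableModel(
                kind="linear",
                coef=coef,
                resid_sd=float(np.sqrt(resid @ resid / dof)),
                sorted_values=np.sort(y),
            )
    return SynthesizerModel(visit_order=list(visit_order), models=models, n_fit=len(df))


def _norm_rank_map(draws: np.ndarray, sorted_values: np.ndarray) -> np.ndarray:
    """Replace draws by empirical quantiles of matching rank."""
    m = len(draws)
    ranks = np.argsort(np.argsort(draws, kind="stable"), kind="stable")
    probs = (ranks + 0.5) / m
    return np.quantile(sorted_values, probs, method="linear")


def synthesize(model: SynthesizerModel, m: int, seed: int = 0) -> Cohort:
    """Draw ``m`` synthetic patients from the fitted sequential models."""
    if not isinstance(model, SynthesizerModel) or not model.fitted:
        raise InvalidParameterError("synthesizer model is not fitted")
    if m < 0:
        raise InvalidParameterError("m must be non-negative")
    rng = np.random.default_rng(seed)
    data: Dict[str, np.ndarray] = {}
    df = pd.DataFrame(index=range(m))
    for i, var in enumerate(model.visit_order):
        vm = model.models[var]
        if vm.kind == "constant":
            vals = np.full(m, vm.constant)
        elif vm.kind == "marginal-binary":
            vals = rng.binomial(1, vm.p, m).astype(float)
        elif vm.kind == "marginal-continuous":
            draws = rng.normal(size=m)
            vals = _norm_rank_map(draws, vm.sorted_values)
        elif vm.kind == "logistic":
            X = df[model.visit_order[:i]].to_numpy(dtype=float) if i else np.empty((m, 0))
            p = vm.clf.predict_proba(X)[:, 1] if m else np.empty(0)
            vals = rng.binomial(1, p).astype(float) if m else np.empty(0)
        elif vm.kind == "linear":
            X = _design(df, model.visit_order[:i])
            mu = X @ vm.coef
            draws = rng.normal(mu, vm.resid_sd)
            vals = _norm_rank_map(draws, vm.sorted_values)
        else:  # pragma: no cover
            raise InvalidParameterError(f"unknown model kind {vm.kind!r}")
        df[var] = vals
        data[var] = vals
    out = pd.DataFrame({"ID": _random_ids(rng, m)})
    for var in model.visit_order:
        out[var] = data[var]
    for var in BINARY_VARS:
        if var in out.columns:
            out[var] = out[var].astype(int)
    from .cohort import ALL_COLUMNS

    partial = any(c not in out.columns for c in ALL_COLUMNS)
    return Cohort(out, partial=partial)


# ---------------------------------------------------------------------------
# Frequency-distribution distance
# ---------------------------------------------------------------------------


def distribution_distance(
    original: Cohort, synthetic: Cohort, variable: str, n_bins: int = 10
) -> float:
    """Mean absolute relative-frequency difference over bins, in percent.

    Binary variables use the natural bins {0, 1}; continuous variables use
    ``n_bins`` equal-width bins spanning the pooled range of both cohorts.
    """
    for coh, label in ((original, "original"), (synthetic, "synthetic")):
        if len(coh) == 0:
            raise SchemaError(f"{label} cohort is empty")
        if variable not in coh.df.columns:
            raise SchemaError(f"variable {variable!r} absent from {label} cohort")
    x = original.df[variable].to_numpy(dtype=float)
    y = synthetic.df[variable].to_numpy(dtype=float)
    if variable in BINARY_VARS:
        edges = np.array([-0.5, 0.5, 1.5])
    else:
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        if hi == lo:
            return 0.0
        edges = np.linspace(lo, hi, n_bins + 1)
    fx, _ = np.histogram(x, bins=edges)
    fy, _ = np.histogram(y, bins=edges)
    rel_x = fx / len(x)
    rel_y = fy / len(y)
    return float(np.mean(np.abs(rel_x - rel_y))) * 100.0


@dataclass
class DistanceReport:
    """Per-variable frequency-distribution distances (percent) and their mean."""

    per_variable: Dict[str, float]
    n_bins: int

    @property
    def overall_mean(self) -> float:
        return float(np.mean(list(self.per_variable.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": k, "distance_percent": v} for k, v in self.per_variable.items()]
        rows.append({"variable": "OVERALL_MEAN", "distance_percent": self.overall_mean})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = {
            "per_variable": self.per_variable,
            "overall_mean": self.overall_mean,
            "n_bins": self.n_bins,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)


def synthesis_report(
    original: Cohort, synthetic: Cohort, n_bins: int = 10
) -> DistanceReport:
    """Distance for every modeled variable present in both cohorts."""
    variables = [
        c for c in DEFAULT_VISIT_ORDER
        if c in original.df.columns and c in synthetic.df.columns
    ]
    per_var = {
        v: distribution_distance(original, synthetic, v, n_bins=n_bins)
        for v in variables
    }
    return DistanceReport(per_variable=per_var, n_bins=n_bins)
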