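"""Clinical-biomarker severity models for severe acute pancreatitis.

Workflow: filter clinical tests by availability, impute (median) and
standardize on the training samples only, rank tests by recursive feature
elimination under a logistic estimator, fit a maximum-likelihood logistic
model on the retained tests, and optionally expand the feature table with
the aggregate cfDNA methylation score.  The curated 12-test model used in
the published severity predictor ships as a fixture
(:func:`table1_fixture`) with its printed coefficients and per-test
summary statistics; no intercept was printed for it, so it supports
relative ranking of samples, not calibrated probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cfmhl.io import ClinicalTable, PathLike
from cfmhl.screen import ScoreVector

__all__ = [
    "FeatureTable",
    "PreprocessRecord",
    "SeverityModel",
    "build_expanded_features",
    "filter_tests_by_availability",
    "fit_logistic",
    "fit_random_forest",
    "impute_and_standardize",
    "predict",
    "rfe_select",
    "table1_fixture",
]


@dataclass
class FeatureTable:
    """Samples x model features; provenance marks clinical vs methylation columns."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("values shape does not match sample/feature lists")
        for name in self.feature_names:
            self.provenance.setdefault(name, "clinical")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.sample_ids),
            list(names),
            self.values[:, idx],
            {n: self.provenance[n] for n in names},
        )


@dataclass
class SeverityModel:
    """A fitted (or fixed) logistic severity classifier.

    ``standardization`` maps each feature to its (center, scale); an empty
    map means raw-scale features.  ``intercept`` may be absent (None), in
    which case predictions are relative scores around 0.5, not calibrated
    probabilities.
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float | None = None
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)
    positive_class: str = "SAP"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.feature_names),):
            raise ValueError("one coefficient per feature required")
        for name, (_, scale) in self.standardization.items():
            if scale <= 0:
                raise ValueError(f"feature {name!r}: scale must be > 0")

    def coefficient(self, feature_name: str) -> float:
        return float(self.coefficients[self.feature_names.index(feature_name)])

    def to_json(self, path: PathLike | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": self.intercept,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "positive_class": self.positive_class,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
        if path is not None:
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str | PathLike) -> "SeverityModel":
        text = source
        if not str(source).lstrip().startswith("{"):
            with open(source, "rt", encoding="utf-8") as fh:
                text = fh.read()
        payload = json.loads(text)
        return cls(
            feature_names=list(payload["feature_names"]),
            coefficients=np.array(payload["coefficients"], dtype=float),
            intercept=payload.get("intercept"),
            standardization={k: tuple(v) for k, v in payload.get("standardization", {}).items()},
            positive_class=payload.get("positive_class", "SAP"),
            metadata=payload.get("metadata", {}),
        )


def filter_tests_by_availability(
    table: ClinicalTable, max_missing_fraction: float = 0.2
) -> ClinicalTable:
    """Drop tests missing in MORE than ``max_missing_fraction`` of samples.

    A test exactly at the threshold is kept; column order is preserved.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError(
            f"max_missing_fraction must be in [0, 1), got {max_missing_fraction}"
        )
    miss = np.isnan(table.values).mean(axis=0)
    keep = [j for j, m in enumerate(miss) if m <= max_missing_fraction]
    names = [table.test_names[j] for j in keep]
    return ClinicalTable(
        list(table.sample_ids),
        names,
        table.values[:, keep],
        {n: table.units.get(n, "") for n in names},
    )


@dataclass
class PreprocessRecord:
    """Training-fitted imputation medians and standardization statistics.

    Applying the record to a new table always uses these training
    statistics, never the new table's own — the no-leakage contract.
    """

    feature_names: list[str]
    medians: np.ndarray
    centers: np.ndarray
    scales: np.ndarray

    def apply(self, table: ClinicalTable | FeatureTable) -> FeatureTable:
        names = table.test_names if isinstance(table, ClinicalTable) else table.feature_names
        idx = [names.index(n) for n in self.feature_names]
        raw = table.values[:, idx].astype(float)
        for j in range(raw.shape[1]):
            col = raw[:, j]
            col[np.isnan(col)] = self.medians[j]
        z = (raw - self.centers) / self.scales
        return FeatureTable(list(table.sample_ids), list(self.feature_names), z)

    def standardization_map(self) -> dict[str, tuple[float, float]]:
        return {
            n: (float(c), float(s))
            for n, c, s in zip(self.feature_names, self.centers, self.scales)
        }


def impute_and_standardize(
    table: ClinicalTable, strategy: str = "MEDIAN"
) -> tuple[FeatureTable, PreprocessRecord]:
    """Median-impute and z-score the table; returns the reusable record.

    Every test must have at least one observed value.  Zero-variance
    features get scale 1 with a warning instead of dividing by zero.
    """
    if strategy != "MEDIAN":
        raise ValueError(f"unknown strategy {strategy!r}")
    vals = table.values
    if np.isnan(vals).all(axis=0).any():
        bad = [n for n, c in zip(table.test_names, np.isnan(vals).all(axis=0)) if c]
        raise ValueError(f"tests with no observed values: {bad}")
    medians = np.nanmedian(vals, axis=0)
    filled = np.where(np.isnan(vals), medians, vals)
    centers = filled.mean(axis=0)
    scales = filled.std(axis=0, ddof=0)
    zero_var = scales == 0
    if zero_var.any():
        names = [n for n, z in zip(table.test_names, zero_var) if z]
        warnings.warn(f"zero-variance features scaled by 1: {names}", stacklevel=2)
        scales = np.where(zero_var, 1.0, scales)
    record = PreprocessRecord(list(table.test_names), medians, centers, scales)
    return record.apply(table), record


def _logistic_coefs_sklearn(
    X: np.ndarray, y: np.ndarray, alpha: float
) -> tuple[np.ndarray, float]:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / alpha, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def fit_logistic(
    features: FeatureTable,
    labels: Sequence[bool],
    regularization: float | None = None,
) -> SeverityModel:
    """Maximum-likelihood binary logistic regression (statsmodels Logit).

    ``regularization`` is an optional ridge strength; when the
    unregularized likelihood diverges (separable data) a ridge fit with
    strength 1.0 is used instead, with a warning.  Feature values are used
    as given (standardize upstream); the model records no standardization
    of its own.
    """
    import statsmodels.api as sm

    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = features.values
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")

    if regularization is None:
        design = sm.add_constant(X, has_constant="add")
        converged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200, method="newton", tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            # separation shows up as convergence to huge coefficients
            if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
                converged = False
        except Exception:
            converged = False
        if converged:
            return SeverityModel(
                feature_names=list(features.feature_names),
                coefficients=params[1:],
                intercept=float(params[0]),
                metadata={"estimator": "statsmodels-logit"},
            )
        warnings.warn(
            "logistic likelihood diverged (separable data?); ridge fallback engaged",
            stacklevel=2,
        )
        regularization = 1.0

    coefs, intercept = _logistic_coefs_sklearn(X, y.astype(int), regularization)
    return SeverityModel(
        feature_names=list(features.feature_names),
        coefficients=coefs,
        intercept=intercept,
        metadata={"estimator": "logistic-ridge", "alpha": regularization},
    )


def rfe_select(
    features: FeatureTable,
    labels: Sequence[bool],
    n_keep: int,
    estimator: str = "LOGISTIC",
    regularization: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Recursive feature elimination under a (ridge) logistic estimator.

    Repeatedly fits the estimator on the surviving features and drops the
    one with the smallest absolute coefficient until ``n_keep`` remain.
    Returns ``(kept_features, elimination_order)`` (first eliminated
    first).  Deterministic for fixed data.
    """
    if estimator != "LOGISTIC":
        raise ValueError(f"unknown estimator {estimator!r}")
    if not 1 <= n_keep <= len(features.feature_names):
        raise ValueError(
            f"n_keep must be in [1, {len(features.feature_names)}], got {n_keep}"
        )
    y = np.asarray(labels, dtype=int)
    surviving = list(features.feature_names)
    eliminated: list[str] = []
    while len(surviving) > n_keep:
        sub = features.select(surviving)
        coefs, _ = _logistic_coefs_sklearn(sub.values, y, regularization)
        drop_idx = int(np.argmin(np.abs(coefs)))
        eliminated.append(surviving.pop(drop_idx))
    return surviving, eliminated


def predict(model: SeverityModel, features: FeatureTable) -> pd.Series:
    """Per-sample probability of the positive class (severe AP).

    Features are standardized by the model's stored (center, scale) when
    present.  An absent intercept is treated as 0 (relative score) with a
    warning.
    """
    missing = set(model.feature_names) - set(features.feature_names)
    if missing:
        raise ValueError(f"feature columns absent from table: {sorted(missing)}")
    sub = features.select(model.feature_names)
    X = sub.values.copy()
    for j, name in enumerate(model.feature_names):
        if name in model.standardization:
            center, scale = model.standardization[name]
            X[:, j] = (X[:, j] - center) / scale
    intercept = model.intercept
    if intercept is None:
        warnings.warn(
            "model has no intercept; probabilities are a relative score", stacklevel=2
        )
        intercept = 0.0
    eta = intercept + X @ model.coefficients
    probs = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(probs, index=features.sample_ids, name="p_" + model.positive_class)


def build_expanded_features(
    clinical: FeatureTable, methylation_scores: ScoreVector
) -> FeatureTable:
    """Join clinical features with the aggregate methylation score column.

    Inner join on sample id; samples present on only one side are dropped
    (reported via a warning).  The new column is named ``umhl_sap_score``.
    """
    score_series = methylation_scores.to_series()
    common = [s for s in clinical.sample_ids if s in score_series.index]
    if not common:
        raise ValueError("no overlapping samples between clinical table and scores")
    dropped = sorted(set(clinical.sample_ids) ^ set(score_series.index))
    if dropped:
        warnings.warn(f"{len(dropped)} samples present on only one side dropped", stacklevel=2)
    frame = clinical.to_frame().loc[common]
    frame["umhl_sap_score"] = score_series.loc[common]
    provenance = dict(clinical.provenance)
    provenance["umhl_sap_score"] = "methylation"
    return FeatureTable(common, list(frame.columns), frame.to_numpy(), provenance)


def fit_random_forest(
    features: FeatureTable,
    labels: Sequence[bool],
    seed: int = 0,
    n_trees: int = 500,
):
    """Proof-of-principle all-measures classifier (random forest, fixed seed).

    Returns the fitted scikit-learn classifier; use
    ``clf.predict_proba(X)[:, 1]`` for severity probabilities.
    """
    from sklearn.ensemble import RandomForestClassifier

    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(features.values, np.asarray(labels, dtype=int))
    return clf


# Curated 12-test severity model: (test, unit, mean, min, max, coefficient).
# Printed coefficients of the published logistic predictor; no intercept was
# printed, so the fixture ranks samples but cannot emit calibrated
# probabilities.
_TABLE1_ROWS: list[tuple[str, str, float, float, float, float]] = [
    ("Creatinine level", "µmol/L", 78.189, 55.0, 270.0, 0.2109),
    ("Estimated glomerular filtration rate", "mL/min/1.73 m2", 105.483, 10.5, 264.9, 0.1430),
    ("Globulin level", "g/L", 29.976, 17.8, 46.9, -0.0942),
    ("Absolute lymphocyte count", "10^9/L", 1.318, 0.1, 3.21, -1.4145),
    ("Mean hemoglobin", "pg", 30.354, 20.8, 37.6, -0.3217),
    ("Absolute neutrophils count", "10^9/L", 7.99, 0.99, 28.16, 0.4330),
    ("Red blood cell distribution width", "%", 13.695, 11.9, 24.0, 1.9985),
    ("Red blood cell count", "10^12/L", 4.174, 2.13, 6.06, -3.8955),
    ("Serum chloride", "mmol/L", 98.703, 82.0, 119.0, -0.2569),
    ("Triglyceride", "mmol/L", 3.722, 0.35, 56.25, 0.5150),
    ("Urea nitrogen", "mmol/L", 6.798, 1.3, 40.0, 0.7063),
    ("Uric acid", "µmol/L", 339.56, 75.0, 852.0, -0.0146),
]


def table1_fixture() -> SeverityModel:
    """The curated 12-test severity model with its published coefficients.

    Per-test unit, cohort mean, min and max are stored in the model
    metadata; the intercept is absent (relative-score model).
    """
    names = [row[0] for row in _TABLE1_ROWS]
    coefs = np.array([row[5] for row in _TABLE1_ROWS])
    metadata = {
        "tests": {
            name: {"unit": unit, "mean": mean, "min": lo, "max": hi}
            for name, unit, mean, lo, hi, _ in _TABLE1_ROWS
        },
        "intercept_note": "not published; predictions are relative scores",
    }
    return SeverityModel(
        feature_names=names,
        coefficients=coefs,
        intercept=None,
        positive_class="SAP",
        metadata=metadata,
    )
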