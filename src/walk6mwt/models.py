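"""Feature screening, selection, collinearity reduction, classification,
and the published reference logistic models for walk-test reliability.

Two binary targets are supported: *error-based* (baseline distance error
above/below the 30 m minimal-detectable-change band) and *user-based*
(conventional vs unconventional test execution). Screening uses the
point-biserial correlation and the two-sample Kolmogorov-Smirnov
statistic per feature; selection uses recursive feature elimination with
a regularized logistic estimator under participant-grouped
cross-validation; collinear survivors are merged into standardized sums
until every variance inflation factor is at or below 2.5; and three
classifier families (logistic regression, RBF support-vector machine,
random forest) are evaluated with stratified 5-fold cross-validation on
pooled out-of-fold predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.outliers_influence import variance_inflation_factor

VIF_THRESHOLD = 2.5
SIGNIFICANCE_LEVEL = 0.05


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_features(features: pd.DataFrame, labels: Sequence[int]) -> pd.DataFrame:
    """Point-biserial and two-sample KS statistics per feature column.

    Returns a frame indexed by feature name with columns r, r_pvalue,
    ks, ks_pvalue, significant (both p-values below 0.05).
    """
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("screening needs exactly two classes in the labels")
    rows = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0:
            r, rp, ks, kp = 0.0, 1.0, 0.0, 1.0
        else:
            r, rp = stats.pointbiserialr(y, x)
            ks, kp = stats.ks_2samp(x[y == classes[0]], x[y == classes[1]])
        rows[col] = {
            "r": r,
            "r_pvalue": rp,
            "ks": ks,
            "ks_pvalue": kp,
            "significant": (rp < SIGNIFICANCE_LEVEL) and (kp < SIGNIFICANCE_LEVEL),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# RFE selection with participant-grouped CV
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Feature-selection outcome: per-repetition subsets, their consensus,
    and (after VIF reduction) the combined-feature definitions."""

    repetition_sets: list[set[str]] = field(default_factory=list)
    consensus: list[str] = field(default_factory=list)
    combinations: dict[str, list[str]] = field(default_factory=dict)
    final_vif: dict[str, float] = field(default_factory=dict)


def _grouped_folds(
    groups: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    uniq = np.array(sorted(set(groups)))
    rng.shuffle(uniq)
    chunks = np.array_split(uniq, n_folds)
    folds = []
    idx = np.arange(len(groups))
    for chunk in chunks:
        test = idx[np.isin(groups, chunk)]
        train = idx[~np.isin(groups, chunk)]
        folds.append((train, test))
    return folds


def rfe_select(
    features: pd.DataFrame,
    labels: Sequence[int],
    participant_ids: Sequence[str],
    seed: int = 0,
    n_repetitions: int = 5,
    n_folds: int = 10,
    consensus_min: int = 3,
) -> SelectionResult:
    """Recursive feature elimination repeated over participant splits.

    Each of ``n_repetitions`` runs uses a fresh participant-grouped
    ``n_folds``-fold split; within a run, an L2-regularized logistic
    estimator inside cross-validated RFE picks the subset size with the
    best mean CV score. Features present in at least ``consensus_min`` of
    the repetition subsets form the consensus. Deterministic per seed.
    """
    groups = np.asarray(list(participant_ids))
    uniq = set(groups)
    if len(uniq) < n_folds:
        raise ValueError(
            f"need at least {n_folds} participants for {n_folds}-fold grouped CV, got {len(uniq)}"
        )
    y = np.asarray(labels, dtype=int)
    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    result = SelectionResult()
    for _ in range(n_repetitions):
        folds = _grouped_folds(groups, n_folds, rng)
        est = LogisticRegression(C=1.0, max_iter=2000)  # L2 ridge penalty (default)
        rfecv = RFECV(est, cv=folds, scoring="accuracy", min_features_to_select=1)
        rfecv.fit(X, y)
        chosen = {c for c, keep in zip(features.columns, rfecv.support_) if keep}
        result.repetition_sets.append(chosen)
    counts = {c: sum(c in s for s in result.repetition_sets) for c in features.columns}
    result.consensus = [c for c in features.columns if counts[c] >= consensus_min]
    return result


# ---------------------------------------------------------------------------
# VIF reduction
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=0)
    return (x - np.mean(x)) / sd


def compute_vif(features: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per column (intercept included)."""
    X = features.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(X)), X])
    with np.errstate(divide="ignore"):  # perfectly collinear columns give inf
        return {
            col: float(variance_inflation_factor(X, i + 1))
            for i, col in enumerate(features.columns)
        }


def vif_reduce(
    features: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> tuple[pd.DataFrame, SelectionResult]:
    """Merge collinear features into standardized sums until all VIFs
    are at or below ``threshold``.

    While the largest VIF exceeds the threshold, the offending feature
    and its most-correlated partner are replaced by the sum of their
    z-scores, named ``"a+b"``. Terminates because every step reduces the
    column count by one. Raises on constant columns, for which VIF is
    undefined.
    """
    if features.shape[1] < 2:
        raise ValueError("VIF reduction needs at least 2 features")
    for col in features.columns:
        if float(np.std(features[col].to_numpy(dtype=float))) == 0.0:
            raise ValueError(f"feature {col!r} is constant; VIF undefined")
    work = features.copy()
    result = SelectionResult()
    while work.shape[1] >= 2:
        vifs = compute_vif(work)
        worst = max(vifs, key=vifs.get)
        if vifs[worst] <= threshold:
            break
        corr = work.corr().abs()
        partner = corr[worst].drop(worst).idxmax()
        combined_name = f"{worst}+{partner}"
        combined = _zscore(work[worst].to_numpy(dtype=float)) + _zscore(
            work[partner].to_numpy(dtype=float)
        )
        constituents = result.combinations.pop(worst, [worst]) + result.combinations.pop(
            partner, [partner]
        )
        work = work.drop(columns=[worst, partner])
        work[combined_name] = combined
        result.combinations[combined_name] = constituents
    result.final_vif = compute_vif(work) if work.shape[1] >= 2 else {}
    return work, result


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ModelMetrics:
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    auc: float


@dataclass
class ClassifierReport:
    """Pooled out-of-fold metrics per model family, plus the logistic
    model's full-data coefficients and odds ratios."""

    metrics: dict[str, ModelMetrics]
    lr_coefficients: dict[str, float]
    lr_intercept: float

    @property
    def lr_odds_ratios(self) -> dict[str, float]:
        return odds_ratios(self.lr_coefficients)


def _model_zoo(seed: int) -> dict[str, Pipeline]:
    return {
        "LR": Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
        ),
        "SVM": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", random_state=seed)),
            ]
        ),
        "RF": Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", RandomForestClassifier(n_estimators=200, random_state=seed)),
            ]
        ),
    }


def train_evaluate(
    features: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    n_folds: int = 5,
    global_standardization: bool = False,
) -> ClassifierReport:
    """Stratified ``n_folds``-fold evaluation of LR, SVM and RF.

    Standardization is fitted on each training fold and applied to its
    test fold (set ``global_standardization`` to normalize once on the
    full table instead). Out-of-fold scores are pooled and the metrics —
    sensitivity, specificity, F1, accuracy, AUC — computed once on the
    pool, with a 0.5 threshold for the class metrics. The reported
    logistic coefficients come from a full-data refit on standardized
    features; exponentiating them gives odds ratios per one standard
    deviation of the input.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size != 2:
        raise ValueError("training needs exactly two classes")
    X = features.to_numpy(dtype=float)
    if global_standardization:
        X = StandardScaler().fit_transform(X)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for tr, _ in folds:
        if np.unique(y[tr]).size < 2:
            raise ValueError("a training fold contains a single class; use a larger cohort")
    metrics: dict[str, ModelMetrics] = {}
    for name, pipe in _model_zoo(seed).items():
        scores = np.zeros(len(y))
        pred = np.zeros(len(y), dtype=int)
        for tr, te in folds:
            pipe.fit(X[tr], y[tr])
            if hasattr(pipe, "predict_proba"):
                scores[te] = pipe.predict_proba(X[te])[:, 1]
                pred[te] = (scores[te] >= 0.5).astype(int)
            else:  # margin scores rank identically for AUC
                scores[te] = pipe.decision_function(X[te])
                pred[te] = pipe.predict(X[te])
        tn, fp, fn, tp = confusion_matrix(y, pred).ravel()
        metrics[name] = ModelMetrics(
            sensitivity=tp / (tp + fn) if tp + fn else 0.0,
            specificity=tn / (tn + fp) if tn + fp else 0.0,
            f1=float(f1_score(y, pred)),
            accuracy=float(accuracy_score(y, pred)),
            auc=float(roc_auc_score(y, scores)),
        )
    full = Pipeline(
        [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=2000))]
    ).fit(X, y)
    coefs = full.named_steps["clf"].coef_[0]
    return ClassifierReport(
        metrics=metrics,
        lr_coefficients={c: float(b) for c, b in zip(features.columns, coefs)},
        lr_intercept=float(full.named_steps["clf"].intercept_[0]),
    )


def odds_ratios(coefficients: Mapping[str, float]) -> dict[str, float]:
    """Odds ratio per coefficient: exp(beta)."""
    out = {}
    for name, b in coefficients.items():
        if not math.isfinite(b):
            raise ValueError(f"coefficient for {name!r} is not finite")
        out[name] = math.exp(b)
    return out


# ---------------------------------------------------------------------------
# published reference logistic models
# ---------------------------------------------------------------------------

#: input bindings: each model input is the sum of the standardized
#: constituent features listed here.
ERROR_BASED_BINDINGS: dict[str, list[str]] = {
    "X1": ["speed_iqr"],
    "X2": ["curve_iqr"],
    "X3": ["heading_sampen"],
    "X4": ["fs_sampen"],
    "X5": ["crows_median", "fs_iqr"],
}
USER_BASED_BINDINGS: dict[str, list[str]] = {
    "X1": ["quality_sampen"],
    "X2": ["heading_std"],
    "X3": ["curve_mean", "curve_sampen"],
    "X4": ["deltaheading_mean", "deltaheading_iqr"],
}
ERROR_BASED_COEFS = {"X1": 0.26, "X2": 0.52, "X3": 0.51, "X4": -0.18, "X5": 0.26}
ERROR_BASED_INTERCEPT = -0.22
USER_BASED_COEFS = {"X1": 1.03, "X2": 0.81, "X3": -2.65, "X4": 1.54}
USER_BASED_INTERCEPT = 0.90


@dataclass
class ReferenceLogisticModel:
    """A published logistic model with its feature bindings.

    The publication does not include the standardization statistics of
    its inputs, so absolute probabilities depend on the (mean, sd) pairs
    supplied here; the packaged defaults were fitted on a seeded
    simulated cohort and make the output approximate for real traces.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    bindings: dict[str, list[str]]
    standardization: dict[str, tuple[float, float]]

    def predict_from_inputs(self, inputs: Mapping[str, float]) -> float:
        """Probability from already-standardized model inputs X1..Xn."""
        z = self.intercept
        for xname, beta in self.coefficients.items():
            if xname not in inputs:
                raise KeyError(f"missing model input {xname!r}")
            z += beta * inputs[xname]
        return 1.0 / (1.0 + math.exp(-z))

    def predict(self, features: Mapping[str, float]) -> float:
        """Probability of the positive class (high error / unconventional)
        from raw named features."""
        inputs = {}
        for xname, constituents in self.bindings.items():
            total = 0.0
            for feat in constituents:
                if feat not in features:
                    raise KeyError(f"missing feature {feat!r} required by {self.name}")
                mu, sd = self.standardization[feat]
                total += (features[feat] - mu) / sd if sd > 0 else 0.0
            inputs[xname] = total
        return self.predict_from_inputs(inputs)


def _load_default_standardization() -> dict[str, tuple[float, float]]:
    ref = resources.files("walk6mwt.data").joinpath("reference_standardization.json")
    doc = json.loads(ref.read_text())
    return {k: (v["mean"], v["sd"]) for k, v in doc["features"].items()}


def load_reference_model(
    which: str,
    standardization: Optional[dict[str, tuple[float, float]]] = None,
) -> ReferenceLogisticModel:
    """Load the error-based or user-based published model.

    ``standardization`` maps constituent feature names to (mean, sd); the
    packaged simulator-cohort statistics are used when omitted.
    """
    if standardization is None:
        standardization = _load_default_standardization()
    if which == "error_based":
        return ReferenceLogisticModel(
            name="error_based",
            intercept=ERROR_BASED_INTERCEPT,
            coefficients=dict(ERROR_BASED_COEFS),
            bindings={k: list(v) for k, v in ERROR_BASED_BINDINGS.items()},
            standardization=standardization,
        )
    if which == "user_based":
        return ReferenceLogisticModel(
            name="user_based",
            intercept=USER_BASED_INTERCEPT,
            coefficients=dict(USER_BASED_COEFS),
            bindings={k: list(v) for k, v in USER_BASED_BINDINGS.items()},
            standardization=standardization,
        )
    raise ValueError(f"unknown reference model {which!r}")
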