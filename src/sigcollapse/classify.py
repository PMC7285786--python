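"""Diagnostic scoring of signatures with regularized logistic regression.

The feature space is the de-duplicated union of signature members, z-scaled
with parameters fit on the training cohort only.  The inverse-regularization
strength C is chosen by stratified k-fold cross-validation over a log-spaced
grid, scoring by ROC-AUC (ties broken toward the smaller C, i.e. stronger
regularization); the final model is refit on the full training cohort at the
chosen C.  An L1 penalty yields the sparse feature selection; evaluation on
held-out cohorts and per-time-point cohorts always reuses the frozen
training scaler and coefficients.

Surface is statsmodels-style: :class:`SignatureClassifier` is the model,
``fit()`` returns a :class:`ClassifierResult` carrying coefficients, the CV
table, AUCs and a ``summary()``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionMatrix
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 13))


def _logreg(penalty: str, C: float, seed: int) -> LogisticRegression:
    # scikit-learn >= 1.8 expresses the penalty through l1_ratio
    return LogisticRegression(l1_ratio=1.0 if penalty == "l1" else 0.0, C=C,
                              solver="liblinear", random_state=seed, max_iter=1000)


# ---------------------------------------------------------------------------
# Features and scaling
# ---------------------------------------------------------------------------


def build_features(sigs: SignatureSet, m: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Samples x features matrix (lexicographic de-duplicated signature genes)
    and 0/1 labels (case = 1)."""
    genes = sigs.unique_genes
    missing = sorted(set(genes) - set(m.values.index))
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    X = m.values.loc[genes].T.copy()
    y = (m.group.to_numpy() == "case").astype(int)
    return X, y


@dataclass(frozen=True)
class Scaler:
    """Per-feature (mean, sd) z-scaling parameters."""

    mean: pd.Series
    sd: pd.Series


def zscale_fit(train: pd.DataFrame) -> Scaler:
    """Fit z-scaling on training data; constant columns are an error."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")
    return Scaler(mean=mean, sd=sd)


def zscale_apply(scaler: Scaler, data: pd.DataFrame) -> pd.DataFrame:
    missing = sorted(set(scaler.mean.index) - set(data.columns))
    if missing:
        raise KeyError(f"features absent from data: {missing}")
    data = data[scaler.mean.index]
    return (data - scaler.mean) / scaler.sd


# ---------------------------------------------------------------------------
# ROC-AUC (Mann-Whitney convention)
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(score_case > score_control) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class ClassifierResult:
    """A fitted, frozen signature classifier.

    ``coefficients`` are on the z-scaled feature space; ``decision_function``
    applies the frozen scaler, so it accepts raw (unscaled) feature frames.
    """

    feature_names: tuple[str, ...]
    scaler: Scaler
    penalty: str
    C: float
    coefficients: np.ndarray
    intercept: float
    cv_results: pd.DataFrame
    train_auc: float
    test_auc: float | None = None
    timepoint_auc: dict[str, float] = field(default_factory=dict)

    @property
    def selected_features(self) -> list[str]:
        return [g for g, c in zip(self.feature_names, self.coefficients) if c != 0]

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        Z = zscale_apply(self.scaler, X)
        return Z.to_numpy() @ self.coefficients + self.intercept

    def evaluate(self, X: pd.DataFrame, y: Sequence[int]) -> float:
        """ROC-AUC on a held-out cohort; stored as ``test_auc``."""
        auc = roc_auc(self.decision_function(X), y)
        self.test_auc = auc
        return auc

    def summary(self) -> str:
        coefs = pd.Series(self.coefficients, index=self.feature_names)
        coefs = coefs.reindex(coefs.abs().sort_values(ascending=False).index)
        lines = [
            f"Signature classifier ({self.penalty} penalty, C = {self.C:g})",
            f"  features: {len(self.feature_names)}   nonzero: {len(self.selected_features)}",
            f"  train ROC-AUC: {self.train_auc:.3f}"
            + (f"   test ROC-AUC: {self.test_auc:.3f}" if self.test_auc is not None else ""),
        ]
        if self.timepoint_auc:
            lines.append("  per-timepoint AUC: "
                         + ", ".join(f"{tp}={auc:.3f}" for tp, auc in self.timepoint_auc.items()))
        lines += ["", "Coefficients (z-scaled features):",
                  coefs.to_string(float_format=lambda v: f"{v: .4f}")]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "scaler": {"mean": self.scaler.mean.tolist(), "sd": self.scaler.sd.tolist()},
            "penalty": self.penalty,
            "C": self.C,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "train_auc": self.train_auc,
            "test_auc": self.test_auc,
            "timepoint_auc": self.timepoint_auc,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierResult":
        payload = json.loads(Path(path).read_text())
        names = tuple(payload["feature_names"])
        scaler = Scaler(mean=pd.Series(payload["scaler"]["mean"], index=names),
                        sd=pd.Series(payload["scaler"]["sd"], index=names))
        return cls(feature_names=names, scaler=scaler, penalty=payload["penalty"],
                   C=payload["C"], coefficients=np.asarray(payload["coefficients"]),
                   intercept=payload["intercept"], cv_results=pd.DataFrame(),
                   train_auc=payload["train_auc"], test_auc=payload.get("test_auc"),
                   timepoint_auc=payload.get("timepoint_auc", {}))


def train_logistic(X: pd.DataFrame, y: Sequence[int], penalty: str = "l2",
                   C_grid: Sequence[float] = DEFAULT_C_GRID, folds: int = 10,
                   seed: int = 0) -> ClassifierResult:
    """Grid-search CV over C, then refit on the full training data.

    Within each CV fold the scaler is fit on the fold's training part only;
    the final frozen scaler is fit on all training data.  Deterministic
    under a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    class_counts = np.bincount(y)
    if class_counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} members for {folds}-fold CV "
                         f"(got {class_counts.tolist()})")
    if penalty not in ("l1", "l2"):
        raise ValueError(f"penalty must be 'l1' or 'l2', got {penalty!r}")
    C_grid = sorted(float(c) for c in C_grid)
    if any(c <= 0 for c in C_grid):
        raise ValueError("C values must be positive")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cv_rows = []
    for C in C_grid:
        fold_aucs = []
        for train_idx, val_idx in splits:
            scaler = zscale_fit(X.iloc[train_idx])
            Zt = zscale_apply(scaler, X.iloc[train_idx])
            Zv = zscale_apply(scaler, X.iloc[val_idx])
            model = _logreg(penalty, C, seed)
            model.fit(Zt, y[train_idx])
            fold_aucs.append(roc_auc(model.decision_function(Zv), y[val_idx]))
        cv_rows.append({"C": C, "mean_cv_auc": float(np.mean(fold_aucs)),
                        "sd_cv_auc": float(np.std(fold_aucs))})
    cv = pd.DataFrame(cv_rows)
    # grid is ascending, strict '>' keeps the smallest C on ties
    best_C, best_auc = None, -np.inf
    for row in cv_rows:
        if row["mean_cv_auc"] > best_auc:
            best_C, best_auc = row["C"], row["mean_cv_auc"]

    scaler = zscale_fit(X)
    Z = zscale_apply(scaler, X)
    model = _logreg(penalty, best_C, seed)
    model.fit(Z, y)
    coefficients = model.coef_.ravel()
    intercept = float(model.intercept_[0])
    train_auc = roc_auc(Z.to_numpy() @ coefficients + intercept, y)
    return ClassifierResult(feature_names=tuple(X.columns), scaler=scaler,
                            penalty=penalty, C=best_C, coefficients=coefficients,
                            intercept=intercept, cv_results=cv, train_auc=train_auc)


class SignatureClassifier:
    """Regularized logistic-regression model over a signature set's genes.

    Parameters
    ----------
    signatures : SignatureSet
        Validated signatures whose de-duplicated gene union is the feature
        space.
    penalty : {"l2", "l1"}
        L2 for the full diagnostic model, L1 for sparse feature selection.
    """

    def __init__(self, signatures: SignatureSet, penalty: str = "l2",
                 C_grid: Sequence[float] = DEFAULT_C_GRID, folds: int = 10,
                 seed: int = 0):
        self.signatures = signatures
        self.penalty = penalty
        self.C_grid = tuple(C_grid)
        self.folds = folds
        self.seed = seed

    def fit(self, train: ExpressionMatrix) -> ClassifierResult:
        X, y = build_features(self.signatures, train)
        return train_logistic(X, y, penalty=self.penalty, C_grid=self.C_grid,
                              folds=self.folds, seed=self.seed)


def evaluate_timepoints(result: ClassifierResult,
                        cohorts: Mapping[str, ExpressionMatrix | tuple[pd.DataFrame, Sequence[int]]],
                        sigs: SignatureSet | None = None) -> dict[str, float]:
    """Apply the frozen scaler+model to each time-point cohort.

    Cohorts may be :class:`ExpressionMatrix` objects (features are extracted
    by gene name) or pre-built ``(X, y)`` pairs.  The AUC map is stored on
    the result and returned.
    """
    aucs: dict[str, float] = {}
    for tp, cohort in cohorts.items():
        if isinstance(cohort, ExpressionMatrix):
            X = cohort.values.loc[list(result.feature_names)].T
            y = (cohort.group.to_numpy() == "case").astype(int)
        else:
            X, y = cohort
        aucs[tp] = roc_auc(result.decision_function(X), y)
    result.timepoint_auc = aucs
    return aucs


def select_features_l1(result: ClassifierResult, tol: float = 1e-8) -> list[str]:
    """Genes with ``|coefficient| > tol``, ordered by |coefficient| descending."""
    coefs = pd.Series(result.coefficients, index=result.feature_names)
    picked = coefs[coefs.abs() > tol]
    return list(picked.reindex(picked.abs().sort_values(ascending=False).index).index)
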