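"""Supervised subspecies assignment from panel genotypes.

Genotypes are one-hot encoded with an explicit *missing* state — a
systematically failing marker (null allele) is informative about
subspecies and is kept as signal rather than imputed away.  Candidate
classifiers are compared by stratified k-fold cross-validation; the
winner (by default a linear support-vector classifier, whose margins
are mapped to probabilities by cross-validated sigmoid calibration
fitted on training data only) emits a per-class probability table.
Samples whose top probability falls below a rejection threshold
(default 0.90) are reported as unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC, LinearSVC

from .errors import LayoutError, ParameterError, ValidationError
from .io_formats import MISSING, GenotypeMatrix, SnpKey

#: per-SNP one-hot block layout
STATES = ("hom_ref", "het", "hom_alt", "missing")
UNASSIGNED = "unassigned"


@dataclass
class FeatureMatrix:
    """Samples x (4 * n_snps) binary indicators, one block per SNP."""

    values: np.ndarray
    samples: list[str]
    snps: list[SnpKey]

    def __post_init__(self) -> None:
        expected = (len(self.samples), 4 * len(self.snps))
        if self.values.shape != expected:
            raise ValidationError(f"feature matrix must have shape {expected}")

    @property
    def column_names(self) -> list[str]:
        return [f"{snp}|{state}" for snp in self.snps for state in STATES]


def one_hot_encode(gm: GenotypeMatrix) -> FeatureMatrix:
    """Expand each genotype into a (hom-ref, het, hom-alt, missing) block.

    Exactly one indicator per block is set; column order is SNP order x
    state order and is deterministic.
    """
    state_index = {0: 0, 1: 1, 2: 2, MISSING: 3}
    n, m = gm.g.shape
    out = np.zeros((n, 4 * m), dtype=np.uint8)
    cols = 4 * np.arange(m)[None, :] + np.vectorize(state_index.get)(gm.g)
    rows = np.repeat(np.arange(n)[:, None], m, axis=1)
    out[rows.ravel(), cols.ravel()] = 1
    return FeatureMatrix(out, list(gm.samples), list(gm.snps))


def split_reference(samples: list[str], train_fraction: float = 0.7,
                    seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded shuffle-and-split; train size = floor(fraction * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError("train_fraction must be in (0, 1)")
    if len(samples) < 2:
        raise ParameterError("need at least 2 samples to split")
    order = list(samples)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    n_train = int(np.floor(train_fraction * len(order)))
    return order[:n_train], order[n_train:]


def default_candidates(seed: int = 0) -> dict[str, object]:
    """The candidate model family compared by cross-validation."""
    return {
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=2000, C=1.0),
        "svm_rbf": SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "linear_svc": LinearSVC(C=1.0, max_iter=5000, random_state=seed),
    }


def linear_candidates(seed: int = 0) -> dict[str, object]:
    """Just the two linear candidates (cheap model selection)."""
    cands = default_candidates(seed)
    return {k: cands[k] for k in ("logistic_regression", "linear_svc")}


def evaluate_candidates(
    candidates: dict[str, object],
    features: FeatureMatrix,
    labels: pd.Series | list[str],
    k_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified k-fold CV accuracy (mean, SD) per candidate.

    Rows are sorted best-first: highest mean accuracy, ties broken by
    lowest SD, then candidate name.  When the rarest class has fewer
    samples than ``k_folds`` the fold count degrades with a warning.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    n_splits = k_folds
    if counts.min() < k_folds:
        n_splits = max(2, int(counts.min()))
        warnings.warn(
            f"rarest class has {counts.min()} samples; using {n_splits}-fold CV "
            f"instead of {k_folds}",
            stacklevel=2,
        )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rows = []
    for name, est in candidates.items():
        scores = cross_val_score(clone(est), features.values, y, cv=cv, scoring="accuracy")
        rows.append({"model": name, "cv_accuracy_mean": scores.mean(),
                     "cv_accuracy_sd": scores.std()})
    report = pd.DataFrame(rows).sort_values(
        ["cv_accuracy_mean", "cv_accuracy_sd", "model"],
        ascending=[False, True, True],
    )
    return report.reset_index(drop=True)


@dataclass
class AssignmentModel:
    """A fitted classifier plus the metadata needed to reuse it safely."""

    estimator: object            # exposes predict_proba
    classes: list[str]
    snps: list[SnpKey]
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "AssignmentModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValidationError(f"{path} does not contain an AssignmentModel")
        return model


def fit(
    estimator,
    features: FeatureMatrix,
    labels: pd.Series | list[str],
    seed: int = 0,
    calibration: str = "isotonic",
    calibration_cv: int = 5,
    name: str | None = None,
) -> AssignmentModel:
    """Fit a candidate on the training set and make it probabilistic.

    Margin-based models without ``predict_proba`` (e.g. LinearSVC) are
    wrapped in cross-validated calibration, fitted on the training data
    only.  Isotonic calibration is the default: with a multi-way
    one-vs-rest problem, sigmoid calibration leaves every negative class
    a non-negligible probability, which after row normalisation caps the
    top-class probability well below 1 even for unambiguous samples and
    makes a high rejection threshold unusable.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("training set must contain at least 2 classes")
    est = clone(estimator)
    if hasattr(est, "random_state"):
        est.set_params(random_state=seed)
    calibrated = not hasattr(est, "predict_proba")
    if calibrated:
        min_count = int(np.unique(y, return_counts=True)[1].min())
        cv = min(calibration_cv, max(2, min_count))
        est = CalibratedClassifierCV(est, method=calibration, cv=cv)
    est.fit(features.values, y)
    return AssignmentModel(
        estimator=est,
        classes=[str(c) for c in est.classes_],
        snps=list(features.snps),
        metadata={"seed": seed, "candidate": name or type(estimator).__name__,
                  "n_train": len(y),
                  "calibration": calibration if calibrated else "native"},
    )


def predict_probabilities(model: AssignmentModel, features: FeatureMatrix) -> pd.DataFrame:
    """Per-sample class probabilities; rows sum to 1.

    The feature layout (SNP list and order) must match the one the model
    was trained on; the first mismatching SNP block is named in the
    error.
    """
    if features.snps != model.snps:
        for k, (a, b) in enumerate(zip(model.snps, features.snps)):
            if a != b:
                raise LayoutError(
                    f"feature layout mismatch at SNP block {k}: model expects {a}, got {b}"
                )
        raise LayoutError(
            f"feature layout mismatch: model expects {len(model.snps)} SNPs, "
            f"got {len(features.snps)}"
        )
    probs = model.estimator.predict_proba(features.values)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, index=features.samples, columns=model.classes)


@dataclass(frozen=True)
class AssignmentConfig:
    """Rejection rule: assign argmax class iff its probability >= threshold."""

    threshold: float = 0.90
    unassigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ParameterError("threshold must be in [0, 1]")


def assign(probs: pd.DataFrame, config: AssignmentConfig = AssignmentConfig()) -> pd.Series:
    """Label each sample with its argmax class, or unassigned below the
    threshold.  Exact argmax ties go to the first class in column order."""
    vals = probs.to_numpy()
    best = vals.argmax(axis=1)
    best_p = vals[np.arange(len(vals)), best]
    labels = np.array(probs.columns, dtype=object)[best]
    labels[best_p < config.threshold] = config.unassigned_label
    return pd.Series(labels, index=probs.index, name="assignment")
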