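"""Performance reporting for subspecies assignment.

Confusion matrices keep unassigned samples in a separate tally: when a
rejection threshold is active, row percentages and accuracy are
computed over *assigned* samples only, with raw counts always retained
alongside.  Also provides lineage collapsing, threshold sweeps, call
rates, a t-SNE embedding and k-NN label-outlier flagging.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .classify import UNASSIGNED
from .errors import ParameterError, ValidationError
from .io_formats import MISSING, GenotypeMatrix


@dataclass
class ConfusionMatrix:
    """True x predicted counts plus a per-true-class unassigned tally."""

    classes: list[str]
    counts: pd.DataFrame          # true x predicted, integers
    unassigned: pd.Series         # per true class
    threshold_active: bool = False

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any() or (self.unassigned < 0).any():
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum() + self.unassigned.sum())

    def row_percentages(self, decimals: int = 1) -> pd.DataFrame:
        """Row percentages over assigned samples; rows with no assigned
        samples come out as zeros."""
        c = self.counts.to_numpy(dtype=float)
        denom = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pct = np.where(denom > 0, 100.0 * c / np.maximum(denom, 1), 0.0)
        return pd.DataFrame(pct, index=self.counts.index,
                            columns=self.counts.columns).round(decimals)


def confusion(
    true_labels: Sequence[str],
    predictions: Sequence[str],
    classes: Sequence[str],
    count_unassigned: bool = True,
) -> ConfusionMatrix:
    """Cross-tabulate true vs predicted classes.

    Unassigned predictions are excluded from the count matrix and
    tallied per true class (when ``count_unassigned``); any other label
    outside ``classes`` is an error.
    """
    if len(true_labels) != len(predictions):
        raise ValidationError(
            f"{len(true_labels)} true labels vs {len(predictions)} predictions"
        )
    classes = list(classes)
    class_set = set(classes)
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    unassigned = pd.Series(0, index=classes, dtype=int)
    saw_unassigned = False
    for t, p in zip(true_labels, predictions):
        if t not in class_set:
            raise ValidationError(f"true label {t!r} not in class list")
        if p == UNASSIGNED:
            if not count_unassigned:
                raise ValidationError(
                    "unassigned prediction encountered with count_unassigned=False"
                )
            unassigned[t] += 1
            saw_unassigned = True
        elif p in class_set:
            counts.loc[t, p] += 1
        else:
            raise ValidationError(f"predicted label {p!r} not in class list")
    return ConfusionMatrix(classes, counts, unassigned, threshold_active=saw_unassigned)


def accuracy_report(cm: ConfusionMatrix) -> dict:
    """Overall and per-class accuracy bookkeeping.

    Without a threshold the denominators are all test samples; with a
    threshold active, percentages are over assigned samples only and the
    unassigned count is reported separately.
    """
    c = cm.counts.to_numpy(dtype=float)
    n_assigned = c.sum()
    n_total = cm.total
    if n_total == 0:
        raise ValidationError("empty confusion matrix")
    correct = np.trace(c)
    denom = n_assigned if cm.threshold_active else n_total
    per_class = {}
    for k, cls in enumerate(cm.classes):
        row_assigned = c[k].sum()
        row_total = row_assigned + cm.unassigned[cls]
        row_denom = row_assigned if cm.threshold_active else row_total
        per_class[cls] = 100.0 * c[k, k] / row_denom if row_denom > 0 else float("nan")
    return {
        "n_total": int(n_total),
        "n_assigned": int(n_assigned),
        "n_unassigned": int(cm.unassigned.sum()),
        "denominator": "assigned" if cm.threshold_active else "total",
        "overall_accuracy_pct": 100.0 * correct / denom if denom else float("nan"),
        "misclassified_pct": 100.0 * (n_assigned - correct) / denom if denom else float("nan"),
        "per_class_accuracy_pct": per_class,
    }


def collapse_to_lineage(predictions: Sequence[str],
                        lineage_map: Mapping[str, str]) -> list[str]:
    """Replace subspecies labels by their lineage; unassigned passes through."""
    out = []
    for p in predictions:
        if p == UNASSIGNED:
            out.append(p)
        elif p in lineage_map:
            out.append(lineage_map[p])
        else:
            raise ValidationError(f"no lineage mapping for class {p!r}")
    return out


def threshold_sweep(probs: pd.DataFrame, true_labels: Sequence[str],
                    taus: Iterable[float]) -> pd.DataFrame:
    """Assignment bookkeeping across a grid of rejection thresholds.

    For each tau: the assigned fraction, and accuracy / misclassification
    among assigned samples.  Assigned + unassigned = total at every tau.
    """
    y = np.asarray(true_labels)
    vals = probs.to_numpy()
    best = vals.argmax(axis=1)
    best_p = vals[np.arange(len(vals)), best]
    pred = np.array(probs.columns, dtype=object)[best]
    rows = []
    for tau in taus:
        # tau slightly above 1 is allowed: it keeps only probability-1 calls
        if not 0.0 <= tau <= 1.0 + 1e-6:
            raise ParameterError(f"threshold {tau} outside [0, 1]")
        assigned = best_p >= tau
        n_assigned = int(assigned.sum())
        correct = int((pred[assigned] == y[assigned]).sum())
        rows.append({
            "tau": tau,
            "n_total": len(y),
            "n_assigned": n_assigned,
            "n_unassigned": len(y) - n_assigned,
            "assigned_fraction": n_assigned / len(y),
            "accuracy_assigned_pct":
                100.0 * correct / n_assigned if n_assigned else float("nan"),
            "misclassified_assigned_pct":
                100.0 * (n_assigned - correct) / n_assigned if n_assigned else float("nan"),
        })
    return pd.DataFrame(rows)


def call_rate(gm: GenotypeMatrix) -> tuple[pd.Series, pd.Series | None]:
    """Per-sample fraction of non-missing genotypes, and per-subspecies
    means when the matrix carries labels."""
    non_missing = (gm.g != MISSING).mean(axis=1)
    per_sample = pd.Series(non_missing, index=gm.samples, name="call_rate")
    per_class = None
    if gm.labels is not None:
        sub = gm.label_series("subspecies")
        per_class = per_sample.groupby(sub).mean()
    return per_sample, per_class


def embed_2d(features: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding to 2-D; deterministic for a given seed."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise ParameterError("embedding needs at least 3 samples")
    if perplexity >= X.shape[0]:
        raise ParameterError(
            f"perplexity {perplexity} must be smaller than the sample count {X.shape[0]}"
        )
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(X)


def flag_label_outliers(gm: GenotypeMatrix, labels: Mapping[str, str] | pd.Series,
                        k: int = 10) -> list[str]:
    """Flag samples whose k nearest neighbours vote for a different label.

    Distance is the Hamming distance over genotype states where a
    missing call never matches anything (including another missing
    call).  Neighbour ties at equal distance and majority-vote ties are
    broken deterministically (sample order, then alphabetical label).
    """
    n = gm.n_samples
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the sample count {n}")
    lab = pd.Series(labels)
    lab = lab.reindex(gm.samples)
    if lab.isna().any():
        raise ValidationError("every sample needs a label for outlier flagging")

    # matches via one-hot over the three called states; missing matches nothing
    onehot = np.stack([(gm.g == s) for s in (0, 1, 2)], axis=2).reshape(n, -1)
    matches = onehot.astype(np.float32) @ onehot.astype(np.float32).T
    dist = gm.n_snps - matches
    np.fill_diagonal(dist, np.inf)

    flagged = []
    for i in range(n):
        order = np.lexsort((np.arange(n), dist[i]))[:k]
        votes = Counter(lab.iloc[j] for j in order)
        top = max(votes.items(), key=lambda kv: (kv[1], ), default=(None, 0))
        # alphabetical tie-break among equally common labels
        best_count = top[1]
        winner = sorted(l for l, c in votes.items() if c == best_count)[0]
        if winner != lab.iloc[i]:
            flagged.append(gm.samples[i])
    return flagged
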