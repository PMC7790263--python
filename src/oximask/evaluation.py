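"""Validation of discriminating algorithms: confusion matrices,
accuracy rates, outlier screening and swap-based cross-validation.

The cross-validation scheme mirrors the original study design: the
held-out validation sites are returned to the pooled data, an equally
sized (per class) replacement validation set is drawn at random from
the original construction sites, the boundary is refitted on the
remaining pool and scored on the replacement set. The study drew the
replacement with a random number table; here a seeded pseudo-random
generator plays that role so every replicate is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discriminant import (
    DiscriminantLine,
    LabeledFeatureSet,
    classify_points,
    fit_lda,
)
from .exceptions import DomainError, FitError, ValidationError


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts for one discrimination task; rows are the true class,
    columns the predicted class (positive = adherent substance)."""

    positive_class: str
    negative_class: str
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"count {name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
        }

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: rows true class, columns Positive/Negative."""
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=[self.positive_class, self.negative_class],
            columns=["Positive", "Negative"],
        )


def accuracy_rate(cm: ConfusionMatrix) -> float:
    """Percent of correctly classified sites, ``100*(tp+tn)/total``.

    Stored at full precision; display rounds to one decimal.
    """
    if cm.total == 0:
        raise DomainError("accuracy rate is undefined for an empty confusion matrix")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def format_accuracy(percent: float) -> str:
    """One-decimal display convention, e.g. ``'95.9'``."""
    return f"{percent:.1f}"


def evaluate(model: DiscriminantLine, test: LabeledFeatureSet) -> ConfusionMatrix:
    """Score a boundary on a labeled feature set."""
    labels = test.labels.astype(str)
    allowed = {model.positive_class, model.negative_class}
    foreign = sorted(set(labels) - allowed)
    if foreign:
        raise ValidationError(
            f"test set contains labels {foreign} foreign to the model's "
            f"classes {sorted(allowed)}"
        )
    predicted = classify_points(test.points, model).astype(str)
    is_pos = labels == model.positive_class
    pred_pos = predicted == model.positive_class
    return ConfusionMatrix(
        positive_class=model.positive_class,
        negative_class=model.negative_class,
        tp=int(np.sum(is_pos & pred_pos)),
        fn=int(np.sum(is_pos & ~pred_pos)),
        fp=int(np.sum(~is_pos & pred_pos)),
        tn=int(np.sum(~is_pos & ~pred_pos)),
    )


def exclude_outliers(
    data: LabeledFeatureSet, quantile: float = 0.999
) -> tuple[LabeledFeatureSet, list[int]]:
    """Screen per-class outliers by within-class Mahalanobis distance.

    A point is excluded when its squared Mahalanobis distance from its
    own class mean (class covariance, unbiased estimate) exceeds the
    chi-square quantile with 2 degrees of freedom. The original study
    excluded a single aberrant validation site by inspection; this is
    the rule-based analogue and is off by default in the pipeline.

    Returns the kept subset and the list of excluded original indices.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValidationError(f"quantile must be in (0, 1], got {quantile}")
    labels = data.labels.astype(str)
    threshold = float(stats.chi2.ppf(quantile, df=2))
    excluded: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValidationError(
                f"class {cls!r} has {idx.size} points; >= 3 required"
            )
        pts = data.points[idx]
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T)
        if np.linalg.cond(cov) > 1e12:
            raise FitError(f"degenerate covariance for class {cls!r}")
        centred = pts - mean
        d2 = np.einsum("ij,ij->i", centred @ np.linalg.inv(cov), centred)
        excluded.extend(idx[d2 > threshold].tolist())
    excluded.sort()
    keep = np.setdiff1d(np.arange(len(data)), np.array(excluded, dtype=int))
    return data.subset(keep), excluded


@dataclass(frozen=True)
class CrossValReport:
    """Result of one swap replicate."""

    replicate_id: int
    line: DiscriminantLine
    confusion: ConfusionMatrix
    accuracy_percent: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy_percent <= 100.0:
            raise ValidationError("accuracy_percent must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "replicate_id": self.replicate_id,
            "line": self.line.to_dict(),
            "confusion": self.confusion.to_dict(),
            "accuracy_percent": self.accuracy_percent,
            "seed": self.seed,
        }


def cross_validate(
    train: LabeledFeatureSet,
    validation: LabeledFeatureSet,
    replicates: int,
    seed: int,
    priors: str = "equal",
    positive_class: str | None = None,
    swap: bool = True,
) -> list[CrossValReport]:
    """Swap-based cross-validation of a discriminating algorithm.

    Per replicate: (1) the original validation sites join the training
    pool; (2) a replacement validation set matching the original
    validation's per-class counts is drawn uniformly without
    replacement from the *original training* sites; (3) the boundary is
    refitted on the remaining pool; (4) the refit is scored on the
    replacement set. Deterministic for a fixed ``seed``.

    With ``swap=False`` the validation set is reused as-is and each
    replicate simply refits on ``train`` and scores on ``validation``.
    """
    if replicates < 0:
        raise ValidationError("replicates must be non-negative")
    train_counts = train.class_counts()
    val_counts = validation.class_counts()
    if set(val_counts) - set(train_counts):
        raise ValidationError(
            f"validation classes {sorted(val_counts)} not all present in "
            f"training classes {sorted(train_counts)}"
        )
    for cls, n_val in val_counts.items():
        if train_counts[cls] < n_val:
            raise ValidationError(
                f"class {cls!r}: training count {train_counts[cls]} is smaller "
                f"than validation count {n_val}; the swap is impossible"
            )

    reports: list[CrossValReport] = []
    train_labels = train.labels.astype(str)
    for rep in range(replicates):
        if swap:
            rng = np.random.default_rng([seed, rep])
            new_val_idx: list[np.ndarray] = []
            for cls in sorted(val_counts):
                cls_idx = np.flatnonzero(train_labels == cls)
                new_val_idx.append(
                    rng.choice(cls_idx, size=val_counts[cls], replace=False)
                )
            val_idx = np.concatenate(new_val_idx)
            keep_idx = np.setdiff1d(np.arange(len(train)), val_idx)
            new_validation = train.subset(val_idx)
            pool = train.subset(keep_idx).concat(validation)
        else:
            new_validation = validation
            pool = train
        line = fit_lda(pool, priors=priors, positive_class=positive_class)
        cm = evaluate(line, new_validation)
        reports.append(
            CrossValReport(
                replicate_id=rep,
                line=line,
                confusion=cm,
                accuracy_percent=accuracy_rate(cm),
                seed=seed,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------


def write_confusion_report(path, cm: ConfusionMatrix) -> None:
    """Confusion matrix + accuracy as JSON."""
    payload = cm.to_dict()
    payload["accuracy_percent"] = accuracy_rate(cm)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_crossval_reports(path, reports: list[CrossValReport]) -> None:
    """Cross-validation reports as JSON lines, one object per replicate."""
    with open(path, "w", encoding="utf-8") as fh:
        for report in reports:
            fh.write(json.dumps(report.to_dict(), sort_keys=True))
            fh.write("\n")


def read_crossval_reports(path) -> list[CrossValReport]:
    reports = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            reports.append(
                CrossValReport(
                    replicate_id=d["replicate_id"],
                    line=DiscriminantLine.from_dict(d["line"]),
                    confusion=ConfusionMatrix(**d["confusion"]),
                    accuracy_percent=d["accuracy_percent"],
                    seed=d["seed"],
                )
            )
    return reports
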