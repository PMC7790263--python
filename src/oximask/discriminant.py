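"""Two-class linear discriminant boundaries in the log-ratio plane.

Each discrimination task separates an adherent substance from the
similarly coloured exposed tumor: blood vs. reddish tumor, and white
coating vs. whitish tumor. Classes are modelled as Gaussians with a
shared (pooled within-class) covariance, so the optimal decision rule
is linear; the boundary is reported in the slope/intercept form used
clinically, e.g. "blood where Y > -4.90 X + 7.13".

With equal priors the rule is exactly nearest-Mahalanobis-mean
classification under the pooled covariance; empirical priors add the
usual ``ln(n_pos/n_neg)`` offset to the decision score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateBoundaryError,
    FitError,
    UnsupportedGeometryError,
    ValidationError,
)
from .features import ADHERENT_LABELS, FeaturePoint

_SIDES = ("above", "below")

#: numerical threshold below which a boundary is treated as vertical
_VERTICAL_TOL = 1e-12


@dataclass(frozen=True)
class DiscriminantLine:
    """A straight decision boundary ``Y = slope*X + intercept``.

    ``positive_side`` states which half-plane ("above" or "below" the
    line) selects ``positive_class`` — by convention the adherent
    substance; ``negative_class`` is the tumor class. Points exactly on
    the line are assigned to the tumor class (ambiguous pixels are
    retained rather than masked out).
    """

    slope: float
    intercept: float
    positive_side: str
    positive_class: str
    negative_class: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValidationError("slope and intercept must be finite")
        if self.positive_side not in _SIDES:
            raise ValidationError(
                f"positive_side must be one of {_SIDES}, got {self.positive_side!r}"
            )
        if self.positive_class == self.negative_class:
            raise ValidationError("positive and negative class must differ")

    # -- geometry ----------------------------------------------------------

    def signed_offset(self, x, y):
        """``y`` minus the line's height at ``x`` (vectorised)."""
        return np.asarray(y) - (self.slope * np.asarray(x) + self.intercept)

    def fires(self, x, y):
        """Boolean (array): does the point lie strictly on the positive
        side of the boundary?"""
        v = self.signed_offset(x, y)
        return v > 0 if self.positive_side == "above" else v < 0

    def formula(self, precision: int = 2) -> str:
        """Human-readable rule, e.g. ``'Y > -4.90X + 7.13'``."""
        op = ">" if self.positive_side == "above" else "<"
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"Y {op} {self.slope:.{precision}f}X {sign} "
            f"{abs(self.intercept):.{precision}f}"
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "positive_side": self.positive_side,
            "positive_class": self.positive_class,
            "negative_class": self.negative_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantLine":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            positive_side=d["positive_side"],
            positive_class=d["positive_class"],
            negative_class=d["negative_class"],
        )


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Feature points with parallel class labels (exactly two classes
    for fitting; each class needs >= 3 members for within-class
    scatter)."""

    points: np.ndarray  # (n, 2) float
    labels: np.ndarray  # (n,) str

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValidationError(f"points must have shape (n, 2), got {points.shape}")
        if labels.shape != (points.shape[0],):
            raise ValidationError(
                f"labels length {labels.shape} does not match points {points.shape}"
            )
        if not np.all(np.isfinite(points)):
            raise ValidationError("feature points must be finite")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_feature_points(
        cls, points: Sequence[FeaturePoint], labels: Sequence[str]
    ) -> "LabeledFeatureSet":
        arr = np.array([[p.x, p.y] for p in points], dtype=float).reshape(-1, 2)
        return cls(points=arr, labels=np.array(list(labels), dtype=object))

    def __len__(self) -> int:
        return self.points.shape[0]

    def class_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def subset(self, index) -> "LabeledFeatureSet":
        index = np.asarray(index)
        return LabeledFeatureSet(points=self.points[index], labels=self.labels[index])

    def concat(self, other: "LabeledFeatureSet") -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            points=np.vstack([self.points, other.points]),
            labels=np.concatenate([self.labels, other.labels]),
        )


def _resolve_positive_class(classes: list[str], positive_class: str | None) -> str:
    if positive_class is not None:
        if positive_class not in classes:
            raise ValidationError(
                f"positive_class {positive_class!r} not among classes {classes}"
            )
        return positive_class
    adherent = [c for c in classes if c in ADHERENT_LABELS]
    if len(adherent) == 1:
        return adherent[0]
    raise ValidationError(
        f"cannot infer the positive (adherent) class from labels {classes}; "
        "pass positive_class explicitly"
    )


def fit_lda(
    data: LabeledFeatureSet,
    priors: str = "equal",
    positive_class: str | None = None,
) -> DiscriminantLine:
    """Fit the two-class LDA boundary with pooled within-class covariance.

    ``priors="equal"`` (default) makes the boundary depend on geometry
    only; ``priors="empirical"`` weights by observed class frequencies.
    The positive class is the adherent substance, inferred from the
    labels when possible.

    Raises :class:`FitError` for singular pooled covariance,
    :class:`DegenerateBoundaryError` for coincident class means and
    :class:`UnsupportedGeometryError` for a (numerically) vertical
    boundary.
    """
    if priors not in ("equal", "empirical"):
        raise ValidationError(f"priors must be 'equal' or 'empirical', got {priors!r}")
    counts = data.class_counts()
    classes = sorted(counts)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    if min(counts.values()) < 3:
        raise ValidationError(
            f"each class needs >= 3 points for pooled covariance, got {counts}"
        )
    pos = _resolve_positive_class(classes, positive_class)
    neg = classes[0] if classes[1] == pos else classes[1]

    labels = data.labels.astype(str)
    z_pos = data.points[labels == pos]
    z_neg = data.points[labels == neg]
    mu_pos = z_pos.mean(axis=0)
    mu_neg = z_neg.mean(axis=0)

    scatter = (z_pos - mu_pos).T @ (z_pos - mu_pos) + (z_neg - mu_neg).T @ (
        z_neg - mu_neg
    )
    pooled = scatter / (len(z_pos) + len(z_neg) - 2)
    if np.linalg.cond(pooled) > 1e12:
        raise FitError(
            "pooled within-class covariance is singular (collinear points?)"
        )

    delta = mu_pos - mu_neg
    scale = max(np.linalg.norm(mu_pos), np.linalg.norm(mu_neg), 1.0)
    if np.linalg.norm(delta) < 1e-12 * scale:
        raise DegenerateBoundaryError(
            "class means coincide: no discriminant direction exists"
        )

    w = np.linalg.solve(pooled, delta)
    c = -0.5 * float(w @ (mu_pos + mu_neg))
    if priors == "empirical":
        c += float(np.log(len(z_pos) / len(z_neg)))

    # decision score w.(x, y) + c > 0 selects the positive class
    w_x, w_y = float(w[0]), float(w[1])
    if abs(w_y) < _VERTICAL_TOL * max(abs(w_x), 1.0):
        raise UnsupportedGeometryError(
            "fitted boundary is vertical and has no Y = aX + b form"
        )
    return DiscriminantLine(
        slope=-w_x / w_y,
        intercept=-c / w_y,
        positive_side="above" if w_y > 0 else "below",
        positive_class=pos,
        negative_class=neg,
    )


def classify_point(p: FeaturePoint, line: DiscriminantLine) -> str:
    """Class label of a single feature point. Points exactly on the
    boundary are assigned to the negative (tumor) class."""
    return (
        line.positive_class if bool(line.fires(p.x, p.y)) else line.negative_class
    )


def classify_points(points: np.ndarray, line: DiscriminantLine) -> np.ndarray:
    """Vectorised :func:`classify_point` over an ``(n, 2)`` array."""
    points = np.asarray(points, dtype=float)
    fired = line.fires(points[:, 0], points[:, 1])
    return np.where(fired, line.positive_class, line.negative_class).astype(object)


def reference_models() -> tuple[DiscriminantLine, DiscriminantLine]:
    """The two published decision boundaries.

    Returns ``(blood_line, coating_line)``: blood where
    ``Y > -4.90X + 7.13`` (vs. reddish tumor) and white coating where
    ``Y < -0.52X + 0.17`` (vs. whitish tumor).
    """
    blood = DiscriminantLine(
        slope=-4.90,
        intercept=7.13,
        positive_side="above",
        positive_class="blood",
        negative_class="reddish_tumor",
    )
    coating = DiscriminantLine(
        slope=-0.52,
        intercept=0.17,
        positive_side="below",
        positive_class="white_coating",
        negative_class="whitish_tumor",
    )
    return blood, coating


# ---------------------------------------------------------------------------
# Model JSON I/O
# ---------------------------------------------------------------------------


def save_model(path, line: DiscriminantLine, **metadata) -> None:
    """Write a model JSON (full float precision; bit-exact round trip).

    Extra keyword arguments (task, priors, n_train_per_class, seed, ...)
    are stored alongside the geometry.
    """
    payload = dict(metadata)
    payload.update(line.to_dict())
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> DiscriminantLine:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        return DiscriminantLine.from_dict(payload)
    except KeyError as exc:
        raise ValidationError(f"model file {path} is missing field {exc}") from exc
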