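"""Log-ratio spectral features for white-light endoscopic imaging.

Tumor tissue and the substances adhering to it (fresh blood, fibrinous
white coating) are characterised here by two G-normalised log signal
ratios computed from raw, linear sensor counts of a laser endoscope:

* ``x = ln(R/G)`` — haemoglobin absorbs green light far more strongly
  than red, so this ratio rises with the haemoglobin content of the
  observed surface.
* ``y = ln(B445/G)`` — the 445 nm narrow-band blue signal is even more
  strongly absorbed by surface blood than green, so this ratio falls
  in the presence of adherent blood.

Normalising both channels by G and taking logarithms removes the common
illumination/geometry gain shared by all three channels, which is why
these features are comparable across images, working distances and
light-source settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

#: The four site classes used throughout the package.
CLASS_LABELS = ("blood", "reddish_tumor", "white_coating", "whitish_tumor")

#: Substances adhering to the tumor surface (the "positive" classes of
#: the two discrimination tasks).
ADHERENT_LABELS = frozenset({"blood", "white_coating"})

#: Exposed tumor tissue classes.
TUMOR_LABELS = frozenset({"reddish_tumor", "whitish_tumor"})

_CHANNELS = ("r", "g", "b445")

_PLOT_TABLE_COLUMNS = ["image_id", "site_id", "label", "r", "g", "b445"]


@dataclass(frozen=True)
class SpectralSample:
    """Raw spectral signal values of one plotted site.

    ``r``, ``g`` and ``b445`` are unitless linear sensor counts
    (positive reals; real data spans roughly 4–1060, no bit depth is
    assumed). ``label`` is one of :data:`CLASS_LABELS` or ``None`` for
    unlabeled data.
    """

    r: float
    g: float
    b445: float
    label: str | None = None
    image_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        for name in _CHANNELS:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                raise DomainError(
                    f"channel {name!r} of site {self.site_id!r} is not finite: {value!r}"
                )
            if value <= 0.0:
                raise DomainError(
                    f"channel {name!r} of site {self.site_id!r} must be positive "
                    f"(got {value!r}); log ratios are undefined otherwise"
                )
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValidationError(
                f"unknown class label {self.label!r} for site {self.site_id!r}; "
                f"expected one of {CLASS_LABELS}"
            )


@dataclass(frozen=True)
class FeaturePoint:
    """A site's coordinates in the discriminant plane:
    ``x = ln(R/G)``, ``y = ln(B445/G)`` (both dimensionless)."""

    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


def compute_features(sample: SpectralSample) -> FeaturePoint:
    """Map one spectral sample to the (x, y) log-ratio plane.

    Natural logarithms are used throughout. Raises
    :class:`~oximask.exceptions.DomainError` if any channel is
    non-positive or non-finite (the message names the offending field).
    """
    for name in _CHANNELS:
        value = getattr(sample, name)
        if not math.isfinite(value) or value <= 0.0:
            raise DomainError(
                f"channel {name!r} of site {sample.site_id!r} is invalid: {value!r}"
            )
    return FeaturePoint(
        x=math.log(sample.r / sample.g),
        y=math.log(sample.b445 / sample.g),
    )


def compute_features_batch(samples: Sequence[SpectralSample]) -> list[FeaturePoint]:
    """Feature points for a sequence of samples, preserving order.

    The first invalid sample aborts the batch with an error naming its
    position and ``site_id``.
    """
    out: list[FeaturePoint] = []
    for i, sample in enumerate(samples):
        try:
            out.append(compute_features(sample))
        except DomainError as exc:
            raise DomainError(f"sample {i} (site {sample.site_id!r}): {exc}") from exc
    return out


def log_ratio_planes(
    r: np.ndarray,
    g: np.ndarray,
    b445: np.ndarray,
    zero_policy: str = "mask",
    epsilon: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised feature computation for whole image planes.

    Returns ``(x, y, valid)`` where ``valid`` flags pixels whose three
    channel values are finite and positive. Under the default
    ``zero_policy="mask"`` invalid pixels get NaN features and are meant
    to be treated as unclassifiable downstream; ``zero_policy="clamp"``
    instead clamps finite channel values below ``epsilon`` (default 0.5
    counts) up to ``epsilon``, leaving no holes at the cost of
    fabricating features in fully shadowed pixels.
    """
    if zero_policy not in ("mask", "clamp"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    planes = [np.asarray(p, dtype=float) for p in (r, g, b445)]
    if not (planes[0].shape == planes[1].shape == planes[2].shape):
        raise ValidationError(
            f"channel planes have mismatched shapes: "
            f"{[p.shape for p in planes]}"
        )
    finite = np.isfinite(planes[0]) & np.isfinite(planes[1]) & np.isfinite(planes[2])
    if zero_policy == "clamp":
        planes = [np.where(finite, np.maximum(p, epsilon), p) for p in planes]
    valid = finite & (planes[0] > 0) & (planes[1] > 0) & (planes[2] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(valid, np.log(planes[0] / planes[1]), np.nan)
        y = np.where(valid, np.log(planes[2] / planes[1]), np.nan)
    return x, y, valid


# ---------------------------------------------------------------------------
# Plot-table I/O
# ---------------------------------------------------------------------------


def read_plot_table(path) -> list[SpectralSample]:
    """Read a plot-table CSV (columns image_id, site_id, label, r, g,
    b445; header required, UTF-8; empty label = unlabeled)."""
    df = pd.read_csv(path, dtype={"image_id": str, "site_id": str, "label": str})
    missing = [c for c in _PLOT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plot table {path} is missing columns {missing}")
    samples = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        label = row.label if isinstance(row.label, str) and row.label else None
        try:
            samples.append(
                SpectralSample(
                    r=row.r,
                    g=row.g,
                    b445=row.b445,
                    label=label,
                    image_id=row.image_id if isinstance(row.image_id, str) else "",
                    site_id=row.site_id if isinstance(row.site_id, str) else "",
                )
            )
        except (DomainError, ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}, row {row_number}: {exc}") from exc
    return samples


def _samples_frame(samples: Iterable[SpectralSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": s.image_id,
                "site_id": s.site_id,
                "label": s.label or "",
                "r": s.r,
                "g": s.g,
                "b445": s.b445,
            }
            for s in samples
        ],
        columns=_PLOT_TABLE_COLUMNS,
    )


def write_plot_table(path, samples: Iterable[SpectralSample]) -> None:
    """Write samples as a plot-table CSV."""
    _samples_frame(samples).to_csv(path, index=False)


def write_feature_table(path, samples: Sequence[SpectralSample]) -> None:
    """Write a plot-table CSV augmented with the feature columns x, y."""
    df = _samples_frame(samples)
    points = compute_features_batch(samples)
    df["x"] = [p.x for p in points]
    df["y"] = [p.y for p in points]
    df.to_csv(path, index=False)
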