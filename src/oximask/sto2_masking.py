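"""Pixel-wise masking of adherent substances in StO2 maps.

Oxygen-saturation endoscopy estimates tissue oxygen saturation (StO2,
percent) for every pixel, but blood and white coating on the tumor
surface contaminate the map: their StO2 readings do not describe the
tumor. This module applies the two discriminant boundaries per pixel to
the co-registered white-light channel planes, labels each pixel inside
the tumor ROI as tumor, blood, white coating or unclassifiable, and
summarises StO2 separately for the combined region, the exposed tumor
and the adherent substances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .discriminant import DiscriminantLine
from .exceptions import DomainError, ValidationError
from .features import log_ratio_planes

logger = logging.getLogger(__name__)

#: Fixed label-map legend (written into output metadata).
LABEL_CODES = {"unclassifiable": 0, "tumor": 1, "blood": 2, "white_coating": 3}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

_ROUTINGS = ("either", "red_route", "annotation")

#: Task codes for routing="annotation": per pixel, which single model applies.
TASK_BLOOD = 2
TASK_COATING = 3


@dataclass
class SpectralImage:
    """Co-registered channel planes plus an StO2 map.

    ``r_plane``, ``g_plane``, ``b445_plane`` hold positive sensor
    counts; ``sto2_plane`` holds StO2 percent in [0, 100] with NaN as
    the missing-value marker (saturation/halation); ``roi`` is an
    optional boolean tumor mask (whole image when absent — summaries
    are only meaningful with a real tumor ROI).
    """

    r_plane: np.ndarray
    g_plane: np.ndarray
    b445_plane: np.ndarray
    sto2_plane: np.ndarray
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_plane = np.asarray(self.r_plane, dtype=float)
        self.g_plane = np.asarray(self.g_plane, dtype=float)
        self.b445_plane = np.asarray(self.b445_plane, dtype=float)
        self.sto2_plane = np.asarray(self.sto2_plane, dtype=float)
        shape = self.r_plane.shape
        for name in ("g_plane", "b445_plane", "sto2_plane"):
            if getattr(self, name).shape != shape:
                raise ValidationError(
                    f"{name} shape {getattr(self, name).shape} does not match "
                    f"r_plane shape {shape}"
                )
        if self.roi is not None:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != shape:
                raise ValidationError(
                    f"roi shape {self.roi.shape} does not match planes {shape}"
                )
        valid = self.sto2_plane[np.isfinite(self.sto2_plane)]
        if valid.size and (valid.min() < 0.0 or valid.max() > 100.0):
            raise ValidationError("StO2 values must lie in [0, 100] or be NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r_plane.shape

    def roi_mask(self) -> np.ndarray:
        return self.roi if self.roi is not None else np.ones(self.shape, dtype=bool)


def classify_pixels(
    img: SpectralImage,
    blood_model: DiscriminantLine,
    coating_model: DiscriminantLine,
    routing: str = "either",
    red_threshold: float = 0.8,
    task_map: np.ndarray | None = None,
    zero_policy: str = "mask",
    epsilon: float = 0.5,
) -> np.ndarray:
    """Label every pixel as tumor / blood / white coating / unclassifiable.

    The two boundaries were each constructed for sites of one colour
    family, so whole-image application needs a routing rule:

    * ``"either"`` (default): a pixel is blood if the blood boundary
      fires, else white coating if the coating boundary fires, else
      tumor. When both fire, blood wins (its spectral signature is the
      more extreme and clinically the more important to exclude).
    * ``"red_route"``: a chroma gate sends pixels with
      ``ln(R/G) > red_threshold`` (default 0.8) to the blood-vs-reddish
      task and the rest to the coating-vs-whitish task.
    * ``"annotation"``: a user-supplied per-pixel ``task_map`` (values
      :data:`TASK_BLOOD` or :data:`TASK_COATING`) decides which single
      model applies.

    Pixels outside the ROI or with invalid channel values are coded
    unclassifiable. Returns a uint8 map with legend :data:`LABEL_CODES`.
    """
    if routing not in _ROUTINGS:
        raise ValidationError(f"routing must be one of {_ROUTINGS}, got {routing!r}")
    x, y, valid = log_ratio_planes(
        img.r_plane, img.g_plane, img.b445_plane, zero_policy=zero_policy,
        epsilon=epsilon,
    )
    active = img.roi_mask() & valid
    labels = np.zeros(img.shape, dtype=np.uint8)
    # evaluate boundaries only where features exist
    xa = np.where(active, x, 0.0)
    ya = np.where(active, y, 0.0)
    blood = blood_model.fires(xa, ya)
    coating = coating_model.fires(xa, ya)

    if routing == "either":
        labels[active] = LABEL_CODES["tumor"]
        labels[active & coating] = LABEL_CODES["white_coating"]
        labels[active & blood] = LABEL_CODES["blood"]  # blood precedence
    elif routing == "red_route":
        to_blood = active & (xa > red_threshold)
        to_coating = active & ~to_blood
        labels[to_blood] = np.where(
            blood[to_blood], LABEL_CODES["blood"], LABEL_CODES["tumor"]
        )
        labels[to_coating] = np.where(
            coating[to_coating], LABEL_CODES["white_coating"], LABEL_CODES["tumor"]
        )
    else:  # annotation
        if task_map is None:
            raise ValidationError("routing='annotation' requires a task_map")
        task_map = np.asarray(task_map)
        if task_map.shape != img.shape:
            raise ValidationError(
                f"task_map shape {task_map.shape} does not match image {img.shape}"
            )
        known = np.isin(task_map, (TASK_BLOOD, TASK_COATING))
        if not np.all(known[active]):
            raise ValidationError(
                f"task_map must contain only codes {TASK_BLOOD} (blood task) "
                f"or {TASK_COATING} (coating task) inside the ROI"
            )
        to_blood = active & (task_map == TASK_BLOOD)
        to_coating = active & (task_map == TASK_COATING)
        labels[to_blood] = np.where(
            blood[to_blood], LABEL_CODES["blood"], LABEL_CODES["tumor"]
        )
        labels[to_coating] = np.where(
            coating[to_coating], LABEL_CODES["white_coating"], LABEL_CODES["tumor"]
        )
    return labels


@dataclass(frozen=True)
class StO2Summary:
    """Distributional summary of StO2 (percent) over one region."""

    region_name: str
    n_pixels: int
    median_percent: float
    min_percent: float
    max_percent: float

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValidationError("a reported region needs at least one pixel")
        if not (
            0.0 <= self.min_percent <= self.median_percent <= self.max_percent <= 100.0
        ):
            raise ValidationError(
                "summary must satisfy 0 <= min <= median <= max <= 100"
            )

    def to_dict(self) -> dict:
        return {
            "region": self.region_name,
            "n_pixels": self.n_pixels,
            "median_percent": self.median_percent,
            "min_percent": self.min_percent,
            "max_percent": self.max_percent,
        }


def _region_summary(name: str, values: np.ndarray) -> StO2Summary | None:
    values = values[np.isfinite(values)]
    if values.size == 0:
        logger.info("region %r has no valid StO2 pixels; omitted from summary", name)
        return None
    return StO2Summary(
        region_name=name,
        n_pixels=int(values.size),
        median_percent=float(np.median(values)),
        min_percent=float(values.min()),
        max_percent=float(values.max()),
    )


def summarize_sto2(img: SpectralImage, labels: np.ndarray) -> list[StO2Summary]:
    """StO2 summaries for the combined (tumor + adherent), tumor-only
    and adherent-only (blood + white coating) regions.

    Missing (NaN) StO2 pixels are excluded from the statistics and from
    the pixel counts; regions without any valid pixel are omitted with
    a logged notice. Medians use the mean-of-middle-two convention for
    even counts.
    """
    labels = np.asarray(labels)
    if labels.shape != img.shape:
        raise ValidationError(
            f"label map shape {labels.shape} does not match image {img.shape}"
        )
    tumor = labels == LABEL_CODES["tumor"]
    adherent = (labels == LABEL_CODES["blood"]) | (
        labels == LABEL_CODES["white_coating"]
    )
    if not np.any(tumor | adherent):
        raise DomainError("no classified pixels to summarise")
    sto2 = img.sto2_plane
    n_missing = int(np.sum((tumor | adherent) & ~np.isfinite(sto2)))
    if n_missing:
        logger.info("%d classified pixels have missing StO2 and were excluded",
                    n_missing)
    out = []
    for name, mask in (
        ("combined", tumor | adherent),
        ("tumor", tumor),
        ("adherent", adherent),
    ):
        summary = _region_summary(name, sto2[mask])
        if summary is not None:
            out.append(summary)
    return out


# ---------------------------------------------------------------------------
# TIFF / CSV I/O
# ---------------------------------------------------------------------------


def write_spectral_image(directory, img: SpectralImage) -> None:
    """Write a spectral image bundle into ``directory``:
    ``channels.tif`` (pages R, G, B445, float32 counts), ``sto2.tif``
    (float32 percent, NaN = missing) and ``roi.tif`` (uint8) when an
    ROI is present."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [img.r_plane, img.g_plane, img.b445_plane]
    ).astype(np.float32)
    tifffile.imwrite(directory / "channels.tif", stack,
                     photometric="minisblack")
    tifffile.imwrite(directory / "sto2.tif", img.sto2_plane.astype(np.float32))
    if img.roi is not None:
        tifffile.imwrite(directory / "roi.tif", img.roi.astype(np.uint8))


def read_spectral_image(directory) -> SpectralImage:
    directory = Path(directory)
    channels_path = directory / "channels.tif"
    sto2_path = directory / "sto2.tif"
    for path in (channels_path, sto2_path):
        if not path.exists():
            raise ValidationError(f"missing image file: {path}")
    stack = tifffile.imread(channels_path)
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValidationError(
            f"{channels_path} must hold 3 pages (R, G, B445), got shape {stack.shape}"
        )
    roi_path = directory / "roi.tif"
    roi = tifffile.imread(roi_path).astype(bool) if roi_path.exists() else None
    return SpectralImage(
        r_plane=stack[0],
        g_plane=stack[1],
        b445_plane=stack[2],
        sto2_plane=tifffile.imread(sto2_path),
        roi=roi,
    )


def write_label_map(path, labels: np.ndarray) -> None:
    """Label map as single-page 8-bit TIFF plus a sidecar legend JSON."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8))
    legend_path = path.with_suffix(".legend.json")
    with open(legend_path, "w", encoding="utf-8") as fh:
        json.dump({"legend": LABEL_CODES}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.uint8)


def write_summaries(path, summaries: list[StO2Summary]) -> None:
    """Region summaries as CSV (region, n_pixels, median, min, max)."""
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(path, index=False)
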