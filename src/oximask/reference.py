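"""Published reference values of the adherent-substance study.

These numbers were reported for 50 advanced upper-gastrointestinal
tumors (20 gastric, 30 esophageal) imaged with a laser endoscope in
white-light mode: per-class summary statistics of the raw R, G and
445 nm blue signal values at manually plotted sites, the validation
confusion counts of the two published discrimination boundaries, and
the per-region StO2 medians and ranges observed in oxygen-saturation
mode. They serve two roles in this package: calibration targets for
the synthetic-data generator and worked-example inputs for the
evaluation module. The published boundaries themselves live in
:func:`oximask.discriminant.reference_models`.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

#: Per-class channel statistics of the construction cohort
#: (50 images; n sites per class): channel -> (average, median, (min, max)).
CONSTRUCTION_CHANNEL_STATS: dict[str, dict] = {
    "blood": {
        "n": 68,
        "r": (232.9, 188.8, (20.1, 724.4)),
        "g": (36.6, 30.4, (4.7, 114.3)),
        "b445": (25.0, 18.7, (4.0, 126.5)),
    },
    "reddish_tumor": {
        "n": 83,
        "r": (376.2, 346.1, (128.7, 1057.2)),
        "g": (118.0, 98.3, (41.6, 457.2)),
        "b445": (91.5, 75.8, (33.0, 523.6)),
    },
    "white_coating": {
        "n": 89,
        "r": (398.1, 371.9, (126.3, 899.3)),
        "g": (266.8, 249.6, (63.4, 713.8)),
        "b445": (226.0, 196.1, (53.4, 733.1)),
    },
    "whitish_tumor": {
        "n": 79,
        "r": (380.2, 350.5, (127.6, 779.5)),
        "g": (211.4, 197.8, (67.9, 559.6)),
        "b445": (212.8, 199.7, (64.8, 631.8)),
    },
}

#: Same layout for the 15-image validation cohort.
VALIDATION_CHANNEL_STATS: dict[str, dict] = {
    "blood": {
        "n": 24,
        "r": (302.5, 290.1, (132.2, 619.4)),
        "g": (36.7, 31.9, (18.0, 57.6)),
        "b445": (24.2, 21.5, (12.7, 43.1)),
    },
    "reddish_tumor": {
        "n": 25,
        "r": (462.0, 515.6, (169.4, 655.5)),
        "g": (134.3, 140.8, (51.0, 208.3)),
        "b445": (96.5, 94.6, (41.2, 168.1)),
    },
    "white_coating": {
        "n": 25,
        "r": (476.6, 461.0, (154.6, 955.9)),
        "g": (310.1, 303.6, (100.2, 547.6)),
        "b445": (242.0, 217.9, (73.3, 532.1)),
    },
    "whitish_tumor": {
        "n": 25,
        "r": (441.3, 439.2, (224.9, 682.2)),
        "g": (232.1, 246.9, (121.0, 340.9)),
        "b445": (219.2, 225.4, (94.4, 382.6)),
    },
}

#: Published StO2 statistics per region: label -> (median %, (min %, max %)).
#: "combined" entries pool the tumor with its adherent substance.
STO2_STATS: dict[str, tuple[float, tuple[float, float]]] = {
    "blood": (79.3, (37.8, 100.0)),
    "reddish_tumor": (74.5, (62.0, 86.9)),
    "white_coating": (73.8, (42.1, 100.0)),
    "whitish_tumor": (65.7, (53.0, 76.3)),
    "blood_reddish_combined": (75.9, (37.8, 100.0)),
    "coating_whitish_combined": (66.1, (42.1, 100.0)),
}


def validation_confusions() -> dict[str, ConfusionMatrix]:
    """The published held-out confusion counts of the two boundaries
    (after exclusion of one aberrant blood site), keyed by the positive
    class."""
    return {
        "blood": ConfusionMatrix(
            positive_class="blood",
            negative_class="reddish_tumor",
            tp=24,
            fn=0,
            fp=2,
            tn=23,
        ),
        "white_coating": ConfusionMatrix(
            positive_class="white_coating",
            negative_class="whitish_tumor",
            tp=25,
            fn=0,
            fp=2,
            tn=23,
        ),
    }


def class_average_sample(stats: dict, label: str):
    """A :class:`~oximask.features.SpectralSample` built from a cohort's
    per-class channel averages."""
    from .features import SpectralSample

    row = stats[label]
    return SpectralSample(
        r=row["r"][0],
        g=row["g"][0],
        b445=row["b445"][0],
        label=label,
        site_id=f"{label}-average",
    )
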