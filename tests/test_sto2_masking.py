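"""Pixel-wise masking and StO2 region summaries."""

import numpy as np
import pytest

from oximask import (
    DomainError,
    SpectralImage,
    ValidationError,
    classify_pixels,
    reference_models,
    summarize_sto2,
)
from oximask.sto2_masking import (
    LABEL_CODES,
    TASK_BLOOD,
    TASK_COATING,
    StO2Summary,
    read_label_map,
    read_spectral_image,
    write_label_map,
    write_spectral_image,
    write_summaries,
)


def uniform_image(r, g, b445, sto2=70.0, shape=(8, 10), roi=None):
    return SpectralImage(
        r_plane=np.full(shape, float(r)),
        g_plane=np.full(shape, float(g)),
        b445_plane=np.full(shape, float(b445)),
        sto2_plane=np.full(shape, float(sto2)),
        roi=roi,
    )


@pytest.fixture(scope="module")
def lines():
    return reference_models()


class TestClassifyPixels:
    def test_uniform_blood_average_is_all_blood(self, lines):
        img = uniform_image(232.9, 36.6, 25.0)  # blood class averages
        labels = classify_pixels(img, *lines)
        assert (labels == LABEL_CODES["blood"]).all()

    def test_equal_channels_route_to_white_coating(self, lines):
        """At r = g = b445 the features are (0, 0): the blood rule does
        not fire (7.13 > 0) but the coating rule does (0 < 0.17)."""
        img = uniform_image(80, 80, 80)
        labels = classify_pixels(img, *lines)
        assert (labels == LABEL_CODES["white_coating"]).all()

    def test_empty_roi_all_unclassifiable(self, lines):
        img = uniform_image(232.9, 36.6, 25.0,
                            roi=np.zeros((8, 10), dtype=bool))
        labels = classify_pixels(img, *lines)
        assert (labels == LABEL_CODES["unclassifiable"]).all()

    def test_invalid_pixels_unclassifiable_or_clamped(self, lines):
        img = uniform_image(232.9, 36.6, 25.0)
        img.r_plane[0, 0] = 0.0
        labels = classify_pixels(img, *lines)
        assert labels[0, 0] == LABEL_CODES["unclassifiable"]
        assert labels[1, 1] == LABEL_CODES["blood"]
        clamped = classify_pixels(img, *lines, zero_policy="clamp")
        assert clamped[0, 0] != LABEL_CODES["unclassifiable"]

    def test_red_route_gates_by_chroma(self, lines):
        # equal channels (x = 0): under red_route the pixel goes to the
        # coating task and the coating rule fires
        img = uniform_image(80, 80, 80)
        labels = classify_pixels(img, *lines, routing="red_route")
        assert (labels == LABEL_CODES["white_coating"]).all()
        # blood averages (x = 1.85 > 0.8): routed to the blood task
        img2 = uniform_image(232.9, 36.6, 25.0)
        labels2 = classify_pixels(img2, *lines, routing="red_route")
        assert (labels2 == LABEL_CODES["blood"]).all()

    def test_annotation_routing(self, lines):
        img = uniform_image(80, 80, 80, shape=(2, 2))
        task_map = np.array([[TASK_BLOOD, TASK_BLOOD],
                             [TASK_COATING, TASK_COATING]])
        labels = classify_pixels(img, *lines, routing="annotation",
                                 task_map=task_map)
        # blood rule does not fire at the origin -> tumor; coating does
        assert (labels[0] == LABEL_CODES["tumor"]).all()
        assert (labels[1] == LABEL_CODES["white_coating"]).all()

    def test_annotation_requires_task_map(self, lines):
        img = uniform_image(80, 80, 80)
        with pytest.raises(ValidationError, match="task_map"):
            classify_pixels(img, *lines, routing="annotation")
        with pytest.raises(ValidationError, match="codes"):
            classify_pixels(img, *lines, routing="annotation",
                            task_map=np.zeros((8, 10), dtype=int))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            SpectralImage(
                r_plane=np.ones((4, 4)), g_plane=np.ones((4, 5)),
                b445_plane=np.ones((4, 4)), sto2_plane=np.ones((4, 4)),
            )

    def test_sto2_range_enforced(self):
        with pytest.raises(ValidationError, match="StO2"):
            uniform_image(10, 10, 10, sto2=130.0)


class TestSummaries:
    def test_constant_field(self):
        img = uniform_image(300, 100, 80, sto2=65.7)
        labels = np.full(img.shape, LABEL_CODES["tumor"], dtype=np.uint8)
        out = {s.region_name: s for s in summarize_sto2(img, labels)}
        for region in ("combined", "tumor"):
            s = out[region]
            assert (s.median_percent, s.min_percent, s.max_percent) == (
                65.7, 65.7, 65.7)
        assert "adherent" not in out  # empty region omitted

    def test_two_value_field_median_convention(self):
        img = uniform_image(300, 100, 80, shape=(2, 2))
        img.sto2_plane[:] = [[60.0, 60.0], [80.0, 80.0]]
        labels = np.array([[LABEL_CODES["tumor"]] * 2,
                           [LABEL_CODES["blood"]] * 2], dtype=np.uint8)
        out = {s.region_name: s for s in summarize_sto2(img, labels)}
        assert out["combined"].median_percent == 70.0  # mean of middle two
        assert out["tumor"].median_percent == 60.0
        assert out["adherent"].median_percent == 80.0

    def test_counts_conserve_and_missing_excluded(self):
        img = uniform_image(300, 100, 80, shape=(4, 4), sto2=50.0)
        img.sto2_plane[0, 0] = np.nan  # missing StO2 marker
        labels = np.full((4, 4), LABEL_CODES["tumor"], dtype=np.uint8)
        labels[2:] = LABEL_CODES["white_coating"]
        labels[3, 3] = LABEL_CODES["unclassifiable"]
        out = {s.region_name: s for s in summarize_sto2(img, labels)}
        assert out["combined"].n_pixels == (
            out["tumor"].n_pixels + out["adherent"].n_pixels
        )
        assert out["tumor"].n_pixels == 7  # 8 tumor pixels, 1 missing StO2

    def test_median_betweenness(self):
        rng = np.random.default_rng(0)
        img = uniform_image(300, 100, 80, shape=(20, 20))
        img.sto2_plane[:] = rng.uniform(40, 90, size=(20, 20))
        labels = np.where(rng.random((20, 20)) < 0.3, LABEL_CODES["blood"],
                          LABEL_CODES["tumor"]).astype(np.uint8)
        out = {s.region_name: s for s in summarize_sto2(img, labels)}
        lo = min(out["tumor"].median_percent, out["adherent"].median_percent)
        hi = max(out["tumor"].median_percent, out["adherent"].median_percent)
        assert lo <= out["combined"].median_percent <= hi

    def test_no_classified_pixels_rejected(self):
        img = uniform_image(1, 1, 1)
        labels = np.zeros(img.shape, dtype=np.uint8)
        with pytest.raises(DomainError):
            summarize_sto2(img, labels)

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValidationError):
            StO2Summary("tumor", n_pixels=0, median_percent=50,
                        min_percent=40, max_percent=60)
        with pytest.raises(ValidationError):
            StO2Summary("tumor", n_pixels=5, median_percent=30,
                        min_percent=40, max_percent=60)


class TestIO:
    def test_spectral_image_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        img = SpectralImage(
            r_plane=rng.uniform(10, 500, (6, 7)),
            g_plane=rng.uniform(10, 500, (6, 7)),
            b445_plane=rng.uniform(10, 500, (6, 7)),
            sto2_plane=rng.uniform(0, 100, (6, 7)),
            roi=rng.random((6, 7)) > 0.4,
        )
        write_spectral_image(tmp_path / "scene", img)
        back = read_spectral_image(tmp_path / "scene")
        assert np.allclose(back.r_plane, img.r_plane, rtol=1e-6)
        assert np.allclose(back.sto2_plane, img.sto2_plane, rtol=1e-6)
        assert np.array_equal(back.roi, img.roi)

    def test_missing_files_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValidationError, match="channels.tif"):
            read_spectral_image(tmp_path / "empty")

    def test_label_map_round_trip_with_legend(self, tmp_path):
        labels = np.arange(12, dtype=np.uint8).reshape(3, 4) % 4
        path = tmp_path / "labels.tif"
        write_label_map(path, labels)
        assert np.array_equal(read_label_map(path), labels)
        import json

        legend = json.loads(path.with_suffix(".legend.json").read_text())
        assert legend["legend"] == LABEL_CODES

    def test_summaries_csv(self, tmp_path):
        import pandas as pd

        s = StO2Summary("tumor", 10, 65.7, 53.0, 76.3)
        write_summaries(tmp_path / "s.csv", [s])
        df = pd.read_csv(tmp_path / "s.csv")
        assert df.loc[0, "region"] == "tumor"
        assert df.loc[0, "median_percent"] == 65.7
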