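"""Linear discriminant boundaries: fitting, classification, geometry."""

import numpy as np
import pytest

from oximask import (
    DegenerateBoundaryError,
    DiscriminantLine,
    FeaturePoint,
    FitError,
    LabeledFeatureSet,
    SpectralSample,
    UnsupportedGeometryError,
    ValidationError,
    classify_point,
    classify_points,
    compute_features,
    fit_lda,
    load_model,
    reference_models,
    save_model,
)
from conftest import gaussian_two_class


class TestFit:
    def test_recovers_analytic_boundary(self):
        """Equal-prior LDA on shared-covariance Gaussians with means
        (2,-1) and (1,0), covariance I: the analytic boundary is the
        perpendicular bisector y = x - 2."""
        data = gaussian_two_class(5000, 5000, (2, -1), (1, 0), np.eye(2), seed=42)
        line = fit_lda(data)
        assert line.slope == pytest.approx(1.0, abs=0.05)
        assert line.intercept == pytest.approx(-2.0, abs=0.05)
        # the positive (blood) mean (2, -1) lies below y = x - 2
        assert line.positive_side == "below"
        assert line.positive_class == "blood"

    def test_identical_means_degenerate(self):
        data = gaussian_two_class(50, 50, (1, 1), (1, 1), np.eye(2), seed=0)
        # force exactly coincident empirical means
        pts = data.points.copy()
        pts[:50] -= pts[:50].mean(axis=0) - (1, 1)
        pts[50:] -= pts[50:].mean(axis=0) - (1, 1)
        with pytest.raises(DegenerateBoundaryError):
            fit_lda(LabeledFeatureSet(points=pts, labels=data.labels))

    def test_mirror_symmetry(self):
        """Reflecting x -> -x negates the slope and flips no labels."""
        data = gaussian_two_class(200, 200, (2, -1), (0.5, 0.5),
                                  [[1.0, 0.3], [0.3, 0.8]], seed=7)
        line = fit_lda(data)
        mirrored = LabeledFeatureSet(
            points=data.points * np.array([-1.0, 1.0]), labels=data.labels
        )
        mline = fit_lda(mirrored)
        assert mline.slope == pytest.approx(-line.slope, rel=1e-9)
        assert mline.intercept == pytest.approx(line.intercept, rel=1e-9)
        before = classify_points(data.points, line)
        after = classify_points(mirrored.points, mline)
        assert (before == after).all()

    def test_collinear_points_singular(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t])  # all on one line
        labels = np.array(["blood"] * 5 + ["reddish_tumor"] * 5, dtype=object)
        with pytest.raises(FitError):
            fit_lda(LabeledFeatureSet(points=pts, labels=labels))

    def test_vertical_boundary_unsupported(self):
        base = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 0.0], [-1.0, 0.0]])
        pts = np.vstack([base, base + (5.0, 0.0)])
        labels = np.array(["blood"] * 4 + ["reddish_tumor"] * 4, dtype=object)
        with pytest.raises(UnsupportedGeometryError):
            fit_lda(LabeledFeatureSet(points=pts, labels=labels))

    def test_needs_two_classes_and_min_counts(self):
        pts = np.random.default_rng(0).normal(size=(6, 2))
        one = np.array(["blood"] * 6, dtype=object)
        with pytest.raises(ValidationError, match="two classes"):
            fit_lda(LabeledFeatureSet(points=pts, labels=one))
        few = np.array(["blood"] * 2 + ["reddish_tumor"] * 4, dtype=object)
        with pytest.raises(ValidationError, match=">= 3"):
            fit_lda(LabeledFeatureSet(points=pts, labels=few))

    def test_positive_class_inference_requires_adherent(self):
        data = gaussian_two_class(10, 10, (0, 0), (3, 3), np.eye(2), seed=1,
                                  pos="a", neg="b")
        with pytest.raises(ValidationError, match="positive_class"):
            fit_lda(data)
        line = fit_lda(data, positive_class="a")
        assert line.positive_class == "a"


class TestMahalanobisOracle:
    """Equal-prior LDA must agree with brute-force
    nearest-Mahalanobis-mean classification under the pooled covariance."""

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_on_points_and_grid(self, seed):
        rng = np.random.default_rng(seed)
        mu_pos = rng.normal(size=2)
        mu_neg = mu_pos + rng.normal(size=2) * 2 + 0.5
        a = rng.normal(size=(2, 2))
        cov = a @ a.T + 0.5 * np.eye(2)
        data = gaussian_two_class(
            40, 30, mu_pos, mu_neg, cov, seed=seed + 100
        )
        line = fit_lda(data)

        labels = data.labels.astype(str)
        zp = data.points[labels == "blood"]
        zn = data.points[labels == "reddish_tumor"]
        pooled = (
            (zp - zp.mean(0)).T @ (zp - zp.mean(0))
            + (zn - zn.mean(0)).T @ (zn - zn.mean(0))
        ) / (len(zp) + len(zn) - 2)
        inv = np.linalg.inv(pooled)

        lo = data.points.min(axis=0)
        hi = data.points.max(axis=0)
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], 25),
                             np.linspace(lo[1], hi[1], 25))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        for pts in (data.points, grid):
            dp = np.einsum("ij,ij->i", (pts - zp.mean(0)) @ inv, pts - zp.mean(0))
            dn = np.einsum("ij,ij->i", (pts - zn.mean(0)) @ inv, pts - zn.mean(0))
            oracle = np.where(dp < dn, "blood", "reddish_tumor")
            assert (classify_points(pts, line).astype(str) == oracle).all()


def test_agrees_with_sklearn_lda():
    """Independent cross-check against scikit-learn's LDA."""
    sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
    data = gaussian_two_class(80, 120, (1.5, -0.5), (0.3, 0.4),
                              [[0.6, 0.2], [0.2, 0.9]], seed=11)
    line = fit_lda(data, priors="empirical")
    clf = sklearn_da.LinearDiscriminantAnalysis(solver="svd")
    clf.fit(data.points, data.labels.astype(str))
    grid = np.random.default_rng(3).uniform(-3, 4, size=(400, 2))
    assert (classify_points(grid, line).astype(str) == clf.predict(grid)).all()


class TestPriors:
    def test_empirical_priors_shift_toward_smaller_class(self):
        data = gaussian_two_class(40, 400, (2, -1), (1, 0), np.eye(2), seed=5)
        equal = fit_lda(data, priors="equal")
        emp = fit_lda(data, priors="empirical")
        assert emp.slope == pytest.approx(equal.slope, rel=1e-9)
        # flipped grid points all lie in the band between the boundaries
        grid = np.random.default_rng(9).uniform(-3, 5, size=(2000, 2))
        flipped = classify_points(grid, equal) != classify_points(grid, emp)
        offsets_e = equal.signed_offset(grid[:, 0], grid[:, 1])
        offsets_m = emp.signed_offset(grid[:, 0], grid[:, 1])
        assert (np.sign(offsets_e[flipped]) != np.sign(offsets_m[flipped])).all()
        # smaller (positive) class loses territory: its mean's side of the
        # equal boundary now starts further toward its mean
        mean_pos_offset = equal.signed_offset(2.0, -1.0)
        shift = emp.intercept - equal.intercept
        assert np.sign(shift) == np.sign(mean_pos_offset)


class TestClassify:
    def test_published_rule_on_class_averages(self, ref_lines):
        blood_line, coating_line = ref_lines
        blood_avg = compute_features(SpectralSample(r=232.9, g=36.6, b445=25.0))
        assert classify_point(blood_avg, blood_line) == "blood"
        whitish_avg = compute_features(SpectralSample(r=380.2, g=211.4, b445=212.8))
        assert classify_point(whitish_avg, coating_line) == "whitish_tumor"

    def test_point_on_line_goes_to_tumor(self, ref_lines):
        blood_line, _ = ref_lines
        on_line = FeaturePoint(x=0.0, y=blood_line.intercept)
        assert classify_point(on_line, blood_line) == blood_line.negative_class


class TestReferenceModels:
    def test_published_coefficients(self, ref_lines):
        blood_line, coating_line = ref_lines
        assert blood_line.formula() == "Y > -4.90X + 7.13"
        assert coating_line.formula() == "Y < -0.52X + 0.17"

    def test_json_round_trip_bit_exact(self, tmp_path, ref_lines):
        for i, line in enumerate(ref_lines):
            path = tmp_path / f"model{i}.json"
            save_model(path, line, task=line.positive_class, priors="equal",
                       seed=0)
            assert load_model(path) == line

    def test_validation_error_on_malformed_model(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"slope": 1.0}')
        with pytest.raises(ValidationError):
            load_model(path)


def test_line_validation():
    with pytest.raises(ValidationError):
        DiscriminantLine(slope=np.nan, intercept=0, positive_side="above",
                         positive_class="blood", negative_class="reddish_tumor")
    with pytest.raises(ValidationError):
        DiscriminantLine(slope=1, intercept=0, positive_side="left",
                         positive_class="blood", negative_class="reddish_tumor")
    with pytest.raises(ValidationError):
        DiscriminantLine(slope=1, intercept=0, positive_side="above",
                         positive_class="blood", negative_class="blood")
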