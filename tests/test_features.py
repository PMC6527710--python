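"""Feature models: GIST, medial axis, skeletal dissimilarity, category RDM."""

import numpy as np
import pytest

from megrwa.containers import squareform_rdm, upper_triangle
from megrwa.features import (
    GISTDescriptor,
    categorical_rdm,
    compute_gist,
    correlation_distance_matrix,
    gist_rdm,
    medial_axis_transform,
    model_intercorrelation,
    skeleton_dissimilarity,
)


def _disc(size=96, radius=28):
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - size / 2) ** 2 + (yy - size / 2) ** 2 <= radius**2


class TestGIST:
    def test_default_descriptor_length_is_512(self):
        d = compute_gist(np.random.default_rng(0).random((64, 64)))
        assert d.values.shape == (512,)
        assert d.n_scales * d.n_orientations * d.grid**2 == 512

    def test_constant_image_gives_zero_descriptor(self):
        d = compute_gist(np.full((64, 64), 0.7))
        assert np.allclose(d.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("scale_idx,orient_idx", [(1, 0), (1, 2), (2, 6), (0, 4)])
    def test_grating_peaks_in_matching_band(self, scale_idx, orient_idx):
        """A full-field grating at a filter's center frequency maximizes the
        energy of exactly that (scale, orientation) band."""
        size = 256
        yy, xx = np.mgrid[0:size, 0:size]
        f0 = 0.25 / 2**scale_idx
        th = np.pi * orient_idx / 8
        img = 0.5 + 0.4 * np.cos(2 * np.pi * f0 * (xx * np.cos(th) + yy * np.sin(th)))
        d = compute_gist(img, prefilter=False)
        band_energy = d.values.reshape(4, 8, 16).sum(axis=2)
        assert np.unravel_index(np.argmax(band_energy), (4, 8)) == (scale_idx, orient_idx)

    def test_invariant_to_constant_offset_with_prefilter(self, rng):
        img = rng.random((64, 64))
        a = compute_gist(img, prefilter=True).values
        b = compute_gist(img + 0.3, prefilter=True).values
        assert np.allclose(a, b, atol=1e-8)

    def test_image_smaller_than_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            compute_gist(np.ones((3, 3)), grid=4)

    def test_nonnegative_before_normalization(self, rng):
        assert (compute_gist(rng.random((64, 64))).values >= 0).all()


class TestGistRDM:
    def _desc(self, values):
        g = int(np.sqrt(len(values) / 2))
        return GISTDescriptor(np.asarray(values, float), 2, 1, g)

    def test_identical_descriptors_distance_zero(self, rng):
        v = rng.random(512)
        d = GISTDescriptor(v, 4, 8, 4)
        rdm = gist_rdm([d, GISTDescriptor(v.copy(), 4, 8, 4)])
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_descriptors_distance_two(self, rng):
        v = rng.random(512)
        centered = v - v.mean()
        a = GISTDescriptor(centered, 4, 8, 4)
        b = GISTDescriptor(-centered, 4, 8, 4)
        rdm = gist_rdm([a, b], normalize="none")
        assert rdm.matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_pearson(self, rng):
        vecs = rng.normal(size=(3, 512))
        descs = [GISTDescriptor(v, 4, 8, 4) for v in vecs]
        rdm = gist_rdm(descs, normalize="none")
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else 1 - np.corrcoef(vecs[i], vecs[j])[0, 1]
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_descriptor_fallback_distance_one(self, rng):
        a = GISTDescriptor(np.zeros(512), 4, 8, 4)
        b = GISTDescriptor(rng.random(512), 4, 8, 4)
        rdm = gist_rdm([a, b])
        assert rdm.matrix[0, 1] == pytest.approx(1.0)


class TestMedialAxis:
    def test_disc_skeleton_compact_with_disc_radius(self):
        sk = medial_axis_transform(_disc(96, 28))
        assert sk.radii.max() == pytest.approx(28, abs=1.5)
        assert np.allclose(sk.points.mean(axis=0), [48, 48], atol=2.0)

    def test_one_pixel_line_is_its_own_skeleton(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 3:17] = True
        sk = medial_axis_transform(m)
        assert (sk.points[:, 0] == 10).all()
        assert len(sk.points) == 14

    def test_rectangle_dominant_segment_with_oblique_branches(self):
        """A 40 x 10 rectangle has a central horizontal segment whose
        inscribed radius is the half-height, plus 4 oblique corner branches
        (the analytic medial axis of a rectangle)."""
        m = np.zeros((30, 60), dtype=bool)
        m[10:20, 10:50] = True
        sk = medial_axis_transform(m)
        assert sk.radii.max() == pytest.approx(5.0, abs=1.0)
        central = np.abs(sk.points[:, 0] - 14.5) < 1.0
        assert central.sum() >= 30  # dominant horizontal run
        assert sk.n_branches == 5  # trunk + 4 obliques

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            medial_axis_transform(np.zeros((10, 10), dtype=bool))

    def test_points_inside_mask_and_radii_positive(self):
        m = _disc(64, 20)
        sk = medial_axis_transform(m)
        assert m[sk.points[:, 0].astype(int), sk.points[:, 1].astype(int)].all()
        assert (sk.radii > 0).all()


class TestSkeletonDissimilarity:
    def test_identical_masks_zero(self):
        sk = medial_axis_transform(_disc())
        assert skeleton_dissimilarity(sk, sk) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        masks = [_disc(64, 20), np.zeros((64, 64), bool)]
        masks[1][20:44, 10:54] = True
        a, b = (medial_axis_transform(m) for m in masks)
        assert skeleton_dissimilarity(a, b) == pytest.approx(skeleton_dissimilarity(b, a))

    def test_star_farther_from_disc_than_mild_ellipse(self):
        """With areas matched, a 5-pointed star deforms a disc's skeleton far
        more than a 1.1:1 ellipse does."""
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        x = (xx - size / 2) / (size / 2)
        y = (yy - size / 2) / (size / 2)
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        disc = r <= 0.5
        ellipse = (x / (0.5 * np.sqrt(1.1))) ** 2 + (y / (0.5 / np.sqrt(1.1))) ** 2 <= 1
        c, dep = 0.775, 0.45
        R_star = 0.5 / np.sqrt(c**2 + dep**2 / 8)
        star = r <= R_star * (c + dep / 2 * np.cos(5 * theta))
        areas = [m.sum() for m in (disc, ellipse, star)]
        assert max(areas) / min(areas) < 1.1  # matched areas
        d0 = medial_axis_transform(disc)
        d_star = skeleton_dissimilarity(d0, medial_axis_transform(star))
        d_ell = skeleton_dissimilarity(d0, medial_axis_transform(ellipse))
        assert d_star > d_ell

    def test_matches_brute_force_chamfer(self):
        a = medial_axis_transform(_disc(64, 20))
        m = np.zeros((64, 64), bool)
        m[16:48, 10:54] = True
        b = medial_axis_transform(m)

        def features(s):
            pts = s.points - s.points.mean(axis=0)
            scale = np.sqrt(np.mean((pts**2).sum(axis=1)) + np.mean(s.radii**2))
            return np.column_stack([pts / scale, s.radii / scale])

        fa, fb = features(a), features(b)
        near_ab = [min(np.linalg.norm(p - q) for q in fb) for p in fa]
        near_ba = [min(np.linalg.norm(p - q) for q in fa) for p in fb]
        d_ab = np.dot(a.radii, near_ab) / a.radii.sum()
        d_ba = np.dot(b.radii, near_ba) / b.radii.sum()
        expected = 0.5 * (d_ab + d_ba) + 0.05 * abs(a.n_branches - b.n_branches) / (
            a.n_branches + b.n_branches
        )
        assert skeleton_dissimilarity(a, b) == pytest.approx(expected, rel=1e-10)

    def test_rotation_equivariance_90_degrees(self):
        """Rotating both shapes by 90 degrees leaves the dissimilarity
        unchanged up to the thinning discretization tolerance."""
        m1 = np.zeros((64, 64), bool)
        m1[16:48, 10:54] = True
        m2 = _disc(64, 18) | m1
        d = skeleton_dissimilarity(medial_axis_transform(m1), medial_axis_transform(m2))
        d_rot = skeleton_dissimilarity(
            medial_axis_transform(np.rot90(m1)), medial_axis_transform(np.rot90(m2))
        )
        assert d_rot == pytest.approx(d, rel=0.05)


class TestCategoricalRDM:
    def test_six_by_five_same_category_pair_count(self):
        labels = np.repeat(np.arange(6), 5)
        rdm = categorical_rdm(labels)
        same = (upper_triangle(rdm.matrix) == 0).sum()
        assert same == 60  # 6 * C(5, 2)

    def test_single_category_all_zero(self):
        assert not categorical_rdm(np.zeros(5, int)).matrix.any()

    def test_all_distinct_all_ones_off_diagonal(self):
        rdm = categorical_rdm(np.arange(5))
        assert (upper_triangle(rdm.matrix) == 1).all()


class TestModelIntercorrelation:
    def test_self_correlation_is_one(self, model_rdms):
        rho = model_intercorrelation([model_rdms[0], model_rdms[0]])
        assert rho[0, 1] == pytest.approx(1.0)

    def test_monotone_transform_preserves_rank_correlation(self, model_rdms):
        from megrwa.containers import ModelRDM

        base = model_rdms[0]
        transformed = ModelRDM("t", np.sqrt(base.matrix) * 3.0, base.stimulus_ids)
        rho = model_intercorrelation([base, transformed])
        assert rho[0, 1] == pytest.approx(1.0)

    def test_hand_computed_toy_spearman(self):
        from megrwa.containers import ModelRDM

        d1 = ModelRDM("a", squareform_rdm(np.array([1, 2, 3, 4, 5, 6.0]), 4))
        d2 = ModelRDM("b", squareform_rdm(np.array([2, 1, 3, 4, 6, 5.0]), 4))
        rho = model_intercorrelation([d1, d2])
        # distinct integer ranks, sum d^2 = 4: rho = 1 - 6*4 / (6*35) = 31/35
        assert rho[0, 1] == pytest.approx(31 / 35, abs=1e-12)

    def test_constant_rdm_reported_missing_with_warning(self):
        from megrwa.containers import ModelRDM

        const = ModelRDM("c", np.ones((4, 4)) - np.eye(4))
        other = ModelRDM("a", squareform_rdm(np.arange(1, 7, dtype=float), 4))
        with pytest.warns(UserWarning, match="constant RDM"):
            rho = model_intercorrelation([const, other])
        assert np.isnan(rho[0, 1])

    def test_collinear_synthetic_set_all_positive(self, model_rdms):
        """The default stimulus set reproduces weak positive collinearity
        between all three models."""
        rho = model_intercorrelation(model_rdms)
        off = rho[np.triu_indices(3, k=1)]
        assert (off > 0).all()


class TestRDMValidity:
    def test_all_model_rdms_symmetric_hollow_finite(self, model_rdms):
        for rdm in model_rdms:
            assert np.allclose(rdm.matrix, rdm.matrix.T)
            assert np.allclose(np.diag(rdm.matrix), 0)
            assert np.isfinite(rdm.matrix).all()

    def test_correlation_distance_range(self, rng):
        d = correlation_distance_matrix(rng.normal(size=(10, 40)))
        assert (d >= 0).all() and (d <= 2).all()
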