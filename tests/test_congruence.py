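import numpy as np
import pytest

from conftest import brute_force_knn_radii, brute_force_manifold_fraction
from smd_scorecard.congruence import (
    metric_centroid_alignment,
    metric_fid,
    metric_knn_precision,
    metric_marginal_divergence,
    metric_paired_image_similarity,
)
from smd_scorecard.data_model import DataModelError, FeatureMatrix, ImageSet
from smd_scorecard.fixtures import gen_embedding_pair


def fm(a):
    return FeatureMatrix(np.asarray(a, dtype=float))


class TestFid:
    def test_identity_is_zero(self, rng):
        X = fm(rng.normal(size=(30, 4)))
        assert metric_fid(X, X).raw_value == pytest.approx(0.0, abs=1e-8)

    def test_one_dim_mean_shift(self):
        # sample moments: mu_r=0, mu_s=2, sigma_r=sigma_s=1
        assert metric_fid(fm([[-1], [0], [1]]), fm([[1], [2], [3]])).raw_value \
            == pytest.approx(4.0, abs=1e-8)

    def test_one_dim_scale_gap(self):
        # equal means, sigma_r=1, sigma_s=3 -> (1-3)^2 = 4
        assert metric_fid(fm([[-1], [0], [1]]), fm([[-3], [0], [3]])).raw_value \
            == pytest.approx(4.0, abs=1e-8)

    def test_matches_1d_closed_form_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            r = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 3), size=50)
            s = rng.normal(rng.uniform(-3, 3), rng.uniform(0.5, 3), size=60)
            expected = (r.mean() - s.mean()) ** 2 + (r.std(ddof=1) - s.std(ddof=1)) ** 2
            got = metric_fid(fm(r[:, None]), fm(s[:, None])).raw_value
            assert got == pytest.approx(expected, abs=1e-6)

    def test_requires_two_samples(self):
        with pytest.raises(DataModelError):
            metric_fid(fm([[1.0]]), fm([[1.0], [2.0]]))


class TestMarginalDivergence:
    def test_jsd_identity_zero(self, rng):
        X = fm(rng.normal(size=(40, 3)))
        assert metric_marginal_divergence(X, X, "jsd").raw_value == pytest.approx(0.0)

    def test_jsd_disjoint_supports_one_bit(self, rng):
        r = fm(rng.uniform(0, 1, (50, 2)))
        s = fm(rng.uniform(10, 11, (50, 2)))
        assert metric_marginal_divergence(r, s, "jsd").raw_value == pytest.approx(1.0)

    def test_emd_location_shift_closed_form(self, rng):
        r = fm(rng.normal(size=(80, 1)))
        s = fm(r.values + 2.5)
        assert metric_marginal_divergence(r, s, "emd").raw_value \
            == pytest.approx(2.5, abs=1e-10)

    def test_emd_symmetric_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b, c = (fm(rng.normal(rng.uniform(-2, 2), 1, (30, 1)))
                       for _ in range(3))
            dab = metric_marginal_divergence(a, b, "emd").raw_value
            dba = metric_marginal_divergence(b, a, "emd").raw_value
            dac = metric_marginal_divergence(a, c, "emd").raw_value
            dcb = metric_marginal_divergence(c, b, "emd").raw_value
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-12

    def test_degenerate_feature_flagged(self):
        r = fm([[1.0, 0.0], [1.0, 1.0]])
        s = fm([[1.0, 0.5], [1.0, 0.7]])
        res = metric_marginal_divergence(r, s, "jsd")
        assert res.params["degenerate_features"] == [0]


class TestCentroidAlignment:
    def test_identical_centroids_cosine_one(self, rng):
        X = fm(rng.normal(1, 1, (20, 3)))
        assert metric_centroid_alignment(X, X, "cosine").raw_value == pytest.approx(1.0)

    def test_orthogonal_centroids_cosine_zero(self):
        r = fm([[1.0, 0.0], [1.0, 0.0]])
        s = fm([[0.0, 1.0], [0.0, 1.0]])
        assert metric_centroid_alignment(r, s, "cosine").raw_value == pytest.approx(0.0)

    def test_distance_to_reference_centroid(self):
        r = fm([[1.0, 1.0], [-1.0, -1.0]])  # centroid (0, 0)
        s = fm([[3.0, 4.0]])
        res = metric_centroid_alignment(r, s, "distance")
        assert res.raw_value == pytest.approx(5.0)
        assert "reference_self_distance" in res.params

    def test_zero_centroid_rejected_for_cosine(self):
        r = fm([[1.0, 0.0], [-1.0, 0.0]])
        with pytest.raises(DataModelError, match="zero centroid"):
            metric_centroid_alignment(r, r, "cosine")


class TestPairedImageSimilarity:
    def test_identical_pairs(self, rng):
        imgs = ImageSet([rng.uniform(0, 255, (16, 16)) for _ in range(3)])
        same = ImageSet([im.copy() for im in imgs.images])
        assert metric_paired_image_similarity(imgs, same, "ssim").raw_value \
            == pytest.approx(1.0)
        assert metric_paired_image_similarity(imgs, same, "psnr").raw_value \
            == pytest.approx(100.0)

    def test_psnr_zero_db_at_full_range_error(self):
        a = ImageSet([np.zeros((12, 12))])
        b = ImageSet([np.full((12, 12), 255.0)])
        assert metric_paired_image_similarity(a, b, "psnr").raw_value \
            == pytest.approx(0.0)

    def test_count_mismatch_rejected(self, rng):
        a = ImageSet([rng.uniform(0, 255, (8, 8))])
        b = ImageSet([rng.uniform(0, 255, (8, 8)) for _ in range(2)])
        with pytest.raises(DataModelError, match="equal counts"):
            metric_paired_image_similarity(a, b, "psnr")


class TestKnnPrecision:
    def test_identical_sets_full_precision(self, rng):
        X = fm(rng.normal(size=(20, 3)))
        assert metric_knn_precision(X, X, k=3).raw_value == pytest.approx(1.0)

    def test_far_translation_zero_precision(self, rng):
        r = fm(rng.normal(size=(20, 3)))
        s = fm(r.values + 1000.0)
        assert metric_knn_precision(r, s, k=3).raw_value == pytest.approx(0.0)

    def test_constructed_grid_half_inside(self):
        ref = fm([[0.0], [1.0], [2.0], [3.0], [4.0]])
        syn = fm([[0.5], [100.0]])
        assert metric_knn_precision(ref, syn, k=1).raw_value == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n_ref = rng.integers(6, 30)
            n_syn = rng.integers(3, 30)
            k = int(rng.integers(1, 4))
            r = rng.normal(size=(n_ref, 2))
            s = rng.normal(size=(n_syn, 2))
            radii = brute_force_knn_radii(r, k)
            expected = brute_force_manifold_fraction(s, r, radii)
            assert metric_knn_precision(fm(r), fm(s), k=k).raw_value \
                == pytest.approx(expected)


class TestMonotoneSensitivity:
    def test_fid_emd_and_one_minus_precision_non_decreasing_in_shift(self):
        fids, emds, miss = [], [], []
        for shift in (0.0, 0.5, 1.0, 2.0):
            ref, syn = gen_embedding_pair(n=500, d=4, shift=shift, seed=0)
            fids.append(metric_fid(ref, syn).raw_value)
            emds.append(metric_marginal_divergence(ref, syn, "emd").raw_value)
            miss.append(1.0 - metric_knn_precision(ref, syn, k=3).raw_value)
        for series in (fids, emds, miss):
            assert all(a <= b + 1e-12 for a, b in zip(series, series[1:])), series


class TestBounds:
    def test_bounded_metrics_respect_bounds_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            r = fm(rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), (15, 2)))
            s = fm(rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), (15, 2)))
            assert 0.0 <= metric_marginal_divergence(r, s, "jsd").raw_value <= 1.0
            assert -1.0 <= metric_centroid_alignment(r, s, "cosine").raw_value <= 1.0
            assert 0.0 <= metric_knn_precision(r, s, k=2).raw_value <= 1.0
            assert metric_fid(r, s).raw_value >= 0.0
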