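import numpy as np
import pytest

from conftest import brute_force_knn_radii, brute_force_manifold_fraction
from smd_scorecard.coverage import (
    metric_cluster_occupancy,
    metric_dispersion,
    metric_hull_ratio,
    metric_inception_style_score,
    metric_kernel_diversity,
    metric_knn_support,
)
from smd_scorecard.data_model import DataModelError, FeatureMatrix
from smd_scorecard.fixtures import gen_embedding_pair


def fm(a):
    return FeatureMatrix(np.asarray(a, dtype=float))


class TestKnnSupport:
    def test_identical_sets_score_one_both_modes(self, rng):
        X = fm(rng.normal(size=(25, 3)))
        for mode in ("recall", "coverage"):
            assert metric_knn_support(X, X, k=3, mode=mode).raw_value \
                == pytest.approx(1.0)

    def test_collapsed_far_synthetic_scores_zero(self, rng):
        ref = fm(rng.normal(size=(20, 2)))
        syn = fm(np.tile([500.0, 500.0], (20, 1)) + rng.normal(0, 1e-6, (20, 2)))
        for mode in ("recall", "coverage"):
            assert metric_knn_support(ref, syn, k=3, mode=mode).raw_value \
                == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n_ref = int(rng.integers(5, 30))
            n_syn = int(rng.integers(5, 30))
            k = int(rng.integers(1, 4))
            r = rng.normal(size=(n_ref, 2))
            s = rng.normal(size=(n_syn, 2))
            # recall: reference points inside the synthetic manifold
            recall_expected = brute_force_manifold_fraction(
                r, s, brute_force_knn_radii(s, k))
            got = metric_knn_support(fm(r), fm(s), k=k, mode="recall").raw_value
            assert got == pytest.approx(recall_expected), f"trial {trial}"
            # coverage: each reference kNN ball must contain a synthetic point
            radii = brute_force_knn_radii(r, k)
            cov_expected = np.mean([
                any(np.linalg.norm(p - q) <= rad for q in s)
                for p, rad in zip(r, radii)
            ])
            got = metric_knn_support(fm(r), fm(s), k=k, mode="coverage").raw_value
            assert got == pytest.approx(cov_expected), f"trial {trial}"

    def test_small_radius_set_rejected(self, rng):
        X = fm(rng.normal(size=(3, 2)))
        with pytest.raises(DataModelError, match="n > k"):
            metric_knn_support(X, X, k=3, mode="recall")


class TestHullRatio:
    def test_identity_ratio_one(self, rng):
        X = fm(rng.normal(size=(30, 4)))
        assert metric_hull_ratio(X, X, dims=2).raw_value == pytest.approx(1.0)

    @pytest.mark.parametrize("s", [0.3, 0.5, 0.9])
    def test_shrink_about_centroid_scales_quadratically(self, s, rng):
        ref = fm(rng.normal(size=(40, 3)))
        centroid = ref.values.mean(axis=0)
        syn = fm(centroid + s * (ref.values - centroid))
        assert metric_hull_ratio(ref, syn, dims=2).raw_value \
            == pytest.approx(s ** 2, abs=1e-6)

    def test_triangle_over_unit_square(self):
        ref = fm([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        syn = fm([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert metric_hull_ratio(ref, syn, dims=2).raw_value == pytest.approx(0.5)

    def test_degenerate_set_rejected(self):
        ref = fm([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        syn = fm([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DataModelError, match="degenerate|zero volume"):
            metric_hull_ratio(ref, syn, dims=2)


class TestKernelDiversity:
    def test_identical_points_vendi_one(self):
        X = fm(np.tile([1.0, 2.0], (7, 1)))
        assert metric_kernel_diversity(X, "vendi").raw_value == pytest.approx(1.0)

    def test_orthogonal_rows_vendi_n(self):
        X = fm(np.eye(5))
        assert metric_kernel_diversity(X, "vendi").raw_value == pytest.approx(5.0)

    def test_orthogonal_rows_dpp_near_zero(self):
        X = fm(np.eye(5))
        expected = np.log(1.0 + 1e-6)
        assert metric_kernel_diversity(X, "dpp_logdet").raw_value \
            == pytest.approx(expected, abs=1e-9)

    def test_vendi_matches_singular_value_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X = rng.normal(size=(rng.integers(3, 15), rng.integers(2, 6)))
            unit = X / np.linalg.norm(X, axis=1, keepdims=True)
            p = np.linalg.svd(unit, compute_uv=False) ** 2 / len(X)
            p = p[p > 1e-15]
            expected = np.exp(-(p * np.log(p)).sum())
            got = metric_kernel_diversity(fm(X), "vendi").raw_value
            assert got == pytest.approx(expected, abs=1e-6)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(DataModelError, match="zero-norm"):
            metric_kernel_diversity(fm([[0.0, 0.0], [1.0, 0.0]]), "vendi")


class TestDispersion:
    def test_constant_dataset_entropy_zero(self):
        X = fm(np.tile([3.0, 4.0], (10, 1)))
        assert metric_dispersion(None, X, "entropy").raw_value == pytest.approx(0.0)

    def test_variance_ratio_scales_quadratically(self, rng):
        ref = fm(rng.normal(size=(50, 3)))
        syn = fm(2.0 * ref.values)
        res = metric_dispersion(ref, syn, "variance")
        assert res.params["ratio_to_reference"] == pytest.approx(4.0)

    def test_uniform_spread_reaches_five_bits(self):
        # every bin of the 32-bin histogram equally occupied
        vals = np.repeat(np.arange(32) + 0.5, 4) / 32.0
        X = fm(vals[:, None])
        assert metric_dispersion(None, X, "entropy").raw_value \
            == pytest.approx(5.0, abs=1e-9)


class TestClusterOccupancy:
    def test_identical_well_separated_data_full_occupancy(self, rng):
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        ref = fm(np.vstack([c + rng.normal(0, 0.5, (20, 2)) for c in centers]))
        res = metric_cluster_occupancy(ref, ref, n_clusters=3, seed=0)
        assert res.raw_value == pytest.approx(1.0)

    def test_single_blob_synthetic_covers_half(self, rng):
        a = rng.normal(0, 0.5, (30, 2))
        b = rng.normal(0, 0.5, (30, 2)) + 100.0
        ref = fm(np.vstack([a, b]))
        syn = fm(rng.normal(0, 0.5, (30, 2)))
        res = metric_cluster_occupancy(ref, syn, n_clusters=2, seed=0)
        assert res.raw_value == pytest.approx(0.5)

    def test_reference_smaller_than_clusters_rejected(self, rng):
        X = fm(rng.normal(size=(3, 2)))
        with pytest.raises(DataModelError):
            metric_cluster_occupancy(X, X, n_clusters=5, seed=0)


class TestInceptionStyleScore:
    def test_uniform_rows_score_one(self):
        P = np.full((10, 4), 0.25)
        assert metric_inception_style_score(P).raw_value == pytest.approx(1.0)

    def test_balanced_one_hot_rows_score_c(self):
        P = np.tile(np.eye(4), (3, 1))
        assert metric_inception_style_score(P).raw_value == pytest.approx(4.0)

    def test_collapsed_one_hot_score_one(self):
        P = np.tile([1.0, 0.0, 0.0], (8, 1))
        assert metric_inception_style_score(P).raw_value == pytest.approx(1.0)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(DataModelError, match="probability"):
            metric_inception_style_score(np.array([[0.5, 0.6], [0.5, 0.5]]))


class TestMonotoneRecovery:
    def test_coverage_family_non_increasing_as_modes_drop(self):
        values = {"recall": [], "coverage": [], "occupancy": [], "hull": []}
        for drop in (0, 2, 3):  # keep 100%, 50%, 25% of 4 components
            ref, syn = gen_embedding_pair(
                n=500, d=4, n_components=4, drop_components=drop, seed=77)
            values["recall"].append(
                metric_knn_support(ref, syn, k=3, mode="recall").raw_value)
            values["coverage"].append(
                metric_knn_support(ref, syn, k=3, mode="coverage").raw_value)
            values["occupancy"].append(
                metric_cluster_occupancy(ref, syn, n_clusters=4, seed=77).raw_value)
            values["hull"].append(metric_hull_ratio(ref, syn, dims=2).raw_value)
        for name, series in values.items():
            assert all(a >= b - 1e-12 for a, b in zip(series, series[1:])), \
                (name, series)
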