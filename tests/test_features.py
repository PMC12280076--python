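import numpy as np
import pytest

from smd_scorecard.data_model import DataModelError, FeatureMatrix, ImageSet
from smd_scorecard.features import (
    apply_embedding,
    extract_image_features,
    extract_text_features,
    fit_embedding_pipeline,
    select_local,
)


class TestEmbeddingPipeline:
    def test_rank_one_data_preserves_distances_in_1d(self):
        t = np.linspace(-2, 3, 9)
        X = FeatureMatrix(np.column_stack([2 * t + 1, -t + 4]))
        pipe = fit_embedding_pipeline(X, k=1)
        Z = apply_embedding(pipe, X).values
        orig = apply_embedding(fit_embedding_pipeline(X), X).values  # standardized only
        for i in range(X.n):
            for j in range(X.n):
                d_std = np.linalg.norm(orig[i] - orig[j])
                d_proj = abs(Z[i, 0] - Z[j, 0])
                assert d_proj == pytest.approx(d_std, abs=1e-8)

    def test_constant_feature_gets_unit_scale_and_zero_output(self, rng):
        X = FeatureMatrix(np.column_stack([rng.normal(size=10), np.full(10, 7.0)]))
        pipe = fit_embedding_pipeline(X)
        assert pipe.per_feature_scale[1] == 1.0
        Z = apply_embedding(pipe, X).values
        np.testing.assert_allclose(Z[:, 1], 0.0)

    def test_full_rank_projection_reconstructs_standardized_input(self, rng):
        X = FeatureMatrix(rng.normal(size=(10, 5)))
        pipe = fit_embedding_pipeline(X, k=5)
        Z = apply_embedding(pipe, X).values
        standardized = (X.values - pipe.per_feature_center) / pipe.per_feature_scale
        np.testing.assert_allclose(Z @ pipe.projection.T, standardized, atol=1e-8)

    def test_reference_is_centered_after_application(self, rng):
        X = FeatureMatrix(rng.normal(3, 2, (25, 4)))
        pipe = fit_embedding_pipeline(X)
        Z = apply_embedding(pipe, X).values
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-8)

    def test_single_sample_pass_through(self, rng):
        ref = FeatureMatrix(rng.normal(size=(10, 3)))
        pipe = fit_embedding_pipeline(ref, k=2)
        out = apply_embedding(pipe, FeatureMatrix(np.ones((1, 3))))
        assert out.values.shape == (1, 2)

    def test_commutes_with_row_subsetting(self, rng):
        ref = FeatureMatrix(rng.normal(size=(20, 4)))
        X = FeatureMatrix(rng.normal(size=(12, 4)),
                          sample_ids=[f"s{i}" for i in range(12)])
        pipe = fit_embedding_pipeline(ref, k=3)
        idx = [1, 4, 7]
        a = apply_embedding(pipe, X.take(idx)).values
        b = apply_embedding(pipe, X).take(idx).values
        np.testing.assert_allclose(a, b)

    def test_deterministic_sign_convention(self, rng):
        X = FeatureMatrix(rng.normal(size=(30, 6)))
        p1 = fit_embedding_pipeline(X, k=3)
        p2 = fit_embedding_pipeline(X, k=3)
        np.testing.assert_array_equal(p1.projection, p2.projection)
        for col in p1.projection.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_invalid_k_rejected(self, rng):
        X = FeatureMatrix(rng.normal(size=(5, 3)))
        with pytest.raises(DataModelError):
            fit_embedding_pipeline(X, k=4)
        with pytest.raises(DataModelError):
            fit_embedding_pipeline(FeatureMatrix(np.ones((1, 3))))


class TestImageDescriptor:
    def test_constant_image(self):
        fm = extract_image_features(ImageSet([np.full((8, 8), 42.0)]))
        names = fm.feature_names
        row = dict(zip(names, fm.values[0]))
        assert row["std_intensity"] == 0.0
        assert row["histogram_entropy_bits"] == 0.0
        assert row["grad_h_mean_abs"] == 0.0
        assert row["grad_v_mean_abs"] == 0.0

    def test_transpose_swaps_gradient_features_only(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        a = extract_image_features(ImageSet([img])).values[0]
        b = extract_image_features(ImageSet([img.T])).values[0]
        np.testing.assert_allclose(a[[0, 1, 2, 3, 4, 7]], b[[0, 1, 2, 3, 4, 7]])
        assert a[5] == pytest.approx(b[6])
        assert a[6] == pytest.approx(b[5])

    def test_hand_computed_two_by_two(self):
        img = np.array([[0.0, 255.0], [0.0, 255.0]])
        row = extract_image_features(ImageSet([img])).values[0]
        assert row[0] == pytest.approx(127.5)  # mean
        assert row[1] == pytest.approx(127.5)  # population std
        assert row[2] == pytest.approx(np.percentile(img, 5))
        assert row[3] == pytest.approx(np.percentile(img, 95))
        assert row[4] == pytest.approx(1.0)  # two equal-mass bins
        assert row[5] == pytest.approx(255.0)  # horizontal jumps
        assert row[6] == pytest.approx(0.0)  # columns constant
        assert row[7] == pytest.approx(0.5)  # two of four above Otsu

    def test_descriptor_invariant_to_png_round_trip(self, tmp_path, rng):
        imgs = ImageSet([np.round(rng.uniform(0, 255, (12, 12)))],
                        ids=["a"])
        imgs.to_directory(tmp_path / "imgs")
        back = ImageSet.from_directory(tmp_path / "imgs")
        np.testing.assert_allclose(
            extract_image_features(imgs).values,
            extract_image_features(back).values,
        )


class TestTextFeatures:
    def test_identical_documents_identical_rows(self):
        fm = extract_text_features(["Chest pain, acute.", "chest PAIN acute"])
        np.testing.assert_allclose(fm.values[0], fm.values[1])
        cos = fm.values[0] @ fm.values[1]
        assert cos == pytest.approx(1.0)

    def test_disjoint_vocabularies_orthogonal(self):
        fm = extract_text_features(["alpha beta", "gamma delta"])
        assert fm.values[0] @ fm.values[1] == pytest.approx(0.0)

    def test_manual_count_normalization(self):
        fm = extract_text_features(["a b a"], vocabulary=["a", "b"])
        np.testing.assert_allclose(fm.values[0], np.array([2.0, 1.0]) / np.sqrt(5))

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(DataModelError, match="vocabulary"):
            extract_text_features(["...", "!!!"])


class TestSelectLocal:
    def setup_method(self):
        self.fm = FeatureMatrix(np.arange(6.0).reshape(3, 2),
                                sample_ids=["s1", "s2", "s3"])

    def test_select_all_is_identity(self):
        out = select_local(self.fm, [True, True, True])
        np.testing.assert_array_equal(out.values, self.fm.values)

    def test_select_by_id(self):
        out = select_local(self.fm, ["s2"])
        assert out.sample_ids == ["s2"]
        np.testing.assert_array_equal(out.values, self.fm.values[[1]])

    def test_empty_selection_rejected(self):
        with pytest.raises(DataModelError, match="empty selection"):
            select_local(self.fm, [False, False, False])

    def test_unknown_id_rejected(self):
        with pytest.raises(DataModelError, match="unknown sample id"):
            select_local(self.fm, ["nope"])
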