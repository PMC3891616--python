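import numpy as np
import pytest

from pfclust import load_x12, make_blobs, make_phantom
from pfclust.data import (
    features_to_labelmap,
    image_to_features,
    read_features_csv,
    read_image,
    read_labels_csv,
    write_features_csv,
    write_label_image,
    write_labels_csv,
)


class TestX12Fixture:
    def test_shape_and_frozen_values(self, x12):
        assert x12.X.shape == (12, 2)
        np.testing.assert_array_equal(x12.X[0], [-5.0, 0.0])
        np.testing.assert_array_equal(x12.X[6], [3.34, 1.67])
        np.testing.assert_array_equal(x12.X[11], [0.0, 10.0])

    def test_inlier_mean_is_origin(self, x12):
        np.testing.assert_allclose(x12.X[:10].mean(axis=0), [0.0, 0.0], atol=1e-12)

    def test_ideal_centers_and_labels(self, x12):
        np.testing.assert_array_equal(x12.true_centers, [[-3.14, 0.0], [3.14, 0.0]])
        np.testing.assert_array_equal(x12.labels, [0] * 5 + [1] * 5 + [-1, -1])

    def test_calls_are_independent_copies(self):
        a, b = load_x12(), load_x12()
        a.X[0, 0] = 99.0
        assert b.X[0, 0] == -5.0


class TestMakeBlobs:
    def test_seeded_determinism(self):
        a = make_blobs(seed=3, n_outliers=5)
        b = make_blobs(seed=3, n_outliers=5)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_degenerate_spread_recovers_centers(self):
        ds = make_blobs(K=3, n_per_cluster=20, centers=((0, 0), (5, 5), (-5, 5)),
                        spread=0.0, seed=0)
        for j in range(3):
            np.testing.assert_allclose(
                ds.X[ds.labels == j].mean(axis=0), ds.true_centers[j], atol=1e-6
            )

    def test_outliers_labeled_minus_one_and_inside_box(self):
        ds = make_blobs(K=2, n_per_cluster=10, n_outliers=7,
                        outlier_box=((-20, 20), (-20, 20)), seed=1)
        out = ds.X[ds.labels == -1]
        assert out.shape == (7, 2)
        assert np.all((out >= -20) & (out <= 20))

    def test_clt_scale_center_recovery(self):
        from pfclust import HyperParams, run_fcm

        ds = make_blobs(K=2, n_per_cluster=100, centers=((-3, 0), (3, 0)),
                        spread=0.5, seed=7)
        res = run_fcm(ds.X, 2, HyperParams(seed=7))
        V = res.V[np.argsort(res.V[:, 0])]
        assert np.max(np.abs(V - ds.true_centers)) < 3 * 0.5 / np.sqrt(100) * 2

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            make_blobs(K=0)
        with pytest.raises(ValueError):
            make_blobs(n_outliers=-1)


class TestMakePhantom:
    def test_noise_free_has_exactly_one_value_per_tissue(self):
        img, labels = make_phantom((32, 32), tissue_means=(0.0, 0.4, 0.8))
        assert img.shape == labels.shape == (32, 32)
        assert set(np.unique(img)) == {0.0, 0.4, 0.8}
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_image_matches_labels(self):
        means = (0.05, 0.35, 0.65, 0.95)
        img, labels = make_phantom((48, 48), tissue_means=means)
        np.testing.assert_array_equal(img, np.asarray(means)[labels])

    def test_seeded_noise_determinism(self):
        a, _ = make_phantom((16, 16), noise_pct=5, seed=2)
        b, _ = make_phantom((16, 16), noise_pct=5, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_noise_sigma_is_percent_of_range(self):
        img0, _ = make_phantom((200, 200), tissue_means=(0.0, 1.0), seed=0)
        img, _ = make_phantom((200, 200), tissue_means=(0.0, 1.0),
                              noise_pct=9, seed=0)
        assert np.std(img - img0) == pytest.approx(0.09, rel=0.05)

    def test_non_decreasing_radii_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((32, 32), tissue_means=(0, 0.5, 1.0), radii=(0.4, 0.6))


class TestImageFeatureConversion:
    def test_raster_order_flatten(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(
            image_to_features(img), [[1.0], [2.0], [3.0], [4.0]]
        )

    def test_label_roundtrip(self):
        labels = np.arange(12).reshape(3, 4)
        flat = labels.ravel()
        np.testing.assert_array_equal(features_to_labelmap(flat, (3, 4)), labels)

    def test_masked_pixels_excluded_and_restored(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.array([[False, True], [True, True]])
        X = image_to_features(img, mask)
        assert X.shape == (3, 1)
        restored = features_to_labelmap(np.array([5, 6, 7]), (2, 2), mask=mask)
        np.testing.assert_array_equal(restored, [[-1, 5], [6, 7]])

    def test_3d_volume_flattens(self):
        vol = np.arange(24, dtype=float).reshape(2, 3, 4)
        X = image_to_features(vol)
        assert X.shape == (24, 1)
        np.testing.assert_array_equal(X.ravel(), vol.ravel())

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            image_to_features(np.zeros((2, 2)), np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError):
            features_to_labelmap(np.zeros(4), (2, 3))


class TestFileIO:
    def test_features_csv_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(5, 3))
        p = tmp_path / "x.csv"
        write_features_csv(p, X)
        np.testing.assert_allclose(read_features_csv(p), X)

    def test_features_csv_with_header(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("a,b\n1.5,2\n3,4\n")
        np.testing.assert_allclose(read_features_csv(p), [[1.5, 2], [3, 4]])

    def test_labels_csv_roundtrip(self, tmp_path):
        p = tmp_path / "l.csv"
        write_labels_csv(p, np.array([0, 1, 2, -1]))
        np.testing.assert_array_equal(read_labels_csv(p), [0, 1, 2, -1])

    def test_png_label_image_roundtrip(self, tmp_path):
        p = tmp_path / "labels.png"
        labels = np.array([[0, 1], [2, 3]])
        write_label_image(p, labels)
        np.testing.assert_array_equal(read_image(p), labels)

    def test_nifti_roundtrip(self, tmp_path):
        p = tmp_path / "vol.nii.gz"
        labels = np.arange(8).reshape(2, 2, 2)
        write_label_image(p, labels)
        np.testing.assert_array_equal(read_image(p), labels)
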