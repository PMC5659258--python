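import numpy as np
import pytest
from scipy import ndimage

from tomocell.pixel_classifier import (
    CLASS_IDS,
    SparseAnnotation,
    TrainedClassifier,
    compute_features,
    predict_probabilities,
    train_classifier,
)
from tomocell.volume_io import ImageVolume, extract_block


def _toy_volume(rng=None):
    """Bright spheres on dark background, linearly separable by smoothing."""
    rng = rng or np.random.default_rng(0)
    data = np.full((40, 40, 40), 0.2, dtype=np.float32)
    for c in [(12, 12, 12), (28, 28, 20)]:
        zz, yy, xx = np.mgrid[:40, :40, :40]
        ball = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= 36
        data[ball] = 0.8
    data += rng.normal(0, 0.02, data.shape).astype(np.float32)
    return ImageVolume(data, voxel_size_um=1.0)


class TestComputeFeatures:
    def test_constant_volume_has_zero_derivative_features(self):
        vol = ImageVolume(np.full((16, 16, 16), 3.0), voxel_size_um=1.0)
        fs = compute_features(vol, scales_um=[1.0, 2.0])
        for name, ch in zip(fs.feature_names, np.moveaxis(fs.features, -1, 0)):
            np.testing.assert_allclose(ch, 0.0, atol=1e-5, err_msg=name)

    def test_feature_count_and_names(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), voxel_size_um=1.0)
        fs = compute_features(vol, scales_um=[1.0, 2.0, 3.0])
        assert fs.n_features == 5 * 3
        fs2 = compute_features(vol, scales_um=[1.0], include_intensity=True)
        assert fs2.feature_names[0] == "intensity"
        assert fs2.n_features == 6

    def test_dog_of_impulse_matches_analytic_gaussians(self):
        # DoG response to a unit impulse is the 3D DoG kernel itself:
        # positive at the centre, negative beyond ~2.15 sigma where the wide
        # Gaussian overtakes the narrow one.
        sigma = 3.0
        n = 49
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 1.0
        fs = compute_features(ImageVolume(vol, voxel_size_um=1.0), scales_um=[sigma])
        dog = fs.features[..., fs.feature_names.index(f"dog@{sigma:g}um")]

        def g3(r2, s):
            return np.exp(-r2 / (2 * s**2)) / (2 * np.pi * s**2) ** 1.5

        c = n // 2
        expected_center = g3(0, sigma) - g3(0, 1.6 * sigma)
        np.testing.assert_allclose(dog[c, c, c], expected_center, rtol=0.05)
        r = int(round(3 * sigma))
        expected_off = g3(r**2, sigma) - g3(r**2, 1.6 * sigma)
        assert expected_off < 0  # negative surround of the DoG
        np.testing.assert_allclose(dog[c, c, c + r], expected_off, rtol=0.05)

    def test_plane_yields_single_dominant_structure_tensor_eigenvalue(self):
        # A bright axis-aligned slab has gradient only along z at its faces,
        # so exactly one structure-tensor eigenvalue is large there.
        vol = np.zeros((40, 40, 40))
        vol[18:22] = 1.0
        fs = compute_features(ImageVolume(vol, voxel_size_um=1.0), scales_um=[1.5])
        i0 = fs.feature_names.index("structure_tensor_eig0@1.5um")
        e0 = fs.features[17, 20, 20, i0]
        e1 = fs.features[17, 20, 20, i0 + 1]
        e2 = fs.features[17, 20, 20, i0 + 2]
        assert e0 > 100 * max(abs(e1), abs(e2), 1e-12)
        # and the dominant eigenvalue matches the squared 1D gradient profile
        grad = ndimage.gaussian_filter1d(vol[:, 20, 20], 1.5, order=1)
        smoothed_sq = ndimage.gaussian_filter1d(grad**2, 3.0)
        np.testing.assert_allclose(e0, smoothed_sq[17], rtol=0.05)

    def test_translation_equivariance(self, rng):
        data = rng.random((48, 48, 48))
        vol = ImageVolume(data, voxel_size_um=1.0)
        shifted = ImageVolume(np.roll(data, 3, axis=1), voxel_size_um=1.0)
        fa = compute_features(vol, scales_um=[1.0]).features
        fb = compute_features(shifted, scales_um=[1.0]).features
        # compare well clear of the reflected boundary (kernel support of the
        # structure tensor chain is ~12 voxels at this scale)
        m = 16
        np.testing.assert_allclose(
            np.roll(fa, 3, axis=1)[m:-m, m:-m, m:-m], fb[m:-m, m:-m, m:-m],
            atol=1e-5,
        )

    def test_small_scale_warns(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), voxel_size_um=1.0)
        with pytest.warns(UserWarning, match="half a voxel"):
            compute_features(vol, scales_um=[0.2])


class TestTrainPredict:
    def _annotation(self, vol):
        bright = np.argwhere(vol.data > 0.5)
        dark = np.argwhere(vol.data < 0.3)
        rng = np.random.default_rng(5)
        bright = bright[rng.choice(len(bright), 200, replace=False)]
        dark = dark[rng.choice(len(dark), 200, replace=False)]
        return SparseAnnotation(
            np.vstack([bright, dark]),
            np.r_[
                np.full(200, CLASS_IDS["cell"]),
                np.full(200, CLASS_IDS["background"]),
            ],
        )

    def test_separable_toy_trains_to_perfect_accuracy(self):
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0, 2.0])
        annot = self._annotation(vol)
        clf = train_classifier(fs, annot, n_trees=20, seed=0)
        X = fs.features[tuple(annot.indices.T)]
        assert clf.forest.score(X, annot.labels) == 1.0

    def test_single_class_error(self):
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0])
        bad = SparseAnnotation(np.array([[1, 1, 1], [2, 2, 2]]),
                               np.array([CLASS_IDS["cell"]] * 2))
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(fs, bad, n_trees=5, seed=0)

    def test_seed_reproducibility(self):
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0])
        annot = self._annotation(vol)
        m1 = predict_probabilities(train_classifier(fs, annot, n_trees=10, seed=42), vol, fs)
        m2 = predict_probabilities(train_classifier(fs, annot, n_trees=10, seed=42), vol, fs)
        np.testing.assert_array_equal(m1.cell, m2.cell)

    def test_probabilities_sum_to_one_and_separate_classes(self):
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0, 2.0])
        clf = train_classifier(fs, self._annotation(vol), n_trees=20, seed=1)
        maps = predict_probabilities(clf, vol, fs)
        np.testing.assert_allclose(maps.total(), 1.0, atol=1e-6)
        truth = vol.data > 0.5
        assert maps.cell[truth].mean() > maps.cell[~truth].mean() + 0.5

    def test_manifest_mismatch_refused(self):
        vol = _toy_volume()
        fs1 = compute_features(vol, scales_um=[1.0])
        clf = train_classifier(fs1, self._annotation(vol), n_trees=5, seed=0)
        fs2 = compute_features(vol, scales_um=[2.0])
        with pytest.raises(ValueError, match="manifest"):
            predict_probabilities(clf, vol, features=fs2)

    def test_model_roundtrip(self, tmp_path):
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0])
        clf = train_classifier(fs, self._annotation(vol), n_trees=5, seed=0)
        clf.save(tmp_path / "model.joblib")
        clf2 = TrainedClassifier.load(tmp_path / "model.joblib")
        m1 = predict_probabilities(clf, vol, fs)
        m2 = predict_probabilities(clf2, vol, fs)
        np.testing.assert_array_equal(m1.cell, m2.cell)

    def test_blockwise_prediction_matches_in_place(self):
        """Prediction on a padded block, cropped to the core, equals the
        in-place prediction away from volume edges (reflective features)."""
        vol = _toy_volume()
        fs = compute_features(vol, scales_um=[1.0])
        clf = train_classifier(fs, self._annotation(vol), n_trees=10, seed=0)
        full = predict_probabilities(clf, vol, fs)
        block = extract_block(vol, (10, 10, 10), (16, 16, 16), pad=12)
        sub = predict_probabilities(clf, block.volume)
        core = block.core_slices_local
        np.testing.assert_allclose(
            sub.cell[core], full.cell[10:26, 10:26, 10:26], atol=1e-6
        )
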