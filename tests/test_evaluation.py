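import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tomocell.evaluation import (
    compute_snr,
    dilation_sweep,
    estimate_resolution,
    fbeta,
    grid_search,
    half_period_resolution,
    match_centroids,
    pixel_eval,
)
from tomocell.phantom import (
    PhantomSpec,
    generate_phantom,
    measure_snr,
    probabilities_from_truth,
)
from tomocell.spatial_analysis import CentroidSet
from tomocell.volume_io import ImageVolume, LabelVolume


class TestFbeta:
    def test_equal_pr_identity(self):
        for beta in (1, 2):
            for x in (0.2, 0.5, 0.9):
                assert fbeta(x, x, beta) == pytest.approx(x)

    def test_worked_value(self):
        assert fbeta(0.86, 0.84, 1) == pytest.approx(0.8499, abs=5e-5)

    def test_zero_recall(self):
        assert fbeta(1, 0, 2) == 0.0
        assert fbeta(0, 0, 1) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        p=st.floats(0, 1), r=st.floats(0, 1),
        dp=st.floats(0, 0.5), beta=st.sampled_from([1.0, 2.0]),
    )
    def test_monotone_and_symmetry(self, p, r, dp, beta):
        assert fbeta(min(p + dp, 1), r, beta) >= fbeta(p, r, beta) - 1e-12
        if beta == 1.0:
            assert fbeta(p, r, 1) == pytest.approx(fbeta(r, p, 1))


class TestPixelEval:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10, 10), dtype=np.int32)
        a[2:5] = 1
        ev = pixel_eval(LabelVolume(a), LabelVolume(a))
        assert (ev.p, ev.r) == (1.0, 1.0)
        b = np.zeros_like(a)
        b[7:9] = 1
        ev2 = pixel_eval(LabelVolume(a), LabelVolume(b))
        assert (ev2.p, ev2.r) == (0.0, 0.0)

    def test_dilated_prediction_counts_shell(self):
        truth = np.zeros((20, 20, 20), dtype=np.int32)
        zz, yy, xx = np.mgrid[:20, :20, :20]
        truth[(zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 25] = 1
        pred = ndimage.binary_dilation(truth > 0).astype(np.int32)
        ev = pixel_eval(LabelVolume(pred), LabelVolume(truth))
        n_truth = int((truth > 0).sum())
        n_pred = int((pred > 0).sum())
        assert ev.r == 1.0
        assert ev.p == pytest.approx(n_truth / n_pred)
        # conservation identities
        assert ev.tp + ev.fn == n_truth
        assert ev.tp + ev.fp == n_pred

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_eval(LabelVolume(np.zeros((2, 2, 2), dtype=np.int32)),
                       LabelVolume(np.zeros((3, 3, 3), dtype=np.int32)))


class TestMatchCentroids:
    def test_interrater_configuration(self, rng):
        """97 truth vs 96 detected, all detected matched -> (p, r) = (1, 96/97)."""
        grid = np.array(
            [[z, y, x] for z in range(0, 150, 30) for y in range(0, 150, 30)
             for x in range(0, 120, 30)]
        , dtype=float)
        truth = CentroidSet(grid[:97])
        detected = CentroidSet(grid[:96] + rng.uniform(-1.5, 1.5, (96, 3)))
        res = match_centroids(detected, truth, max_dist_um=10.0)
        assert res.p == pytest.approx(1.0)
        assert res.r == pytest.approx(96 / 97)
        assert len(res.unmatched_truth) == 1

    def test_exact_match(self):
        pts = CentroidSet(np.arange(30, dtype=float).reshape(10, 3) * 7)
        res = match_centroids(pts, pts)
        assert (res.p, res.r) == (1.0, 1.0)
        assert all(d == 0 for _, _, d in res.pairs)

    def test_offset_beyond_tolerance(self):
        pts = np.arange(30, dtype=float).reshape(10, 3) * 20
        res = match_centroids(CentroidSet(pts + np.array([15.0, 0, 0])),
                              CentroidSet(pts), max_dist_um=10.0)
        assert res.n_matches == 0

    def test_order_invariance(self, rng):
        det = rng.random((40, 3)) * 80
        tru = det[:35] + rng.normal(0, 2, (35, 3))
        r1 = match_centroids(CentroidSet(det), CentroidSet(tru))
        perm = rng.permutation(40)
        r2 = match_centroids(CentroidSet(det[perm]), CentroidSet(tru))
        assert r1.n_matches == r2.n_matches
        assert sorted(d for _, _, d in r1.pairs) == pytest.approx(
            sorted(d for _, _, d in r2.pairs)
        )
        assert r1.n_matches <= min(40, 35)

    def test_globally_closest_first(self):
        # one detection between two truths: it must pair with the closer one
        det = CentroidSet(np.array([[0, 0, 3.0]]))
        tru = CentroidSet(np.array([[0, 0, 0.0], [0, 0, 7.0]]))
        res = match_centroids(det, tru, max_dist_um=10.0)
        assert res.pairs[0][1] == 0
        assert res.pairs[0][2] == pytest.approx(3.0)

    def test_edge_margin_excludes_both_sets(self):
        det = CentroidSet(np.array([[1.0, 50, 50], [50, 50, 50]]))
        tru = CentroidSet(np.array([[2.0, 50, 50], [50, 50, 50]]))
        res = match_centroids(det, tru, max_dist_um=10.0, edge_margin_um=5.0,
                              bounds_um=(np.zeros(3), np.full(3, 100.0)))
        assert res.excluded_edge_detected == 1
        assert res.excluded_edge_truth == 1
        assert (res.p, res.r) == (1.0, 1.0)


class TestComputeSnr:
    def _markers(self):
        interior = np.zeros((10, 10, 10), dtype=np.int32)
        exterior = np.zeros_like(interior)
        interior[2:4, 2:4, 2:4] = 1
        exterior[6:8, 6:8, 6:8] = 1
        return LabelVolume(interior), LabelVolume(exterior)

    def test_ratio_ten_is_20db(self):
        interior, exterior = self._markers()
        data = np.ones((10, 10, 10))
        data[interior.data == 1] = 10.0
        _, mean, sd = compute_snr(ImageVolume(data), interior, exterior)
        assert mean == pytest.approx(20.0)
        assert sd == 0.0

    def test_equal_means_zero_db(self):
        interior, exterior = self._markers()
        _, mean, _ = compute_snr(ImageVolume(np.ones((10, 10, 10))), interior, exterior)
        assert mean == pytest.approx(0.0)

    def test_no_shared_labels(self):
        interior, _ = self._markers()
        empty = LabelVolume(np.zeros((10, 10, 10), dtype=np.int32))
        with pytest.raises(ValueError):
            compute_snr(ImageVolume(np.ones((10, 10, 10))), interior, empty)

    def test_phantom_calibration_roundtrip(self):
        """A phantom built for 4.6 dB measures 4.6 +/- 0.3 dB under the
        marker protocol, across 30 sampled cells."""
        spec = PhantomSpec(shape_vox=(110, 110, 110), n_cells=30, n_vessels=0,
                           target_snr_db=4.6, seed=21)
        ph = generate_phantom(spec)
        mean, sd = measure_snr(ph)
        assert mean == pytest.approx(4.6, abs=0.3)
        assert sd < 2.0  # per-cell spread stays in a plausible band


class TestGridSearch:
    def test_single_point_grid(self, small_truth_maps, small_phantom):
        best, table = grid_search(
            {"cell_size_vox": [18], "stop_threshold": [0.47]},
            small_truth_maps,
            small_phantom.truth_cells,
            objective="f1_cells",
        )
        assert best == {"cell_size_vox": 18, "stop_threshold": 0.47}
        assert len(table) == 1

    def test_selects_matching_template_size(self):
        spec = PhantomSpec(shape_vox=(100, 100, 100), n_cells=12,
                           cell_diameter_um=(12 * 0.65, 1e-6), n_vessels=0, seed=5)
        ph = generate_phantom(spec)
        maps = probabilities_from_truth(ph.truth_masks, blur_sigma=0.5)
        best, table = grid_search(
            {"cell_size_vox": [8, 12, 16], "stop_threshold": [0.47]},
            maps, ph.truth_cells, objective="f1_cells",
        )
        assert best["cell_size_vox"] == 12
        assert table.loc[table["cell_size_vox"] == 12, "score"].iloc[0] == max(table["score"])

    def test_degenerate_grid_warns(self, small_truth_maps, small_phantom):
        with pytest.warns(UserWarning, match="scored 0"):
            best, _ = grid_search(
                {"cell_size_vox": [40], "stop_threshold": [0.99]},
                small_truth_maps, small_phantom.truth_cells, objective="f1_cells",
            )
        assert best["stop_threshold"] == 0.99

    def test_vessel_objective_reproduces_pixel_eval(self, small_truth_maps, small_phantom):
        from tomocell.structure_segmentation import MorphParams, segment_vessels

        grid = {"threshold": [0.3, 0.6], "dilation_radius_vox": [0]}
        best, table = grid_search(grid, small_truth_maps,
                                  small_phantom.truth_masks["vessel"],
                                  objective="f2_vessels")
        for _, row in table.iterrows():
            seg = segment_vessels(
                small_truth_maps.vessel,
                MorphParams(threshold=row["threshold"], dilation_radius_vox=0),
            )
            ev = pixel_eval(seg, small_phantom.truth_masks["vessel"], betas=(2.0,))
            assert row["score"] == pytest.approx(ev.f[2.0])

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            grid_search({}, None, None)


class TestResolution:
    def test_half_period_conversions(self):
        assert half_period_resolution(0.383) == pytest.approx(1.31, abs=0.005)
        assert half_period_resolution(0.525) == pytest.approx(0.95, abs=0.005)
        assert half_period_resolution(0.5) == pytest.approx(1.0)

    def test_known_crossing_recovered(self, rng):
        """Gaussian-filtered white noise has an exactly quadratic log power
        spectrum, so the Rose crossing can be designed analytically."""
        sigma = 1.5
        target_f = 0.2  # cycles/µm at 1 µm voxels
        shape = (40, 128, 128)
        # shape white noise with an exact isotropic Gaussian transfer
        # H(f) = exp(-2 pi^2 sigma^2 |f|^2), so a plane's expected power is
        # exp(-4 pi^2 sigma^2 f_r^2) * mean_z exp(-4 pi^2 sigma^2 f_z^2)
        freqs = [np.fft.fftfreq(n) for n in shape]
        fz, fy, fx = np.meshgrid(*freqs, indexing="ij")
        H = np.exp(-2 * np.pi**2 * sigma**2 * (fz**2 + fy**2 + fx**2))
        signal = np.real(np.fft.ifftn(np.fft.fftn(rng.standard_normal(shape)) * H))
        z_factor = np.mean(np.exp(-4 * np.pi**2 * sigma**2 * freqs[0] ** 2))
        # flat NPS level putting the 5x Rose crossing exactly at target_f
        noise_var = z_factor * np.exp(-4 * np.pi**2 * sigma**2 * target_f**2) / 5.0
        background = rng.standard_normal(shape) * np.sqrt(noise_var)
        vol = ImageVolume(np.concatenate([signal, background], axis=1),
                          voxel_size_um=1.0)
        res = estimate_resolution(
            vol,
            signal_region=(slice(None), slice(0, 128), slice(None)),
            background_region=(slice(None), slice(128, 256), slice(None)),
            n_planes=40,
        )
        expected = 1.0 / (2 * target_f)
        assert res["res_xy_um"] == pytest.approx(expected, rel=0.10)
        assert res["res_xz_um"] == pytest.approx(expected, rel=0.10)

    def test_no_crossing_raises(self, rng):
        flat = rng.standard_normal((20, 64, 64))
        vol = ImageVolume(np.concatenate([flat, flat * 0.9], axis=1), voxel_size_um=1.0)
        with pytest.raises(ValueError, match="crossing"):
            estimate_resolution(vol, (slice(None), slice(0, 64), slice(None)),
                                (slice(None), slice(64, 128), slice(None)), n_planes=20)


class TestDilationSweep:
    def test_underestimating_annotation_recovers_with_dilation(self):
        truth = np.zeros((20, 20, 20), dtype=np.int32)
        truth[5:15, 5:15, 5:15] = 1
        pred = np.zeros_like(truth)
        pred[7:13, 7:13, 7:13] = 1  # conservative under-labelling
        table = dilation_sweep(LabelVolume(pred), LabelVolume(truth), max_steps=4)
        assert table["f"].idxmax() > 0  # some dilation improves agreement
        assert table["r"].iloc[-1] >= table["r"].iloc[0]
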