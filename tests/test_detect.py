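"""Spot detection: DoG filter, clustering, centroiding, photometry."""

import numpy as np
import pytest

from aerotrack.core import AerotrackError, PeakRecord, Particle
from aerotrack.detect import (DetectionConfig, centroid, detect_frame,
                              dog_filter, estimate_ghost_offset,
                              filter_ghosts, filter_proximity, find_peaks,
                              integrate_brightness, suggest_threshold)
from aerotrack.simulate import SceneSpec, render_frame


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        out = dog_filter(np.full((32, 32), 7.0), 3.0, 6.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_linearity(self, rng):
        img = rng.random((32, 32))
        assert np.allclose(dog_filter(2 * img, 3, 6), 2 * dog_filter(img, 3, 6))

    def test_impulse_response_matches_discrete_kernel(self):
        # oracle: direct evaluation of the two truncated discrete
        # Gaussian kernels scipy uses (truncate=4 sigma), normalized
        def discrete_gauss_center(sigma):
            r = int(4 * sigma + 0.5)
            x = np.arange(-r, r + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            k /= k.sum()
            return np.outer(k, k)[r, r]

        n = 101
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        out = dog_filter(img, 3.0, 6.0)
        expected = discrete_gauss_center(3.0) - discrete_gauss_center(6.0)
        assert out[n // 2, n // 2] == pytest.approx(expected, rel=1e-6)

    def test_rejects_non_2d(self):
        with pytest.raises(AerotrackError):
            dog_filter(np.zeros(10), 3, 6)
        with pytest.raises(AerotrackError):
            dog_filter(np.zeros((4, 4)), 6, 3)


def _brute_force_labels(mask):
    """Oracle: exhaustive BFS 4-connected labeling."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                while stack:
                    r, c = stack.pop()
                    if (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]
                            and mask[r, c] and labels[r, c] == 0):
                        labels[r, c] = nxt
                        stack += [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
    return nxt


class TestFindPeaks:
    def test_all_below_threshold_empty(self):
        assert find_peaks(np.zeros((16, 16)), 1.0) == []

    def test_single_blob_is_one_peak(self):
        img = np.zeros((16, 16))
        img[4:6, 4:6] = 5.0
        img[6, 4] = 5.0
        clusters = find_peaks(img, 1.0)
        assert len(clusters) == 1
        assert len(clusters[0]) == 5

    def test_matches_exhaustive_labeling_oracle(self, rng):
        img = rng.random((16, 16)) * 2
        thr = 1.0
        clusters = find_peaks(img, thr)
        assert len(clusters) == _brute_force_labels(img > thr)

    def test_subthreshold_gap_separates_blobs(self):
        img = np.zeros((16, 16))
        img[3, 3:5] = 5.0
        img[3, 6:8] = 5.0  # gap at column 5
        assert len(find_peaks(img, 1.0)) == 2

    def test_diagonal_blobs_split_with_4_connectivity(self):
        img = np.zeros((8, 8))
        img[2, 2] = img[3, 3] = 5.0
        assert len(find_peaks(img, 1.0, connectivity=1)) == 2
        assert len(find_peaks(img, 1.0, connectivity=2)) == 1


class TestCentroid:
    def test_symmetric_spot_geometric_center(self):
        cluster = np.array([[1, 1], [1, 2], [2, 1], [2, 2]])
        w = np.ones(4)
        assert centroid(cluster, w) == pytest.approx((1.5, 1.5))

    def test_hand_computed_weighted_mean(self):
        cluster = np.array([[0, 0], [0, 2]])
        assert centroid(cluster, np.array([1.0, 3.0])) == pytest.approx((0.0, 1.5))

    def test_single_pixel(self):
        assert centroid(np.array([[5, 7]]), np.array([2.0])) == (5.0, 7.0)

    def test_zero_weight_rejected(self):
        with pytest.raises(AerotrackError):
            centroid(np.array([[0, 0]]), np.array([0.0]))


class TestIntegrateBrightness:
    def test_zero_image(self):
        b, partial, sat = integrate_brightness(np.zeros((64, 64)), (32, 32))
        assert b == 0.0 and not partial and not sat

    def test_uniform_image_counts_lattice_points(self):
        # oracle: brute-force count of integer lattice points with
        # distance <= 10 from an integer center
        count = sum(1 for dr in range(-10, 11) for dc in range(-10, 11)
                    if dr * dr + dc * dc <= 100)
        img = np.full((64, 64), 3.0)
        b, _, _ = integrate_brightness(img, (32, 32), radius=10)
        assert b == pytest.approx(count * 3.0)
        assert count == 317

    def test_synthetic_spot_recovers_total_photons(self, quiet_camera):
        from aerotrack.simulate import IlluminationProfile
        p = Particle(diameter_nm=40.0, position_um=(140.0, 140.0, 0.0))
        scene = SceneSpec(particles=[p], pulse_energies_mj=(50.0,),
                          illumination=IlluminationProfile(
                              center_um=(140.0, 140.0)),
                          background=False, dark_noise=False)
        frame, truth = render_frame(scene, quiet_camera)
        r, c = truth.loc[0, "row_px"], truth.loc[0, "col_px"]
        b, _, _ = integrate_brightness(frame.pixels, (r, c), radius=10)
        assert b == pytest.approx(157.0, rel=2e-3)

    def test_edge_disk_flags_partial(self):
        b, partial, _ = integrate_brightness(np.ones((64, 64)), (3, 32))
        assert partial

    def test_centroid_outside_frame_rejected(self):
        with pytest.raises(AerotrackError):
            integrate_brightness(np.ones((64, 64)), (70, 32))

    def test_annulus_median_subtraction_removes_pedestal(self):
        img = np.full((64, 64), 5.0)
        img[30:35, 30:35] += 100.0
        b_raw, _, _ = integrate_brightness(img, (32, 32), radius=10)
        b_sub, _, _ = integrate_brightness(img, (32, 32), radius=10,
                                           background_annulus=(12, 18))
        assert b_sub == pytest.approx(b_raw - 5.0 * 317)
        assert b_sub == pytest.approx(25 * 100.0)

    def test_saturated_pixel_in_disk_flagged(self):
        img = np.zeros((64, 64))
        img[30, 30] = 30700.0
        _, _, sat = integrate_brightness(img, (32, 32),
                                         saturation_level=30700.0)
        assert sat

    def test_brightness_independent_of_subpixel_position(self, quiet_camera):
        values = []
        for frac in (0.0, 0.25, 0.5, 0.77):
            p = Particle(diameter_nm=100.0,
                         position_um=(140.0 + frac * 1.14, 140.0, 0.0))
            scene = SceneSpec(particles=[p], pulse_energies_mj=(25.0,),
                              background=False, dark_noise=False)
            frame, truth = render_frame(scene, quiet_camera)
            b, _, _ = integrate_brightness(
                frame.pixels, (truth.loc[0, "row_px"], truth.loc[0, "col_px"]))
            values.append(b)
        assert max(values) / min(values) - 1 < 0.01


class TestProximityFilter:
    def _peaks(self, *positions):
        return [PeakRecord(centroid=p) for p in positions]

    def test_closer_than_21_both_excluded(self):
        peaks = filter_proximity(self._peaks((10, 10), (10, 30.5)))
        assert all(p.proximity_excluded for p in peaks)

    def test_exactly_21_kept(self):
        peaks = filter_proximity(self._peaks((10, 10), (10, 31)))
        assert not any(p.proximity_excluded for p in peaks)

    def test_isolated_peak_kept(self):
        peaks = filter_proximity(self._peaks((10, 10), (100, 100)))
        assert not any(p.proximity_excluded for p in peaks)


class TestGhostFilter:
    def test_fainter_peak_at_offset_flagged(self):
        a = PeakRecord(centroid=(50, 50), brightness=100.0)
        b = PeakRecord(centroid=(65, 53), brightness=10.0)
        filter_ghosts([a, b], offset=(15, 3), tolerance=1.0)
        assert b.ghost and not a.ghost

    def test_equal_brightness_tie_flags_displaced_peak(self):
        a = PeakRecord(centroid=(50, 50), brightness=100.0)
        b = PeakRecord(centroid=(65, 53), brightness=100.0)
        filter_ghosts([a, b], offset=(15, 3), tolerance=1.0)
        assert b.ghost and not a.ghost

    def test_requires_at_least_one_peak(self):
        with pytest.raises(AerotrackError):
            filter_ghosts([], offset=(15, 3))

    def test_auto_offset_recovery_on_synthetic_frames(self, quiet_camera, rng):
        cfg = DetectionConfig(threshold=2.0)
        peaks_by_frame = []
        for i in range(20):
            particles = [
                Particle(diameter_nm=100.0,
                         position_um=(60.0 + 40 * j + rng.uniform(0, 10),
                                      60.0 + 70 * j + rng.uniform(0, 10), 0.0))
                for j in range(2)]
            scene = SceneSpec(particles=particles, pulse_energies_mj=(25.0,),
                              ghost_offset_px=(15.0, 3.0),
                              ghost_intensity_fraction=0.1,
                              background=False, dark_noise=False,
                              seed=1000 + i)
            frame, _ = render_frame(scene, quiet_camera)
            peaks_by_frame.append(detect_frame(frame, cfg))
        dr, dc = estimate_ghost_offset(peaks_by_frame, min_pairs=10)
        assert abs(dr - 15.0) <= 1.0 and abs(dc - 3.0) <= 1.0


class TestDetectionPipeline:
    def test_centroid_subpixel_bias_below_02px(self, quiet_camera):
        cfg = DetectionConfig(threshold=2.0)
        for frac in (0.2, 0.5, 0.8):
            p = Particle(diameter_nm=100.0,
                         position_um=(140.0 + frac * 1.14, 140.0, 0.0))
            scene = SceneSpec(particles=[p], pulse_energies_mj=(25.0,),
                              background=False, dark_noise=False)
            frame, truth = render_frame(scene, quiet_camera)
            peaks = detect_frame(frame, cfg)
            assert len(peaks) == 1
            err = np.hypot(peaks[0].centroid[0] - truth.loc[0, "row_px"],
                           peaks[0].centroid[1] - truth.loc[0, "col_px"])
            assert err < 0.2

    def test_recall_and_false_discovery_on_noisy_frames(self, camera):
        # spots at >= 10x the background fluctuation, 100 seeded frames
        cfg = DetectionConfig(threshold=8.0)
        n_true = n_found = n_false = 0
        rng = np.random.default_rng(99)
        for i in range(100):
            pos = []
            while len(pos) < 4:
                cand = (rng.uniform(40, 250), rng.uniform(40, 250))
                if all(np.hypot(cand[0] - q[0], cand[1] - q[1]) > 30
                       for q in pos):
                    pos.append(cand)
            particles = [Particle(diameter_nm=100.0, position_um=(x, y, 0.0))
                         for x, y in pos]
            scene = SceneSpec(particles=particles,
                              pulse_energies_mj=(25.0, 25.0), seed=2000 + i)
            frame, truth = render_frame(scene, camera)
            peaks = [p for p in detect_frame(frame, cfg) if p.usable]
            truth_px = truth[truth.flash == 0][["row_px", "col_px"]].to_numpy()
            n_true += len(truth_px)
            for t in truth_px:
                if any(np.hypot(p.centroid[0] - t[0],
                                p.centroid[1] - t[1]) < 3 for p in peaks):
                    n_found += 1
            for p in peaks:
                if not any(np.hypot(p.centroid[0] - t[0],
                                    p.centroid[1] - t[1]) < 3
                           for t in truth_px):
                    n_false += 1
        recall = n_found / n_true
        fdr = n_false / max(n_found + n_false, 1)
        assert recall >= 0.95
        assert fdr <= 0.05

    def test_flagging_invariant_under_peak_permutation(self, rng):
        peaks = [PeakRecord(centroid=(rng.uniform(0, 200), rng.uniform(0, 200)),
                            brightness=float(rng.uniform(10, 100)))
                 for _ in range(12)]
        import copy
        a = copy.deepcopy(peaks)
        b = copy.deepcopy(peaks)[::-1]
        filter_proximity(a)
        filter_proximity(b)
        flags_a = {p.centroid: p.proximity_excluded for p in a}
        flags_b = {p.centroid: p.proximity_excluded for p in b}
        assert flags_a == flags_b

    def test_threshold_suggestion_above_background(self, camera):
        scene = SceneSpec(particles=[], seed=4)
        frame, _ = render_frame(scene, camera)
        from aerotrack.detect import dog_filter
        dog = dog_filter(frame.pixels, 3, 6)
        thr = suggest_threshold(dog)
        assert thr > dog.mean()
        assert (dog > thr).mean() < 1e-3
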