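"""Displacement trains, correlation maps, segmentation, centroids, STA."""

import itertools

import numpy as np
import pytest

import muecho as m
from muecho.matching import CorrelationMap, _half_sine
from muecho.stica import DecompositionSet, ROIDecomposition, ROIGrid


def _fp(times, mu_id=0):
    return m.FiringPattern(mu_id=mu_id, spike_times_s=np.asarray(times, float), mean_rate_pps=10.0)


class TestDisplacementTrain:
    def test_empty_spike_list(self):
        train = m.displacement_train(_fp([]), 1024.0, 1.0)
        assert train.samples.shape == (1024,)
        assert not np.any(train.samples)

    def test_single_spike_is_half_sine(self):
        train = m.displacement_train(_fp([0.1]), 1024.0, 1.0)
        w = _half_sine(1024.0)
        assert w.size == 51  # 50 ms at 1024 fps
        k0 = int(round(0.1 * 1024))
        np.testing.assert_allclose(train.samples[k0 : k0 + 51], w)
        assert not np.any(train.samples[:k0])
        assert train.samples.max() == pytest.approx(1.0)

    def test_overlapping_spikes_sum_linearly(self):
        """Direct-summation oracle for two spikes 20 ms apart."""
        fps = 1024.0
        train = m.displacement_train(_fp([0.1, 0.12]), fps, 1.0)
        w = _half_sine(fps)
        expected = np.zeros(1024)
        for t in (0.1, 0.12):
            k = int(round(t * fps))
            expected[k : k + w.size] += w
        np.testing.assert_allclose(train.samples, expected)

    def test_spike_outside_duration_raises(self):
        with pytest.raises(ValueError):
            m.displacement_train(_fp([1.5]), 1024.0, 1.0)


def _single_roi_decomps(components: np.ndarray, fps: float) -> DecompositionSet:
    """A 1x1 ROI grid whose single ROI holds the given temporal components."""
    k, T = components.shape
    grid = ROIGrid(roi_px=38, step_px=5, row_origins=(0,), col_origins=(0,))
    d = ROIDecomposition(
        roi_index=(0, 0),
        origin=(0, 0),
        spatial=np.zeros((k, 38, 38), np.float32),
        temporal=components.astype(np.float32),
        singular_values=np.ones(k),
    )
    return DecompositionSet(grid=grid, fps=fps, mm_per_px=0.3125, items={(0, 0): d})


class TestCorrelateROIs:
    fps = 512.0

    def _train(self, times=(0.1, 0.5, 0.9, 1.3, 1.7)):
        return m.displacement_train(_fp(list(times)), self.fps, 2.0)

    def test_component_equal_to_train(self):
        train = self._train()
        z = (train.samples - train.samples.mean()) / train.samples.std()
        cmap = m.correlate_rois(train, _single_roi_decomps(z[None, :], self.fps))
        assert cmap.peak_cc[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert cmap.best_lag[0, 0] == 0
        assert cmap.sign[0, 0] == 1

    def test_negated_delayed_component_sign_aligned(self):
        train = self._train()
        z = (train.samples - train.samples.mean()) / train.samples.std()
        lag = int(round(0.010 * self.fps))  # 10 ms delay
        comp = -np.roll(z, lag)
        cmap = m.correlate_rois(train, _single_roi_decomps(comp[None, :], self.fps))
        assert cmap.peak_cc[0, 0] == pytest.approx(1.0, abs=1e-2)
        assert cmap.best_lag[0, 0] == lag
        assert cmap.sign[0, 0] == -1

    def test_delay_beyond_window_excluded(self):
        """A 30 ms delay falls outside the +/-20 ms window, so the windowed
        peak must be below the true (excluded) peak of ~1."""
        train = self._train()
        z = (train.samples - train.samples.mean()) / train.samples.std()
        comp = np.roll(z, int(round(0.030 * self.fps)))
        cmap = m.correlate_rois(train, _single_roi_decomps(comp[None, :], self.fps))
        assert cmap.peak_cc[0, 0] < 0.95
        assert abs(cmap.best_lag[0, 0]) <= int(round(0.020 * self.fps))

    def test_length_mismatch_raises(self):
        train = self._train()
        with pytest.raises(ValueError):
            m.correlate_rois(train, _single_roi_decomps(np.zeros((1, 100)), self.fps))


def _cmap_from(peaks: np.ndarray) -> CorrelationMap:
    shape = peaks.shape
    return CorrelationMap(
        mu_id=0,
        peak_cc=peaks.astype(float),
        best_component=np.zeros(shape, int),
        best_lag=np.zeros(shape, int),
        sign=np.ones(shape, int),
        fps=512.0,
    )


def _brute_force_best_cluster(peaks: np.ndarray, thr: float) -> set[tuple[int, int]]:
    """Enumerate connected groups of supra-threshold cells by flood fill."""
    cells = {(i, j) for i, j in zip(*np.nonzero(peaks > thr))}
    clusters = []
    seen: set[tuple[int, int]] = set()
    for start in sorted(cells):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            c = stack.pop()
            if c in comp:
                continue
            comp.add(c)
            for di, dj in itertools.product((-1, 0, 1), repeat=2):
                nb = (c[0] + di, c[1] + dj)
                if nb in cells and nb not in comp:
                    stack.append(nb)
        seen |= comp
        clusters.append(comp)
    if not clusters:
        return set()
    return max(clusters, key=lambda cl: (len(cl), float(np.mean([peaks[c] for c in cl]))))


class TestSegmentMap:
    def test_single_suprathreshold_roi(self):
        peaks = np.zeros((5, 5))
        peaks[2, 3] = 0.8
        assert m.segment_map(_cmap_from(peaks)) == {(2, 3)}

    def test_larger_cluster_wins(self):
        peaks = np.zeros((5, 5))
        for c in [(0, 0), (0, 1), (1, 0), (1, 1), (2, 1)]:
            peaks[c] = 0.6  # size 5, low cc
        for c in [(4, 3), (4, 4), (3, 4)]:
            peaks[c] = 0.99  # size 3, high cc
        assert m.segment_map(_cmap_from(peaks)) == {(0, 0), (0, 1), (1, 0), (1, 1), (2, 1)}

    def test_all_below_threshold_empty(self):
        peaks = np.full((5, 5), 0.5)  # threshold is strict: cc > 0.5
        assert m.segment_map(_cmap_from(peaks)) == set()

    def test_matches_brute_force_on_random_maps(self):
        """Sampled oracle over random 5x5 thresholdings: the selected cluster
        must equal flood-fill enumeration's (size, mean-cc)-best cluster."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            peaks = np.where(rng.random((5, 5)) < 0.4, rng.uniform(0.5, 1.0, (5, 5)), 0.0)
            got = m.segment_map(_cmap_from(peaks))
            want = _brute_force_best_cluster(peaks, 0.5)
            if len(got) != len(want):
                assert got == want
            else:  # equal-size ties may differ only if mean ccs tie too
                got_mean = np.mean([peaks[c] for c in got]) if got else 0.0
                want_mean = np.mean([peaks[c] for c in want]) if want else 0.0
                assert got_mean == pytest.approx(want_mean)


class TestDisplacementAreaAndProfile:
    def test_single_roi_delta_centroid(self, geometry):
        grid = ROIGrid(roi_px=38, step_px=5, row_origins=(20,), col_origins=(40,))
        spatial = np.zeros((1, 38, 38), np.float32)
        spatial[0, 19, 19] = 2.0
        d = ROIDecomposition(
            roi_index=(0, 0), origin=(20, 40), spatial=spatial,
            temporal=np.zeros((1, 100), np.float32), singular_values=np.ones(1),
        )
        dset = DecompositionSet(grid=grid, fps=512.0, mm_per_px=0.3125, items={(0, 0): d})
        peaks = np.array([[0.9]])
        canvas, (x, depth) = m.displacement_area({(0, 0)}, dset, _cmap_from(peaks), geometry)
        assert x == pytest.approx((40 + 19 + 0.5) * geometry.mm_per_px)
        assert depth == pytest.approx((20 + 19 + 0.5) * geometry.mm_per_px)

    def test_empty_cluster_raises(self, geometry):
        dset = _single_roi_decomps(np.zeros((1, 10)), 512.0)
        with pytest.raises(ValueError):
            m.displacement_area(set(), dset, _cmap_from(np.zeros((1, 1))), geometry)

    def test_sta_of_clean_twitch_train(self):
        """Time course = twitch at every spike with non-overlapping windows:
        the STA equals the twitch and the SD is ~0."""
        fps = 512.0
        w = _half_sine(fps)
        spikes = np.arange(0.5, 9.5, 0.5)  # 2 pps-like spacing, no overlap
        n = int(10 * fps)
        tc = np.zeros(n)
        for t in spikes:
            k = int(round(t * fps))
            tc[k : k + w.size] += w
        dset = _single_roi_decomps(tc[None, :], fps)
        cmap = _cmap_from(np.array([[0.9]]))
        mean, sd, lags = m.velocity_profile({(0, 0)}, dset, cmap, _fp(spikes), min_spikes=15)
        k0 = int(np.searchsorted(lags, -1e-9))
        np.testing.assert_allclose(mean[k0 : k0 + w.size], w, atol=1e-6)
        assert sd.max() < 1e-9

    def test_sta_noise_shrinks_with_spike_count(self):
        """Monte-Carlo: STA standard error scales ~1/sqrt(n spikes)."""
        fps = 512.0
        rng = np.random.default_rng(0)
        w = _half_sine(fps)
        err = {}
        for n_spk in (25, 100):
            spikes = np.arange(1, n_spk + 1) * 0.4
            n = int((spikes[-1] + 1) * fps)
            tc = np.zeros(n)
            for t in spikes:
                k = int(round(t * fps))
                tc[k : k + w.size] += w
            reps = []
            for _ in range(20):
                noisy = tc + rng.standard_normal(n)
                dset = _single_roi_decomps(noisy[None, :], fps)
                mean, _, lags = m.velocity_profile(
                    {(0, 0)}, dset, _cmap_from(np.array([[0.9]])), _fp(spikes), min_spikes=10
                )
                k0 = int(np.searchsorted(lags, -1e-9))
                reps.append(np.mean((mean[k0 : k0 + w.size] - w) ** 2))
            err[n_spk] = np.mean(reps)
        assert err[100] < err[25] / 2.5  # expect ~1/4

    def test_too_few_spikes_raises(self):
        dset = _single_roi_decomps(np.zeros((1, 5120)), 512.0)
        with pytest.raises(ValueError):
            m.velocity_profile({(0, 0)}, dset, _cmap_from(np.array([[0.9]])), _fp([0.5, 1.0]))


class TestOutputs:
    def test_identifications_h5_and_heatmap(self, tmp_path, single_mu_pipeline, geometry):
        import h5py

        ident = single_mu_pipeline["ident"]
        path = tmp_path / "idents.h5"
        m.save_identifications_h5(path, [ident])
        with h5py.File(path) as f:
            g = f[f"mu/{ident.mu_id}"]
            assert bool(g.attrs["matched"])
            assert g.attrs["centroid_x_mm"] == pytest.approx(ident.us_centroid_mm[0])
            np.testing.assert_allclose(g["displacement_map"][...], ident.displacement_map)
        png = tmp_path / "heat.png"
        m.save_heatmap_png(png, ident, geometry)
        assert png.stat().st_size > 0


class TestIdentificationInvariances:
    def test_sign_flip_invariance(self, single_mu_pipeline):
        """Flipping the sign of every ICA component must not change the
        identification (cluster, centroid, profile)."""
        p = single_mu_pipeline
        flipped_items = {}
        for key, d in p["decomps"].items.items():
            flipped_items[key] = ROIDecomposition(
                roi_index=d.roi_index, origin=d.origin, spatial=-d.spatial,
                temporal=-d.temporal, singular_values=d.singular_values,
                converged=d.converged, degenerate=d.degenerate,
            )
        flipped = DecompositionSet(
            grid=p["decomps"].grid, fps=p["decomps"].fps,
            mm_per_px=p["decomps"].mm_per_px, items=flipped_items,
        )
        a = p["ident"]
        b = m.identify_mu(p["fp"], flipped, m.MuscleGeometry(), min_sta_spikes=15)
        assert a.cluster == b.cluster
        assert a.us_centroid_mm == pytest.approx(b.us_centroid_mm)
        np.testing.assert_allclose(a.profile_mean, b.profile_mean, atol=1e-5)

    def test_other_mus_queries_do_not_interact(self, single_mu_pipeline):
        """Identification is independent per MU: querying another firing
        pattern first must not change this MU's result."""
        p = single_mu_pipeline
        other = _fp(np.arange(0.3, 2.2, 0.11), mu_id=99)
        m.identify_mu(other, p["decomps"], m.MuscleGeometry(), min_sta_spikes=15)
        again = m.identify_mu(p["fp"], p["decomps"], m.MuscleGeometry(), min_sta_spikes=15)
        assert again.cluster == p["ident"].cluster
        assert again.us_centroid_mm == pytest.approx(p["ident"].us_centroid_mm)
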