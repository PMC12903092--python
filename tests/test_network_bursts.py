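"""Network-burst detection: binning, smoothing, Otsu, detection, fragmentation."""

import math

import numpy as np
import pytest

from _oracles import brute_force_otsu, oracle_classify
from meaburst.network_bursts import (
    NetworkBurst,
    NetworkBurstParams,
    bin_spikes,
    classify_fragmented,
    combine_standardized,
    detect_network_bursts,
    fragmentation_percentage,
    gaussian_kernel,
    gaussian_smooth,
    otsu_threshold,
)
from meaburst.spike_io import SpikeRecording
from meaburst.synthetic import SimulationConfig, simulate_well




class TestBinSpikes:
    def test_spike_at_zero_lands_in_bin_zero(self):
        rec = SpikeRecording("A1", {"R1C1": np.array([0.0])}, duration=1.0,
                             sampling_rate=1000.0)
        counts, _ = bin_spikes(rec, 0.002)
        assert counts[0, 0] == 1 and counts.sum() == 1

    def test_spike_at_bin_edge_goes_to_later_bin(self):
        rec = SpikeRecording("A1", {"R1C1": np.array([0.002])}, duration=1.0,
                             sampling_rate=1000.0)
        counts, _ = bin_spikes(rec, 0.002)
        assert counts[0, 1] == 1 and counts[0, 0] == 0

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        spikes = {f"E{i}": np.round(np.sort(rng.uniform(0, 10, 50)), 4) for i in range(4)}
        rec = SpikeRecording("A1", spikes, duration=10.0, sampling_rate=10000.0)
        counts, electrodes = bin_spikes(rec, 0.002)
        for i, e in enumerate(electrodes):
            assert counts[i].sum() == spikes[e].size


class TestGaussianSmooth:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(gaussian_smooth(x, 0.070, 0.002), x, atol=1e-12)

    def test_impulse_response_is_the_kernel(self):
        x = np.zeros(501)
        x[250] = 1.0
        y = gaussian_smooth(x, 0.070, 0.002)
        k = gaussian_kernel(0.070, 0.002)
        assert k.size == 35  # 70 ms window at 2 ms bins
        np.testing.assert_allclose(y[250 - 17: 250 + 18], k, atol=1e-12)
        assert abs(y.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(y, y[::-1], atol=1e-12)  # symmetric

    def test_matches_dense_convolution_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=300)
        k = gaussian_kernel(0.070, 0.002)
        half = (k.size - 1) // 2
        padded = np.concatenate([x[half:0:-1], x, x[-2:-2 - half:-1]])
        # dense matrix convolution, independent of np.convolve
        n = x.size
        M = np.zeros((n, padded.size))
        for i in range(n):
            M[i, i: i + k.size] = k[::-1]
        np.testing.assert_allclose(gaussian_smooth(x, 0.070, 0.002), M @ padded, atol=1e-9)


class TestCombineStandardized:
    def test_identical_electrodes_equal_resmoothed_zscore(self):
        rng = np.random.default_rng(2)
        sig = rng.poisson(1.0, 400).astype(float)
        sm = gaussian_smooth(sig, 0.070, 0.002)
        mat = np.vstack([sm, sm, sm])
        z = (sm - sm.mean()) / sm.std()
        expected = gaussian_smooth(z, 0.070, 0.002)
        np.testing.assert_allclose(
            combine_standardized(mat, 0.070, 0.002), expected, atol=1e-12)

    def test_silent_electrode_dropped(self):
        rng = np.random.default_rng(3)
        active = rng.normal(size=(15, 300)) + np.linspace(0, 1, 300)
        silent = np.zeros((1, 300))
        full = np.vstack([active, silent])
        np.testing.assert_allclose(
            combine_standardized(full, 0.070, 0.002),
            combine_standardized(active, 0.070, 0.002), atol=1e-12)

    def test_all_silent_raises(self):
        with pytest.raises(ValueError, match="no active electrodes"):
            combine_standardized(np.zeros((16, 100)), 0.070, 0.002)

    def test_combined_mean_near_zero_before_resmoothing(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(4, 500))
        z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
        assert abs(z.mean(axis=0).mean()) < 1e-9


class TestOtsu:
    def test_bimodal_threshold_separates_classes(self):
        signal = np.concatenate([np.zeros(900), np.full(100, 10.0)])
        t = otsu_threshold(signal)
        assert 0 < t < 10

    def test_constant_signal_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.ones(100))

    def test_matches_brute_force_on_random_signals(self):
        """600 random signals, up to 64 bins: identical threshold to the naive search."""
        rng = np.random.default_rng(5)
        for trial in range(600):
            n_bins = int(rng.integers(4, 65))
            kind = trial % 3
            if kind == 0:
                x = rng.normal(size=rng.integers(10, 300))
            elif kind == 1:
                x = np.concatenate([rng.normal(0, 1, 100), rng.normal(8, 1, 30)])
            else:
                x = rng.exponential(1.0, rng.integers(10, 200))
            if np.unique(x).size < 2:
                continue
            assert otsu_threshold(x, n_bins) == pytest.approx(
                brute_force_otsu(x, n_bins), abs=0), f"trial {trial}"

    def test_agrees_with_skimage_within_one_bin(self):
        """Independent library route: same criterion, different implementation.

        skimage reports the bin center where we report the upper edge of the
        lower class, so agreement is to within one bin width.
        """
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(10)
        for _ in range(50):
            x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1.5, 60)])
            bin_w = (x.max() - x.min()) / 256
            assert abs(otsu_threshold(x, 256) - threshold_otsu(x, nbins=256)) <= bin_w

    def test_affine_invariance_within_one_bin(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = rng.normal(size=200)
            a, b = float(rng.uniform(0.5, 3)), float(rng.uniform(-5, 5))
            t = otsu_threshold(x, 64)
            t2 = otsu_threshold(a * x + b, 64)
            bin_w = a * (x.max() - x.min()) / 64
            assert abs(t2 - (a * t + b)) <= bin_w + 1e-12


class TestDetectNetworkBursts:
    def test_silent_recording_raises_no_threshold(self):
        rec = SpikeRecording("A1", {f"E{i}": np.empty(0) for i in range(16)},
                             duration=10.0)
        with pytest.raises(ValueError):
            detect_network_bursts(rec)

    def test_planted_burst_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(7)
        spikes = {}
        for i in range(16):
            bg = np.sort(rng.uniform(0, 60, rng.poisson(0.1 * 60)))
            if i < 12:  # 12/16 electrodes at 100 Hz for 0.4 s
                burst = np.sort(rng.uniform(30.0, 30.4, 40))
                t = np.sort(np.concatenate([bg, burst]))
            else:
                t = bg
            spikes[f"E{i}"] = np.round(t * 12500) / 12500
        rec = SpikeRecording("A1", spikes, duration=60.0)
        bursts = detect_network_bursts(rec)
        assert len(bursts) == 1
        b = bursts[0]
        assert abs(b.start - 30.0) <= 0.070 and abs(b.end - 30.4) <= 0.070
        assert len(b.participating_electrodes) >= 12

    def test_low_participation_burst_rejected(self):
        rng = np.random.default_rng(8)
        spikes = {}
        for i in range(16):
            bg = np.sort(rng.uniform(0, 60, 12))
            if i < 2:  # only 2/16 electrodes join: below the 25% rule
                t = np.sort(np.concatenate([bg, np.sort(rng.uniform(30.0, 30.4, 40))]))
            else:
                t = bg
            spikes[f"E{i}"] = np.round(t * 12500) / 12500
        rec = SpikeRecording("A1", spikes, duration=60.0)
        assert detect_network_bursts(rec) == []

    def test_intervals_sorted_and_disjoint(self):
        for seed in range(5):
            rec, _ = simulate_well(SimulationConfig(seed=seed, duration=60.0,
                                                    frag_prob=0.4))
            bursts = detect_network_bursts(rec)
            for a, b in zip(bursts, bursts[1:]):
                assert a.end <= b.start

    def test_doubling_in_burst_rate_never_loses_planted_bursts(self):
        """Detection sensitivity is monotone in the in-burst firing rate.

        Counts alone are not monotone (a hotter well can merge two nearby
        supra-threshold runs into one interval), so the check is on recall of
        the planted bursts: every planted burst recovered at the low rate is
        still recovered after doubling the rate.
        """

        def recall(rec, truth):
            detected = detect_network_bursts(rec)
            hit = 0
            for s, e in truth.mains():
                for b in detected:
                    ov = min(e, b.end) - max(s, b.start)
                    if ov >= 0.5 * (e - s):
                        hit += 1
                        break
            return hit / max(len(truth.mains()), 1)

        for seed in range(3):
            low, t_low = simulate_well(SimulationConfig(seed=seed, duration=120.0,
                                                        in_burst_rate=30.0))
            high, t_high = simulate_well(SimulationConfig(seed=seed, duration=120.0,
                                                          in_burst_rate=60.0))
            assert recall(high, t_high) >= recall(low, t_low)


class TestClassifyFragmented:
    def test_short_burst_within_gap_is_fragment(self):
        bursts = [NetworkBurst(0, 0.5), NetworkBurst(1.0, 1.2)]
        out = classify_fragmented(bursts)
        assert out[0].klass == "main"
        assert out[1].klass == "fragment" and out[1].anchor == 0

    def test_isolated_short_burst_is_main(self):
        out = classify_fragmented([NetworkBurst(0, 0.5), NetworkBurst(1.8, 2.0)])
        assert [b.klass for b in out] == ["main", "main"]

    def test_fragments_chain_through_fragments(self):
        out = classify_fragmented(
            [NetworkBurst(0, 0.5), NetworkBurst(1.0, 1.2), NetworkBurst(2.2, 2.4)])
        assert [b.klass for b in out] == ["main", "fragment", "fragment"]
        assert [b.anchor for b in out] == [None, 0, 0]

    def test_gap_exactly_max_qualifies(self):
        out = classify_fragmented([NetworkBurst(0, 0.5), NetworkBurst(1.6, 1.8)])
        assert out[1].klass == "fragment"  # gap exactly 1.1 s, "no more than" => <=

    def test_duration_exactly_main_min_is_main(self):
        out = classify_fragmented([NetworkBurst(0, 0.5), NetworkBurst(1.0, 1.32)])
        assert out[1].klass == "main"  # 0.32 s not < 0.32 s

    def test_matches_left_to_right_oracle(self):
        """1200 random interval lists: identical labels and anchors."""
        rng = np.random.default_rng(9)
        for trial in range(1200):
            n = int(rng.integers(0, 25))
            starts = np.sort(rng.uniform(0, 60, n))
            intervals = []
            prev_end = 0.0
            for s in starts:
                s = max(s, prev_end + 1e-6)
                dur = float(rng.choice([rng.uniform(0.05, 0.31), rng.uniform(0.33, 2.0)]))
                intervals.append((s, s + dur))
                prev_end = s + dur
            got = [(b.start, b.end, b.klass, b.anchor)
                   for b in classify_fragmented([NetworkBurst(s, e) for s, e in intervals])]
            assert got == pytest.approx(oracle_classify(intervals)), f"trial {trial}"


class TestFragmentationPercentage:
    def test_no_fragments_is_zero(self):
        bursts = [NetworkBurst(i, i + 0.5, klass="main") for i in range(10)]
        assert fragmentation_percentage(bursts) == 0.0

    def test_half_fragments_is_fifty(self):
        bursts = [NetworkBurst(i, i + 0.5, klass="main") for i in range(5)]
        bursts += [NetworkBurst(10 + i, 10 + i + 0.2, klass="fragment") for i in range(5)]
        assert fragmentation_percentage(bursts) == 50.0

    def test_empty_is_missing(self):
        assert math.isnan(fragmentation_percentage([]))
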