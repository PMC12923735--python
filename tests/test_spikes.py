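"""Spike detection against ground truth, refractory QC boundary
behaviour, artifact invalidation, waveform features and FS/RS
classification."""

import numpy as np
import pytest
from scipy.stats import norm

from lfpkit import (ContinuousSignal, SpikeUnit, build_units,
                    classify_units, detect_spikes,
                    flag_cross_channel_artifacts, isi_histogram, qc_unit,
                    spike_counts_per_segment, waveform_features)
from lfpkit.spikes import estimate_noise_sd
from lfpkit.synth import (SpikeClassSpec, SpikePopSpec, gen_spikes,
                          gen_units, spike_template)


def unit_from_isis(isis_ms, fs=40000.0, duration=100.0):
    ts = np.concatenate(([0.0], np.cumsum(isis_ms))) * 1e-3
    wf = np.tile(spike_template(fs, 0.5, 0.3, 0.4), (len(ts), 1))
    return SpikeUnit("u", ts, wf, fs, duration)


class TestDetection:
    def test_recovers_ground_truth_spikes(self):
        hits = total = fp = 0
        dur = 20.0
        for seed in range(3):
            sig, truth = gen_spikes(SpikePopSpec(duration_s=dur), seed=seed)
            cands = detect_spikes(sig)
            units = build_units(cands, sig.fs, sig.duration_s)
            by_ch = {u.unit_id: u for u in units}
            for t in truth:
                det = by_ch[t["channel"]].timestamps
                used = np.zeros(len(det), bool)
                for ts in t["timestamps"]:
                    d = np.abs(det - ts)
                    i = d.argmin()
                    if d[i] < 5e-4 and not used[i]:
                        used[i] = True
                        hits += 1
                total += len(t["timestamps"])
                fp += (~used).sum()
        assert hits / total >= 0.99
        assert fp / (3 * 2 * dur) <= 1.0  # false detections per second

    def test_noise_crossing_rate_matches_analytic(self, rng):
        # iid Gaussian noise: downward crossings of -3 sigma occur at
        # fs * P(x[t-1] > thr > x[t]) per second, thinned by the dead time
        fs = 40000.0
        sig = ContinuousSignal(rng.standard_normal(int(10 * fs))[None, :],
                               fs)
        cands = detect_spikes(sig, sd_mult=3.0, dead_time_ms=1.0)
        p = norm.cdf(-3.0)
        raw_rate = fs * p * (1 - p)
        expected = raw_rate / (1 + raw_rate * 1e-3)  # dead-time thinning
        measured = len(cands) / 10.0
        assert measured == pytest.approx(expected, rel=0.25)

    def test_zero_signal_no_detections(self):
        sig = ContinuousSignal(np.zeros((1, 40000)), fs=40000.0)
        assert detect_spikes(sig) == []

    def test_mad_noise_estimate_robust_to_spikes(self, rng):
        x = rng.standard_normal(100000)
        x[::1000] -= 20.0  # large spikes
        assert estimate_noise_sd(x) == pytest.approx(1.0, rel=0.05)


class TestQc:
    def test_clean_unit_included(self):
        u = unit_from_isis([10.0] * 50)
        qc_unit(u)
        assert u.qc["refractory_violation_frac"] == 0.0
        assert u.qc["included"]

    def test_contaminated_unit_excluded(self):
        isis = [10.0] * 95 + [0.5] * 5  # 5% violations
        u = unit_from_isis(isis)
        qc_unit(u)
        assert u.qc["refractory_violation_frac"] == pytest.approx(0.05)
        assert not u.qc["included"]

    def test_boundary_exactly_at_tolerance_included(self):
        # 1 violation in 200 ISIs = 0.005: inclusive boundary
        isis = [10.0] * 199 + [0.5]
        u = unit_from_isis(isis)
        qc_unit(u, violation_tol=0.005)
        assert u.qc["refractory_violation_frac"] == pytest.approx(0.005)
        assert u.qc["included"]

    def test_single_spike_excluded_with_reason(self):
        u = SpikeUnit("u", np.array([1.0]),
                      spike_template(40000.0, 0.5, 0.3, 0.4)[None, :],
                      40000.0, 10.0)
        qc_unit(u)
        assert not u.qc["included"]
        assert "reason" in u.qc

    def test_qc_conservation(self):
        sig, _ = gen_spikes(SpikePopSpec(duration_s=10.0), seed=0)
        units = build_units(detect_spikes(sig), sig.fs, sig.duration_s)
        for u in units:
            qc_unit(u)
        included = [u for u in units if u.qc["included"]]
        excluded = [u for u in units if not u.qc["included"]]
        assert len(included) + len(excluded) == len(units)


class TestArtifacts:
    def _cands_at(self, times_by_channel):
        from lfpkit.spikes import SpikeCandidate

        wf = spike_template(40000.0, 0.5, 0.3, 0.4)
        return [SpikeCandidate(t, ch, wf.copy())
                for ch, times in times_by_channel.items() for t in times]

    def test_simultaneous_on_all_channels_flagged(self):
        cands = self._cands_at({f"ch{i}": [1.0] for i in range(8)})
        flag_cross_channel_artifacts(cands, min_channels=6)
        assert all(c.artifact for c in cands)

    def test_single_channel_unflagged(self):
        cands = self._cands_at({"ch0": [1.0, 2.0, 3.0]})
        flag_cross_channel_artifacts(cands, min_channels=6)
        assert not any(c.artifact for c in cands)

    def test_below_channel_threshold_unflagged(self):
        cands = self._cands_at({f"ch{i}": [1.0] for i in range(3)})
        flag_cross_channel_artifacts(cands, min_channels=6)
        assert not any(c.artifact for c in cands)


class TestWaveformFeatures:
    @pytest.mark.parametrize("ttp,hw,pvr", [
        (0.3, 0.2, 0.35), (0.5, 0.3, 0.4), (0.8, 0.5, 0.55)])
    def test_recovers_generative_parameters(self, ttp, hw, pvr):
        fs = 40000.0
        tmpl = spike_template(fs, ttp, hw, pvr)
        u = SpikeUnit("u", np.array([1.0, 2.0]), np.tile(tmpl, (2, 1)),
                      fs, 10.0)
        f = waveform_features(u)
        one_sample_ms = 1e3 / fs
        assert f["trough_to_peak_ms"] == pytest.approx(ttp,
                                                       abs=one_sample_ms)
        assert f["width_at_half_height_ms"] == pytest.approx(
            hw, abs=one_sample_ms)
        assert f["peak_valley_ratio"] == pytest.approx(pvr, rel=0.02)

    def test_scaling_homogeneity(self):
        fs = 40000.0
        tmpl = spike_template(fs, 0.5, 0.3, 0.4)
        u1 = SpikeUnit("a", np.array([1.0, 2.0]), np.tile(tmpl, (2, 1)),
                       fs, 10.0)
        u2 = SpikeUnit("b", np.array([1.0, 2.0]),
                       np.tile(2 * tmpl, (2, 1)), fs, 10.0)
        f1, f2 = waveform_features(u1), waveform_features(u2)
        assert f2["peak_valley_ratio"] == pytest.approx(
            f1["peak_valley_ratio"], rel=1e-9)
        assert f2["trough_peak_slope"] == pytest.approx(
            2 * f1["trough_peak_slope"], rel=1e-9)

    def test_exact_ratio_on_symmetric_template(self):
        # trough depth 100, post-trough peak 40: ratio 0.4 exactly
        fs = 40000.0
        w = np.zeros(80)
        w[20] = -100.0
        w[40] = 40.0
        u = SpikeUnit("u", np.array([1.0, 2.0]), np.tile(w, (2, 1)),
                      fs, 10.0)
        f = waveform_features(u)
        assert f["peak_valley_ratio"] == pytest.approx(0.4, rel=1e-12)

    def test_no_post_trough_peak_leaves_unit_unclassified(self):
        w = -np.exp(-0.5 * ((np.arange(80) - 40) / 5.0) ** 2)
        u = SpikeUnit("u", np.array([1.0, 2.0]), np.tile(w, (2, 1)),
                      40000.0, 10.0)
        f = waveform_features(u)
        assert "trough_to_peak_ms" not in f
        assert u.label == "unclassified"


class TestClassification:
    def test_two_population_accuracy(self):
        accs = []
        for seed in range(5):
            spec = SpikePopSpec(duration_s=60.0, classes=[
                SpikeClassSpec("FS", 20.0, 0.3, 0.2, 0.35, n_units=20),
                SpikeClassSpec("RS", 2.0, 0.8, 0.5, 0.55, n_units=20)])
            units, labels = gen_units(spec, seed)
            for u in units:
                qc_unit(u)
                waveform_features(u)
            units = classify_units(units, seed=seed)
            accs.append(np.mean([u.label == lab
                                 for u, lab in zip(units, labels)]))
        assert np.mean(accs) >= 0.95

    def test_deterministic_relabeling(self):
        spec = SpikePopSpec(duration_s=60.0, classes=[
            SpikeClassSpec("FS", 20.0, 0.3, 0.2, 0.35, n_units=10),
            SpikeClassSpec("RS", 2.0, 0.8, 0.5, 0.55, n_units=10)])
        units, _ = gen_units(spec, 1)
        for u in units:
            qc_unit(u)
            waveform_features(u)
        labels_a = [u.label for u in classify_units(units, seed=42)]
        labels_b = [u.label for u in classify_units(units, seed=42)]
        assert labels_a == labels_b

    def test_identical_units_flagged_low_confidence(self):
        fs = 40000.0
        tmpl = spike_template(fs, 0.5, 0.3, 0.4)
        units = [SpikeUnit(f"u{i}",
                           np.arange(1, 51) * 0.1 + i * 1e-5,
                           np.tile(tmpl, (50, 1)), fs, 10.0)
                 for i in range(6)]
        for u in units:
            qc_unit(u)
            waveform_features(u)
        units = classify_units(units, seed=0)
        # identical feature vectors: responsibilities near 0.5 or the fit
        # degenerates; units must carry a confidence flag either way
        assert all("label_confidence" in u.qc for u in units)

    def test_fewer_than_two_units_stay_unclassified(self):
        spec = SpikePopSpec(duration_s=30.0, classes=[
            SpikeClassSpec("FS", 20.0, 0.3, 0.2, 0.35, n_units=1)])
        units, _ = gen_units(spec, 0)
        for u in units:
            qc_unit(u)
            waveform_features(u)
        units = classify_units(units, seed=0)
        assert all(u.label == "unclassified" for u in units)


class TestIsiAndCounts:
    def test_regular_train_single_isi_bin(self):
        # ISI mid-bin so float round-off cannot straddle a bin edge
        u = unit_from_isis([100.5] * 30)
        h = isi_histogram(u, bin_ms=1.0, max_ms=200.0)
        assert h.counts.sum() == u.n_spikes - 1
        occupied = np.flatnonzero(h.counts)
        assert len(occupied) == 1
        assert h.bin_edges_ms[occupied[0]] == pytest.approx(100.0)

    def test_counts_sum_is_n_minus_one(self, rng):
        ts = np.sort(rng.uniform(0, 100, 500))
        u = SpikeUnit("u", ts, np.zeros((500, 80)), 40000.0, 100.0)
        h = isi_histogram(u)
        assert h.counts.sum() == 499

    def test_uniform_spikes_per_segment(self, rng):
        ts = np.sort(rng.uniform(0, 1500, 3000))
        u = SpikeUnit("u", ts, np.zeros((3000, 80)), 40000.0, 1500.0)
        counts = spike_counts_per_segment(u, 300.0)
        assert counts.sum() == 3000
        assert len(counts) == 5
        assert np.all(np.abs(counts - 600) <= 3 * np.sqrt(600))
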