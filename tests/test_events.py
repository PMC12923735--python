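"""Epileptiform criteria conjunction, ripple/fast-ripple detector
performance against injected ground truth, and event summaries."""

import numpy as np
import pytest

from lfpkit import (OscEvent, ValidationError, detect_band_events,
                    detect_epileptiform, detect_fast_ripples,
                    detect_ripples, exclude_overlapping, summarize_events)
from lfpkit.events import ConfigurationError, _largest_contiguous
from lfpkit.synth import EventSpec, LfpSpec, gen_lfp


def lfp_with_burst(duration_s=20.0, burst_s=2.0, channels=tuple(range(6)),
                   amplitude=6.0, carrier=150.0, seed=2, fs=1000.0):
    spec = LfpSpec(fs=fs, duration_s=duration_s,
                   events=[EventSpec("epileptiform", 5.0, burst_s, carrier,
                                     amplitude, channels)])
    return gen_lfp(spec, seed=seed)


def scattered_ripples(seed, kind="ripple", carrier=160.0, fs=1000.0,
                      n_events=20, duration=0.05, amplitude=5.0):
    rng = np.random.default_rng(seed)
    t_ons = np.sort(rng.uniform(1.0, 58.0, n_events))
    while np.any(np.diff(t_ons) < 0.3):
        t_ons = np.sort(rng.uniform(1.0, 58.0, n_events))
    events = [EventSpec(kind, float(t), duration, carrier, amplitude, (0,))
              for t in t_ons]
    sig, truth = gen_lfp(LfpSpec(fs=fs, duration_s=60.0, events=events),
                         seed=seed)
    return sig, t_ons


class TestEpileptiform:
    def test_valid_burst_detected_once(self):
        sig, _ = lfp_with_burst()
        evs = detect_epileptiform(sig)
        assert len(evs) == 1
        assert evs[0].duration_s == pytest.approx(2.0, abs=0.1)
        assert len(evs[0].channels) == 6
        assert evs[0].intra_freq_hz == pytest.approx(150.0, abs=5.0)

    def test_overlong_burst_rejected_by_duration_criterion(self):
        sig, _ = lfp_with_burst(burst_s=5.0)
        assert detect_epileptiform(sig) == []

    def test_few_channel_burst_rejected_by_contiguity_criterion(self):
        sig, _ = lfp_with_burst(channels=(0, 1, 2))
        assert detect_epileptiform(sig) == []

    def test_noncontiguous_channels_rejected(self):
        # 5 channels but split 3+2 across the array: largest contiguous
        # group is 3 < 5
        sig, _ = lfp_with_burst(channels=(0, 1, 2, 5, 6))
        assert detect_epileptiform(sig) == []

    def test_raising_threshold_never_increases_count(self):
        sig, _ = lfp_with_burst()
        counts = [len(detect_epileptiform(sig, sd_mult=k))
                  for k in (4.0, 5.0, 6.0, 8.0, 12.0, 20.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_criteria_are_conjunctive(self):
        # relaxing any single criterion can only grow the detected set
        sig, _ = lfp_with_burst(burst_s=5.0)
        assert len(detect_epileptiform(sig, max_duration_s=10.0)) >= 1
        sig3, _ = lfp_with_burst(channels=(0, 1, 2))
        assert len(detect_epileptiform(sig3, min_channels_contig=3)) >= 1

    def test_missing_geometry_is_configuration_error(self):
        sig, _ = lfp_with_burst()
        sig.geometry = []
        with pytest.raises(ConfigurationError):
            detect_epileptiform(sig)

    def test_largest_contiguous_subgraph(self):
        adj = {"a": {"b"}, "b": {"a", "c"}, "c": {"b"}, "d": set()}
        assert _largest_contiguous({"a", "b", "c", "d"}, adj) == 3
        assert _largest_contiguous({"a", "c", "d"}, adj) == 1


class TestBandEvents:
    @pytest.mark.parametrize("kind,carrier,fs,detector", [
        ("ripple", 160.0, 1000.0, detect_ripples),
        ("fast_ripple", 300.0, 2000.0, detect_fast_ripples),
    ])
    def test_sensitivity_precision_onset_frequency(self, kind, carrier, fs,
                                                   detector):
        n_hit = n_fp = 0
        onset_errs, freq_errs = [], []
        for seed in range(5):
            sig, t_ons = scattered_ripples(seed, kind, carrier, fs)
            det = detector(sig)
            matched = set()
            for d in det:
                hit = None
                for i, t in enumerate(t_ons):
                    if i not in matched and abs(d.t_on - t) < 0.05:
                        hit = i
                        break
                if hit is None:
                    n_fp += 1
                else:
                    matched.add(hit)
                    onset_errs.append(abs(d.t_on - t_ons[hit]))
                    freq_errs.append(abs(d.intra_freq_hz - carrier))
            n_hit += len(matched)
        n_true = 5 * 20
        assert n_hit / n_true >= 0.95
        assert n_hit / max(n_hit + n_fp, 1) >= 0.90
        assert max(onset_errs) <= 0.010
        assert np.mean(freq_errs) <= 5.0

    def test_amplitude_scaling_scales_peak_not_count(self):
        sig1, _ = scattered_ripples(3, amplitude=5.0)
        sig2, _ = scattered_ripples(3, amplitude=10.0)
        d1, d2 = detect_ripples(sig1), detect_ripples(sig2)
        assert len(d1) == len(d2)
        p1 = np.mean([e.peak_amplitude for e in d1])
        p2 = np.mean([e.peak_amplitude for e in d2])
        assert p2 / p1 == pytest.approx(2.0, rel=0.10)

    def test_false_positive_rate_on_pure_noise(self):
        rates = []
        for seed in range(10):
            sig, _ = gen_lfp(LfpSpec(duration_s=60.0), seed=seed + 100)
            rates.append(len(detect_ripples(sig)) / 1.0)  # events/min
        assert np.mean(rates) <= 2.0

    def test_threshold_monotonicity(self):
        sig, _ = scattered_ripples(4)
        counts = [len(detect_ripples(sig, envelope_sd_mult=k))
                  for k in (2.0, 3.0, 5.0, 8.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_band_above_nyquist_rejected(self):
        sig, _ = gen_lfp(LfpSpec(duration_s=5.0), seed=0)
        with pytest.raises(ValidationError):
            detect_fast_ripples(sig)  # 500 Hz band at fs 1000

    def test_exclude_overlapping(self):
        ev = [OscEvent("ripple", 1.0, 1.1), OscEvent("ripple", 5.0, 5.1)]
        excl = [OscEvent("epileptiform", 0.9, 1.5)]
        kept = exclude_overlapping(ev, excl)
        assert [e.t_on for e in kept] == [5.0]


class TestSummaries:
    def test_rate_arithmetic(self):
        evs = [OscEvent("epileptiform", 300.0 * i + 1, 300.0 * i + 2)
               for i in range(12)]
        s = summarize_events(evs, recording_duration_s=3600.0)
        assert s.event_rate_per_min == pytest.approx(0.2)
        assert s.per_segment_counts == [1] * 12

    def test_empty_events(self):
        s = summarize_events([], 600.0)
        assert s.n_events == 0 and s.event_rate_per_min == 0.0
        assert s.mean_duration_s is None
        assert s.mean_intra_freq_hz is None

    def test_mean_duration(self):
        evs = [OscEvent("ripple", 0.0, 1.0), OscEvent("ripple", 2.0, 4.0),
               OscEvent("ripple", 5.0, 8.0)]
        s = summarize_events(evs, 60.0)
        assert s.mean_duration_s == pytest.approx(2.0)

    def test_short_final_segment_rate_normalised(self):
        evs = [OscEvent("ripple", 310.0, 311.0)]
        s = summarize_events(evs, recording_duration_s=360.0)
        # second segment is only 60 s long: 1 event/min
        assert s.per_segment_rates_per_min[1] == pytest.approx(1.0)
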