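"""Beat detection, rates, amplitudes and synchrony against simulated truth."""

import numpy as np
import pytest

import needlebeat as nb
from conftest import run_pipeline
from needlebeat.beat_analysis import (
    BeatDetectionConfig,
    amplitude_summary,
    beating_rate,
    detect_beats,
    summarize,
    sync_index,
)
from needlebeat.core import Beat, DisplacementTrace


def _beat(t, amp=8.0):
    return Beat(peak_time=t, peak_amplitude=amp, onset_time=t - 0.1, relax_time=t + 0.2)


class TestDetectBeats:
    def test_flat_trace_yields_no_beats(self):
        trace = DisplacementTrace(needle_id=0, fps=30.0, d=np.zeros(300), reference=(0, 0))
        assert detect_beats(trace) == []

    def test_paced_2hz_with_noise_gives_twenty_beats(self, paced_2hz_run):
        beats = detect_beats(paced_2hz_run.traces[0])
        assert len(beats) == 20

    def test_spontaneous_0p6hz_gives_six_beats(self):
        trace, gt = nb.simulate_trace(nb.TwitchModel(rate=0.6), 10.0, 30.0, seed=0)
        beats = detect_beats(trace)
        assert gt.n_beats == 6
        assert len(beats) == 6

    def test_refractory_no_peaks_closer_than_min_interbeat(self, paced_2hz_run):
        config = BeatDetectionConfig()
        beats = detect_beats(paced_2hz_run.traces[0], config)
        gaps = np.diff([b.peak_time for b in beats])
        assert np.all(gaps >= config.min_interbeat - 1e-9)

    def test_onset_precedes_peak_and_relax_follows(self, paced_1hz_run):
        for b in detect_beats(paced_1hz_run.traces[0]):
            assert b.onset_time <= b.peak_time <= b.relax_time

    def test_short_gaps_interpolated_long_gaps_split(self):
        trace, _ = nb.simulate_trace(nb.TwitchModel().paced(1.0), 10.0, 30.0, seed=0)
        d = trace.d.copy()
        d[40:42] = np.nan  # 2-frame dropout: interpolated away
        short = DisplacementTrace(needle_id=0, fps=30.0, d=d, reference=(0, 0))
        assert len(detect_beats(short)) == 10
        d2 = trace.d.copy()
        d2[100:160] = np.nan  # 2 s dropout spanning two beats: segments analysed apart
        split = DisplacementTrace(needle_id=0, fps=30.0, d=d2, reference=(0, 0))
        n = len(detect_beats(split))
        assert 7 <= n <= 9  # the beats inside the gap are gone, the rest survive

    def test_rate_recovery_grid_exact(self):
        """Full-pipeline beat counts match ground truth over rates x noise.

        Ground truth is the number of onsets visible in the sampled recording
        (an onset after the final frame produces no signal). Every cell must
        match exactly, and raw onset counts are never missed by more than 1.
        """
        mismatches = 0
        for rate in [0.3, 0.6, 0.8, 1.0, 2.0]:
            for noise in [0.0, 2.0, 5.0]:
                seed = int(1000 * rate + noise)
                run = run_pipeline([nb.TwitchModel(rate=rate)], noise_sigma=noise, seed=seed)
                n_detected = len(detect_beats(run.traces[0]))
                if n_detected != run.visible_onsets[0]:
                    mismatches += 1
                assert abs(n_detected - run.truths[0].n_beats) <= 1
        assert mismatches == 0

    def test_beat_count_invariant_to_frame_rate(self):
        """Beat counts agree between 30 and 60 fps renderings (rates <= 2 Hz)."""
        for freq in [1.0, 2.0]:
            counts = []
            for fps in [30.0, 60.0]:
                run = run_pipeline([nb.TwitchModel().paced(freq)], noise_sigma=2.0, seed=5, fps=fps)
                counts.append(len(detect_beats(run.traces[0])))
            assert counts[0] == counts[1]

    def test_recovered_amplitude_monotone_in_true_amplitude(self):
        """Mean recovered amplitude increases with true amplitude {2,4,8,16} px."""
        means = []
        for amp in [2.0, 4.0, 8.0, 16.0]:
            run = run_pipeline(
                [nb.TwitchModel(amplitude=amp).paced(0.8)], noise_sigma=2.0, seed=3
            )
            mean, _ = amplitude_summary(detect_beats(run.traces[0]))
            means.append(mean)
        assert all(a < b for a, b in zip(means, means[1:]))


class TestBeatingRate:
    def test_ten_beats_in_ten_seconds(self):
        beats = [_beat(t + 0.5) for t in range(10)]
        assert beating_rate(beats, (0.0, 10.0)) == 10.0

    def test_empty_list_is_zero(self):
        assert beating_rate([], (0.0, 10.0)) == 0.0

    def test_linear_rescaling_to_10s(self):
        beats = [_beat(1.0), _beat(2.5), _beat(4.0)]
        assert beating_rate(beats, (0.0, 5.0)) == pytest.approx(6.0)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            beating_rate([], (5.0, 5.0))


class TestAmplitudeSummary:
    def test_constant_amplitudes(self):
        mean, cv = amplitude_summary([_beat(1), _beat(2), _beat(3)])
        assert (mean, cv) == (8.0, 0.0)

    def test_recovers_simulated_amplitude_within_ten_percent(self, paced_1hz_run):
        mean, cv = amplitude_summary(detect_beats(paced_1hz_run.traces[0]))
        assert mean == pytest.approx(8.0, rel=0.10)
        assert cv < 0.2

    def test_2hz_pacing_reduces_per_beat_amplitude(self, paced_1hz_run, paced_2hz_run):
        """Incomplete relaxation at 2 Hz lowers the local-trough amplitude."""
        mean_1hz, _ = amplitude_summary(detect_beats(paced_1hz_run.traces[0]))
        mean_2hz, _ = amplitude_summary(detect_beats(paced_2hz_run.traces[0]))
        assert mean_2hz < mean_1hz

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="no beats"):
            amplitude_summary([])


class TestSyncIndex:
    def test_identical_beat_times_give_one(self):
        lists = [[_beat(t) for t in (1.0, 2.0, 3.0)] for _ in range(4)]
        assert sync_index(lists) == 1.0

    def test_mixed_rates_random_phases_below_one(self):
        rng = np.random.default_rng(2)
        lists = []
        for f in [1.0, 1.0, 0.8, 0.8]:
            phase = rng.uniform(0, 1 / f)
            lists.append([_beat(phase + k / f) for k in range(int(10 * f))])
        assert sync_index(lists) < 1.0

    def test_infinite_tolerance_with_beats_everywhere_gives_one(self):
        lists = [[_beat(1.0), _beat(5.0)], [_beat(2.0), _beat(9.0)]]
        assert sync_index(lists, tolerance=np.inf) == 1.0

    def test_zero_beat_needle_contributes_zero(self):
        lists = [[_beat(1.0)], []]
        assert sync_index(lists) == 0.0

    def test_needs_two_needles(self):
        with pytest.raises(ValueError):
            sync_index([[_beat(1.0)]])


class TestSummarize:
    def test_four_needle_rates_match_ground_truth(self, four_needle_run):
        run = four_needle_run
        summary = summarize(run.traces)
        rates = {s.needle_id: s.beats_per_10s for s in summary.per_needle}
        for nid, gt in enumerate(run.truths):
            assert rates[nid] == gt.n_beats
        assert summary.sync_index is not None and summary.sync_index < 1.0

    def test_single_flat_trace_rate_zero_no_sync(self):
        trace = DisplacementTrace(needle_id=0, fps=30.0, d=np.zeros(300), reference=(0, 0))
        summary = summarize([trace])
        assert summary.per_needle[0].beats_per_10s == 0.0
        assert summary.sync_index is None

    def test_mismatched_lengths_rejected(self):
        a = DisplacementTrace(needle_id=0, fps=30.0, d=np.zeros(300), reference=(0, 0))
        b = DisplacementTrace(needle_id=1, fps=30.0, d=np.zeros(200), reference=(0, 0))
        with pytest.raises(ValueError, match="share fps and length"):
            summarize([a, b])
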