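"""Beat detection, beating rate per 10 s, amplitudes, and synchronization.

Displacement traces are lightly smoothed (moving average, default 0.1 s), then
peaks are picked by prominence with a refractory spacing of ``min_interbeat``
seconds (default 0.2 s, admitting pacing up to ~4 Hz with margin). The
prominence threshold defaults to "auto": 20% of the robust (5th-95th
percentile) displacement range, floored at a small absolute value so a flat or
noise-only trace yields zero beats rather than spurious ones. This ties the
beat criterion to each trace's own excursion, so a myosin-inhibitor-like
amplitude loss shrinks measured amplitude without dropping the beat count
until the signal nears the noise floor.

Per-beat amplitude is the peak value minus the higher of the two flanking
troughs — measured against local troughs rather than the global rest position,
so incomplete relaxation under fast pacing shows up as a reduced per-beat
excursion. Onset and relaxation times are the 10%-of-amplitude crossings on
the rising and falling flanks.

Short gaps of missing samples (< 3 frames) are linearly interpolated before
smoothing; longer gaps split the trace into independently analysed segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import ArraySummary, Beat, ContractionSummary, DisplacementTrace

__all__ = [
    "BeatDetectionConfig",
    "detect_beats",
    "beating_rate",
    "amplitude_summary",
    "sync_index",
    "summarize",
]

#: Gaps of this many frames or more split the trace instead of interpolating.
MAX_INTERP_GAP = 3


@dataclass
class BeatDetectionConfig:
    """Parameters of the peak-picking beat detector.

    ``min_prominence=None`` selects the auto threshold: ``auto_fraction`` of
    the 5th-95th percentile displacement range, but at least
    ``min_prominence_floor`` pixels (the noise floor guard).
    ``amplitude_mode`` is ``"local-trough"`` (peak minus the higher flanking
    trough) or ``"above-rest"`` (peak displacement itself).

    ``count_edge_beats`` counts a contraction still rising when the recording
    ends: if the trace's final value exceeds the minimum since the last
    detected peak by at least the prominence threshold, one beat is added with
    its peak at the final sample. Without it, beats whose peak falls just past
    the last frame are silently dropped from rate counts.
    """

    smoothing_window: float = 0.1  # s
    min_prominence: float | None = None  # px; None = auto
    auto_fraction: float = 0.2
    min_prominence_floor: float = 0.5  # px
    min_interbeat: float = 0.2  # s
    amplitude_mode: str = "local-trough"
    count_edge_beats: bool = True

    def __post_init__(self) -> None:
        if not self.min_interbeat > 0:
            raise ValueError("min_interbeat must be > 0")
        if self.smoothing_window < 0:
            raise ValueError("smoothing_window must be >= 0")
        if self.amplitude_mode not in {"local-trough", "above-rest"}:
            raise ValueError(f"unknown amplitude_mode {self.amplitude_mode!r}")


def _moving_average(d: np.ndarray, window_frames: int) -> np.ndarray:
    if window_frames <= 1:
        return d
    kernel = np.ones(window_frames) / window_frames
    # reflect-pad so the smoothed trace keeps its length and edge behaviour
    pad = window_frames // 2
    padded = np.pad(d, pad_width=(pad, window_frames - 1 - pad), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _fill_short_gaps(d: np.ndarray, max_gap: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Interpolate NaN runs shorter than ``max_gap``; return segments around longer ones."""
    d = d.copy()
    isnan = np.isnan(d)
    if not isnan.any():
        return d, [(0, len(d))]
    # identify NaN runs
    edges = np.diff(isnan.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if isnan[0]:
        starts.insert(0, 0)
    if isnan[-1]:
        ends.append(len(d))
    long_runs = []
    for s, e in zip(starts, ends):
        if e - s < max_gap and 0 < s and e < len(d):
            d[s:e] = np.interp(np.arange(s, e), [s - 1, e], [d[s - 1], d[e]])
        else:
            long_runs.append((s, e))
    segments = []
    prev = 0
    for s, e in long_runs:
        if s - prev > 0:
            segments.append((prev, s))
        prev = e
    if len(d) - prev > 0:
        segments.append((prev, len(d)))
    return d, segments


def _beats_in_segment(
    d: np.ndarray,
    fps: float,
    t_offset: float,
    config: BeatDetectionConfig,
    at_trace_end: bool = False,
) -> list[Beat]:
    if len(d) < 3:
        return []
    window_frames = max(1, int(round(config.smoothing_window * fps)))
    smooth = _moving_average(d, window_frames)

    if config.min_prominence is not None:
        prominence = config.min_prominence
    else:
        lo, hi = np.percentile(smooth, [5, 95])
        prominence = max(config.auto_fraction * (hi - lo), config.min_prominence_floor)

    distance = max(1, int(round(config.min_interbeat * fps)))
    peaks, _ = find_peaks(smooth, prominence=prominence, distance=distance)

    beats: list[Beat] = []
    for i, p in enumerate(peaks):
        left_lo = peaks[i - 1] if i > 0 else 0
        right_hi = peaks[i + 1] if i + 1 < len(peaks) else len(smooth) - 1
        left_trough = left_lo + int(np.argmin(smooth[left_lo : p + 1]))
        right_trough = p + int(np.argmin(smooth[p : right_hi + 1]))
        peak_val = smooth[p]
        lt, rt = smooth[left_trough], smooth[right_trough]
        if config.amplitude_mode == "above-rest":
            amplitude = float(peak_val)
        else:
            amplitude = float(peak_val - max(lt, rt))
        if amplitude <= 0:
            continue

        # onset: last 10%-of-rise crossing before the peak
        rise_level = lt + 0.1 * (peak_val - lt)
        onset_idx = left_trough
        seg = smooth[left_trough : p + 1]
        below = np.flatnonzero(seg <= rise_level)
        if below.size:
            onset_idx = left_trough + int(below[-1])
        # relax: first 10%-of-fall crossing after the peak, else the trough
        fall_level = rt + 0.1 * (peak_val - rt)
        relax_idx = right_trough
        seg = smooth[p : right_trough + 1]
        under = np.flatnonzero(seg <= fall_level)
        if under.size:
            relax_idx = p + int(under[0])

        beats.append(
            Beat(
                peak_time=t_offset + p / fps,
                peak_amplitude=amplitude,
                onset_time=t_offset + onset_idx / fps,
                relax_time=t_offset + relax_idx / fps,
            )
        )

    if config.count_edge_beats and at_trace_end:
        edge = _edge_beat(smooth, fps, t_offset, peaks, prominence, distance, config)
        if edge is not None:
            beats.append(edge)
    return beats


def _edge_beat(
    smooth: np.ndarray,
    fps: float,
    t_offset: float,
    peaks: np.ndarray,
    prominence: float,
    distance: int,
    config: BeatDetectionConfig,
) -> Beat | None:
    """A contraction still rising at the end of the recording.

    Counted when the final value exceeds the post-last-peak minimum by the
    prominence threshold, at least ``min_interbeat`` after the last peak; its
    peak is placed at the final sample (no relaxation observed).
    """
    last = len(smooth) - 1
    tail_start = int(peaks[-1]) + 1 if len(peaks) else 0
    if last - tail_start < 2 or (len(peaks) and last - peaks[-1] < distance):
        return None
    tail = smooth[tail_start:]
    trough_rel = int(np.argmin(tail))
    trough_val = float(tail[trough_rel])
    rise = float(smooth[last] - trough_val)
    if rise < prominence:
        return None
    trough_idx = tail_start + trough_rel
    rise_level = trough_val + 0.1 * rise
    below = np.flatnonzero(smooth[trough_idx : last + 1] <= rise_level)
    onset_idx = trough_idx + int(below[-1]) if below.size else trough_idx
    peak_val = float(smooth[last])
    amplitude = peak_val if config.amplitude_mode == "above-rest" else rise
    return Beat(
        peak_time=t_offset + last / fps,
        peak_amplitude=amplitude,
        onset_time=t_offset + onset_idx / fps,
        relax_time=t_offset + last / fps,
    )


def detect_beats(trace: DisplacementTrace, config: BeatDetectionConfig | None = None) -> list[Beat]:
    """Detect contraction events on one displacement trace.

    A flat trace (range below the noise floor) yields an empty list, not an
    error. Returns beats ordered by peak time.
    """
    config = config or BeatDetectionConfig()
    d, segments = _fill_short_gaps(trace.d, MAX_INTERP_GAP)
    beats: list[Beat] = []
    for s, e in segments:
        seg = d[s:e]
        if np.isnan(seg).any():  # boundary gaps that could not be interpolated
            keep = ~np.isnan(seg)
            first = int(np.argmax(keep)) if keep.any() else 0
            last = len(seg) - int(np.argmax(keep[::-1])) if keep.any() else 0
            seg = seg[first:last]
            s += first
            if np.isnan(seg).any() or len(seg) == 0:
                continue
        at_end = s + len(seg) == trace.n_frames
        beats.extend(_beats_in_segment(seg, trace.fps, s / trace.fps, config, at_end))
    return sorted(beats, key=lambda b: b.peak_time)


def beating_rate(beats: list[Beat], window: tuple[float, float]) -> float:
    """Beat count in ``[t0, t1)`` rescaled to a 10 s window."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed start")
    count = sum(1 for b in beats if t0 <= b.peak_time < t1)
    return count * 10.0 / (t1 - t0)


def amplitude_summary(beats: list[Beat]) -> tuple[float, float]:
    """Mean and coefficient of variation of per-beat amplitudes.

    Raises on an empty beat list — the caller decides whether no beats mean
    amplitude 0 (contraction arrest) or an error.
    """
    if not beats:
        raise ValueError("no beats: amplitude summary undefined")
    amps = np.array([b.peak_amplitude for b in beats])
    mean = float(amps.mean())
    cv = float(amps.std(ddof=0) / mean) if mean > 0 else 0.0
    return mean, cv


def sync_index(beat_lists: list[list[Beat]], tolerance: float = 0.15) -> float:
    """Fraction of beats co-occurring across needles within ``tolerance`` s.

    For every ordered needle pair (i, j) the score is the fraction of i's
    beats with a beat on j within +/- tolerance; the index is the mean over
    pairs. 1.0 iff all beats co-occur; a needle with zero beats contributes 0
    to its pairs.
    """
    n = len(beat_lists)
    if n < 2:
        raise ValueError("sync_index needs at least two needles")
    times = [np.array([b.peak_time for b in beats]) for beats in beat_lists]
    scores = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if len(times[i]) == 0 or len(times[j]) == 0:
                scores.append(0.0)
                continue
            matched = sum(1 for t in times[i] if np.min(np.abs(times[j] - t)) <= tolerance)
            scores.append(matched / len(times[i]))
    return float(np.mean(scores))


def summarize(
    traces: list[DisplacementTrace],
    config: BeatDetectionConfig | None = None,
    window: tuple[float, float] | None = None,
    sync_tolerance: float = 0.15,
) -> ArraySummary:
    """Per-needle rates and amplitudes plus the cross-needle sync index.

    All traces must share fps and length. ``window`` defaults to the full
    recording; rates are rescaled to a 10 s window. The sync index is omitted
    for single-needle input.
    """
    if not traces:
        raise ValueError("summarize needs at least one trace")
    fps = traces[0].fps
    n = traces[0].n_frames
    for tr in traces[1:]:
        if tr.fps != fps or tr.n_frames != n:
            raise ValueError("all traces must share fps and length")
    if window is None:
        window = (0.0, n / fps)

    config = config or BeatDetectionConfig()
    per_needle = []
    windowed_beats = []
    for tr in traces:
        beats = [b for b in detect_beats(tr, config) if window[0] <= b.peak_time < window[1]]
        windowed_beats.append(beats)
        if beats:
            mean_amp, cv = amplitude_summary(beats)
        else:
            mean_amp, cv = 0.0, 0.0
        per_needle.append(
            ContractionSummary(
                window=window,
                beats_per_10s=beating_rate(beats, window),
                mean_peak_amplitude=mean_amp,
                amplitude_cv=cv,
                needle_id=tr.needle_id,
            )
        )
    sync = sync_index(windowed_beats, sync_tolerance) if len(traces) >= 2 else None
    return ArraySummary(window=window, per_needle=per_needle, sync_index=sync)
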