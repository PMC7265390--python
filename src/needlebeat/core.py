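"""Domain types, units and coordinate conventions.

Conventions used throughout the package:

* pixel coordinates, origin at the top-left corner, x rightward, y downward;
* 0-based frame indices; time ``t = frame_index / fps`` in seconds;
* displacements are Euclidean distances from a resting reference position and
  are therefore non-negative;
* missing tip detections are represented explicitly as NaN positions, never
  silently interpolated (interpolation is an opt-in step in beat analysis);
* time is stored in seconds everywhere; hour-scale toxicity timepoints are
  converted at the boundary (see :mod:`needlebeat.response`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "TipTrack",
    "DisplacementTrace",
    "Beat",
    "ContractionSummary",
    "ArraySummary",
    "StimulationProtocol",
    "TimePoint",
    "ConditionTimeCourse",
    "MISSING",
]

#: Marker used for missing tip detections in position/confidence arrays.
MISSING = np.nan

# Tolerance for the pulse-schedule invariant pulse_width + gap == period (ms).
_PROTOCOL_ATOL_MS = 1e-6


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames with a frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, 8- or 16-bit grayscale
        (or float for intermediate synthetic data).
    fps
        Frames per second (Hz), strictly positive.
    pixel_size_um
        Optional physical pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width); got shape {self.frames.shape}"
            )
        if len(self.frames) < 1:
            raise ValueError("a FrameStack needs at least one frame")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds (frame_index / fps)."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class TipTrack:
    """Per-frame tip coordinates for one needle.

    ``positions`` has shape ``(n_frames, 2)`` holding (x, y) in pixels; missing
    detections are NaN rows. ``confidence`` holds per-frame match scores in
    [0, 1] (0 for missing frames). ``warnings`` collects tracking-quality
    messages, e.g. when more than 25% of frames are missing.
    """

    needle_id: int
    positions: np.ndarray
    confidence: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if len(self.confidence) != len(self.positions):
            raise ValueError("confidence length must equal positions length")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of frames with no accepted detection."""
        return np.isnan(self.positions).any(axis=1)

    @property
    def fraction_missing(self) -> float:
        return float(self.missing.mean())


@dataclass
class DisplacementTrace:
    """Per-frame scalar displacement of one needle tip from its rest position.

    ``d`` is the Euclidean distance (pixels) from ``reference`` at each frame;
    entries are non-negative, with NaN marking frames where the tip was not
    detected.
    """

    needle_id: int
    fps: float
    d: np.ndarray
    reference: tuple[float, float]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 1:
            raise ValueError("d must be a 1-D array")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        finite = self.d[np.isfinite(self.d)]
        if finite.size and finite.min() < 0:
            raise ValueError("displacements must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.d)

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class Beat:
    """One detected contraction event on a displacement trace.

    ``peak_amplitude`` is the per-beat "top movement": the peak displacement
    minus the higher of the two flanking troughs (pixels). ``onset_time`` and
    ``relax_time`` are the 10%-of-amplitude crossing times on the rising and
    falling flanks.
    """

    peak_time: float
    peak_amplitude: float
    onset_time: float
    relax_time: float

    def __post_init__(self) -> None:
        if self.onset_time > self.peak_time:
            raise ValueError("onset_time must be <= peak_time")
        if not self.peak_amplitude > 0:
            raise ValueError("peak_amplitude must be > 0")


@dataclass
class ContractionSummary:
    """Windowed contraction metrics for one needle (or a whole array).

    ``beats_per_10s`` is the beat count rescaled to a 10 s window — the
    beating-rate unit used for these constructs. ``sync_index`` is only
    populated on multi-needle summaries.
    """

    window: tuple[float, float]
    beats_per_10s: float
    mean_peak_amplitude: float
    amplitude_cv: float
    needle_id: int | None = None
    sync_index: float | None = None

    def __post_init__(self) -> None:
        if self.beats_per_10s < 0:
            raise ValueError("beats_per_10s must be >= 0")
        if self.sync_index is not None and not 0.0 <= self.sync_index <= 1.0:
            raise ValueError("sync_index must lie in [0, 1]")


@dataclass
class ArraySummary:
    """Per-needle summaries plus the cross-needle synchronization index."""

    window: tuple[float, float]
    per_needle: list[ContractionSummary]
    sync_index: float | None

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "sync_index": self.sync_index,
            "per_needle": [
                {
                    "needle_id": s.needle_id,
                    "beats_per_10s": s.beats_per_10s,
                    "mean_peak_amplitude": s.mean_peak_amplitude,
                    "amplitude_cv": s.amplitude_cv,
                }
                for s in self.per_needle
            ],
        }


@dataclass(frozen=True)
class StimulationProtocol:
    """Field-stimulation pacing parameters.

    The invariant ``pulse_width + inter_pulse_gap == 1000 / frequency`` (all in
    ms) is enforced on construction: e.g. 1 Hz / 10 ms pulses repeat every
    990 ms, 2 Hz / 10 ms pulses every 490 ms.
    """

    voltage: float
    pulse_width: float
    frequency: float
    inter_pulse_gap: float

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if self.pulse_width < 0:
            raise ValueError("pulse_width must be >= 0")
        period_ms = 1000.0 / self.frequency
        if abs(self.pulse_width + self.inter_pulse_gap - period_ms) > _PROTOCOL_ATOL_MS:
            raise ValueError(
                "pulse_width + inter_pulse_gap must equal 1000/frequency ms "
                f"({self.pulse_width} + {self.inter_pulse_gap} != {period_ms})"
            )

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency


@dataclass
class TimePoint:
    """One entry of a condition time course (all times in seconds)."""

    label: str
    time_s: float
    beats_per_10s: float
    mean_amplitude_px: float | None
    normalized_amplitude: float


@dataclass
class ConditionTimeCourse:
    """Baseline-normalized amplitude and rate across a protocol.

    The baseline timepoint has ``normalized_amplitude == 1.0`` by
    construction; a timepoint with no beats maps to normalized amplitude 0
    (contraction arrest).
    """

    timepoints: list[TimePoint]

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValueError("a time course needs at least one timepoint")

    @property
    def labels(self) -> list[str]:
        return [tp.label for tp in self.timepoints]

    @property
    def normalized_amplitudes(self) -> np.ndarray:
        return np.array([tp.normalized_amplitude for tp in self.timepoints])

    @property
    def times(self) -> np.ndarray:
        return np.array([tp.time_s for tp in self.timepoints])


def hours_to_seconds(hours: float | Sequence[float]) -> np.ndarray | float:
    """Convert hour-scale timepoints (e.g. 1/24/72 h toxicity) to seconds."""
    return np.asarray(hours, dtype=float) * 3600.0 if np.ndim(hours) else float(hours) * 3600.0
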