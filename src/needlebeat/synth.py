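"""Synthetic twitch waveforms, displacement traces and rendered needle-array videos.

The generator emulates the recorded views of a needle array carrying a beating
cardiac construct: bright needle tips on a dark background, horizontal tip
deflection following cardiac twitch kinetics, additive pixel noise and optional
baseline drift. Every stage carries its ground truth (beat onsets, per-frame
displacements) so detection, tracking and beat analysis can be validated
end-to-end without real recordings.

The twitch kernel is a difference of exponentials with a fast contraction and a
slow relaxation time constant, rescaled so its maximum equals the requested
amplitude. Beat onsets come either from a pacing schedule (one beat per pulse,
1:1 capture) or from a renewal process with Gaussian-jittered inter-beat
intervals. Overlapping twitches superpose additively, so rapid pacing produces
incomplete relaxation between beats — and hence a reduced per-beat excursion —
emergently rather than by special-casing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DisplacementTrace, FrameStack, StimulationProtocol

__all__ = [
    "TwitchModel",
    "SyntheticScene",
    "GroundTruthBeats",
    "twitch_kernel",
    "twitch_peak_time",
    "simulate_trace",
    "render_frames",
    "pulse_schedule",
    "grid_scene",
    "write_frames",
    "write_traces_csv",
    "write_truth_beats_csv",
]

# Default twitch kinetics: fast contraction, slow relaxation.
DEFAULT_TAU_CONTRACT = 0.05  # s
DEFAULT_TAU_RELAX = 0.3  # s
DEFAULT_AMPLITUDE = 8.0  # px
DEFAULT_IBI_CV = 0.05

# Paper-reported pacing pulse parameters (bipolar field pulses).
DEFAULT_PULSE_VOLTAGE = 20.0  # V
DEFAULT_PULSE_WIDTH_MS = 10.0  # ms


def pulse_schedule(
    frequency: float,
    pulse_width: float = DEFAULT_PULSE_WIDTH_MS,
    voltage: float = DEFAULT_PULSE_VOLTAGE,
) -> StimulationProtocol:
    """Build a pacing protocol from frequency (Hz) and pulse width (ms).

    The inter-pulse gap is ``1000/frequency - pulse_width`` ms: 10 ms pulses at
    1 Hz repeat every 990 ms, at 2 Hz every 490 ms.

    Raises
    ------
    ValueError
        If ``frequency <= 0`` or the pulse width is not shorter than the
        period.
    """
    if not frequency > 0:
        raise ValueError(f"pacing frequency must be > 0 Hz, got {frequency}")
    period_ms = 1000.0 / frequency
    if pulse_width >= period_ms:
        raise ValueError(
            f"pulse width {pulse_width} ms must be shorter than the period {period_ms} ms"
        )
    return StimulationProtocol(
        voltage=voltage,
        pulse_width=pulse_width,
        frequency=frequency,
        inter_pulse_gap=period_ms - pulse_width,
    )


@dataclass
class TwitchModel:
    """Parameters of one needle's beating behaviour.

    ``rate`` sets the mean spontaneous beat rate (Hz); if ``protocol`` is given
    the needle is paced instead, one beat per pulse. ``phase_s`` shifts the
    pacing train (used to give needles independent phases). ``ibi_jitter_cv``
    is the coefficient of variation of spontaneous inter-beat intervals.
    ``drift_px_per_s`` adds a slow linear baseline drift.
    """

    amplitude: float = DEFAULT_AMPLITUDE
    tau_contract: float = DEFAULT_TAU_CONTRACT
    tau_relax: float = DEFAULT_TAU_RELAX
    rate: float = 0.6
    protocol: StimulationProtocol | None = None
    ibi_jitter_cv: float = DEFAULT_IBI_CV
    drift_px_per_s: float = 0.0
    phase_s: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (self.tau_contract > 0 and self.tau_relax > 0):
            raise ValueError("time constants must be > 0")
        if self.ibi_jitter_cv < 0:
            raise ValueError("ibi_jitter_cv must be >= 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    def paced(self, frequency: float, **kwargs) -> "TwitchModel":
        """Copy of this model driven by a pacing schedule at ``frequency`` Hz."""
        return replace(self, protocol=pulse_schedule(frequency), **kwargs)


def twitch_peak_time(model: TwitchModel) -> float:
    """Time from onset to the kernel's peak (closed form)."""
    tc, tr = model.tau_contract, model.tau_relax
    if math.isclose(tc, tr, rel_tol=1e-9):
        return tc
    return tc * tr * math.log(tr / tc) / (tr - tc)


def twitch_kernel(t_since_onset, model: TwitchModel) -> np.ndarray | float:
    """Displacement (px) of a single twitch, ``t_since_onset`` seconds after onset.

    ``k(t) = exp(-t/tau_relax) - exp(-t/tau_contract)``, rescaled so the
    maximum equals ``model.amplitude``; zero at ``t = 0`` and for ``t < 0``.
    In the degenerate limit ``tau_contract == tau_relax`` the analytic
    ``t * exp(-t/tau)`` form is used.
    """
    t = np.asarray(t_since_onset, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tc, tr = model.tau_contract, model.tau_relax
    if math.isclose(tc, tr, rel_tol=1e-9):
        # lim of the difference form: k ~ t * exp(-t/tau), peak tau*e^-1 at t=tau
        raw = np.where(t >= 0, t * np.exp(-t / tr), 0.0)
        peak = tr * math.exp(-1.0)
    else:
        raw = np.where(t >= 0, np.exp(-t / tr) - np.exp(-t / tc), 0.0)
        tpk = twitch_peak_time(model)
        peak = math.exp(-tpk / tr) - math.exp(-tpk / tc)
    out = model.amplitude * raw / peak
    return float(out[0]) if scalar else out


@dataclass
class GroundTruthBeats:
    """Known beat timing for a simulated trace."""

    onsets_s: np.ndarray
    peak_times_s: np.ndarray
    amplitude_px: float

    @property
    def n_beats(self) -> int:
        return len(self.onsets_s)


def _spontaneous_onsets(rate: float, cv: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Renewal process: first onset uniform in [0, 1/rate), Gaussian-jittered intervals."""
    if rate <= 0:
        return np.empty(0)
    mean_ibi = 1.0 / rate
    onsets = [rng.uniform(0.0, mean_ibi)]
    while True:
        ibi = rng.normal(mean_ibi, cv * mean_ibi)
        ibi = max(ibi, 0.1 * mean_ibi)  # guard against non-physical negative intervals
        t = onsets[-1] + ibi
        if t >= duration:
            break
        onsets.append(t)
    return np.asarray(onsets)


def _paced_onsets(protocol: StimulationProtocol, phase_s: float, duration: float) -> np.ndarray:
    """1:1 capture: one beat per pulse; exactly floor(duration*f) beats at phase 0."""
    period = protocol.period_s
    n = int(np.ceil((duration - phase_s) / period))
    onsets = phase_s + period * np.arange(max(n, 0))
    return onsets[(onsets >= 0) & (onsets < duration)]


def simulate_trace(
    model: TwitchModel,
    duration: float,
    fps: float,
    seed: int | np.random.Generator = 0,
    needle_id: int = 0,
    reference: tuple[float, float] = (0.0, 0.0),
) -> tuple[DisplacementTrace, GroundTruthBeats]:
    """Simulate a displacement trace and its ground-truth beat times.

    Beat onsets come from the pacing schedule when ``model.protocol`` is set
    (one beat per pulse) or otherwise from a jittered renewal process with mean
    interval ``1/model.rate``. Overlapping twitches superpose additively.
    Deterministic given the seed.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not fps > 0:
        raise ValueError("fps must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if model.protocol is not None:
        onsets = _paced_onsets(model.protocol, model.phase_s, duration)
    else:
        onsets = _spontaneous_onsets(model.rate, model.ibi_jitter_cv, duration, rng)

    n_frames = int(round(duration * fps))
    t = np.arange(n_frames) / fps
    d = np.zeros(n_frames)
    for onset in onsets:
        d += twitch_kernel(t - onset, model)
    if model.drift_px_per_s:
        d += model.drift_px_per_s * t
    d = np.clip(d, 0.0, None)

    truth = GroundTruthBeats(
        onsets_s=onsets,
        peak_times_s=onsets + twitch_peak_time(model),
        amplitude_px=model.amplitude,
    )
    trace = DisplacementTrace(needle_id=needle_id, fps=fps, d=d, reference=reference)
    return trace, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScene:
    """Geometry and imaging parameters of a rendered needle-array view.

    Each needle is drawn as a dim shaft plus a bright Gaussian tip blob; the
    blob is displaced from its rest position along ``deflection_directions``
    (unit vectors, default horizontal) by the per-frame displacement. Tips must
    stay separated by more than 4x the maximum deflection so identities cannot
    swap by construction.
    """

    tip_rest_positions: np.ndarray  # (n_needles, 2) of (x, y) px
    deflection_directions: np.ndarray | None = None  # (n_needles, 2) unit vectors
    frame_shape: tuple[int, int] = (240, 320)  # (height, width)
    fps: float = 30.0
    duration: float = 10.0
    tip_sigma: float = 2.0  # px
    tip_intensity: float = 200.0
    shaft_width: float = 3.0  # px
    shaft_intensity: float = 60.0
    shaft_length: float = 60.0  # px, base sits below the tip
    shaft_gap: float = 10.0  # px between shaft end and tip centre
    background: float = 15.0
    noise_sigma: float = 0.0  # intensity units
    rng_seed: int = 0
    dtype: np.dtype = np.uint8

    def __post_init__(self) -> None:
        self.tip_rest_positions = np.atleast_2d(np.asarray(self.tip_rest_positions, dtype=float))
        n = len(self.tip_rest_positions)
        if self.deflection_directions is None:
            self.deflection_directions = np.tile([1.0, 0.0], (n, 1))
        self.deflection_directions = np.atleast_2d(
            np.asarray(self.deflection_directions, dtype=float)
        )
        norms = np.linalg.norm(self.deflection_directions, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("deflection directions must be non-zero")
        self.deflection_directions = self.deflection_directions / norms
        if len(self.deflection_directions) != n:
            raise ValueError("one deflection direction per needle is required")
        if self.duration * self.fps < 2:
            raise ValueError("scene must span at least 2 frames (duration * fps >= 2)")

    @property
    def n_needles(self) -> int:
        return len(self.tip_rest_positions)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    def check_separation(self, max_deflection: float) -> None:
        """Tips must sit more than 4x the maximum deflection apart."""
        pos = self.tip_rest_positions
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                dist = float(np.linalg.norm(pos[i] - pos[j]))
                if dist <= 4.0 * max_deflection:
                    raise ValueError(
                        f"needles {i} and {j} are {dist:.1f} px apart, within 4x the "
                        f"maximum deflection ({max_deflection:.1f} px); identities could swap"
                    )


def grid_scene(n_needles: int, spacing: float = 70.0, **kwargs) -> SyntheticScene:
    """Convenience scene with needles laid out on a row-major grid."""
    frame_shape = kwargs.pop("frame_shape", (240, 320))
    h, w = frame_shape
    per_row = max(1, int((w - 120) // spacing) + 1)
    positions = []
    for k in range(n_needles):
        r, c = divmod(k, per_row)
        positions.append((60.0 + c * spacing, 60.0 + r * spacing))
    positions = np.asarray(positions)
    if positions[:, 0].max() > w - 30 or positions[:, 1].max() > h - 30:
        raise ValueError("grid does not fit the frame; enlarge frame_shape or shrink spacing")
    return SyntheticScene(tip_rest_positions=positions, frame_shape=frame_shape, **kwargs)


def _add_gaussian_blob(img: np.ndarray, cx: float, cy: float, sigma: float, peak: float) -> None:
    """Stamp ``peak * exp(-r^2 / 2 sigma^2)`` centred at (cx, cy), in place."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma)) + 1
    x0, x1 = max(0, int(math.floor(cx)) - r), min(w, int(math.ceil(cx)) + r + 1)
    y0, y1 = max(0, int(math.floor(cy)) - r), min(h, int(math.ceil(cy)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma**2))
    img[y0:y1, x0:x1] += peak * g


def _add_shaft(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, width: float, intensity: float) -> None:
    """Draw a soft-edged line segment from p0 to p1 (both (x, y)), in place."""
    h, w = img.shape
    half = width / 2.0
    pad = int(math.ceil(3 * half)) + 1
    x0 = max(0, int(math.floor(min(p0[0], p1[0]))) - pad)
    x1 = min(w, int(math.ceil(max(p0[0], p1[0]))) + pad + 1)
    y0 = max(0, int(math.floor(min(p0[1], p1[1]))) - pad)
    y1 = min(h, int(math.ceil(max(p0[1], p1[1]))) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    px, py = np.meshgrid(xs, ys)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist2 = (px - p0[0]) ** 2 + (py - p0[1]) ** 2
    else:
        tproj = ((px - p0[0]) * seg[0] + (py - p0[1]) * seg[1]) / seg_len2
        tproj = np.clip(tproj, 0.0, 1.0)
        dist2 = (px - (p0[0] + tproj * seg[0])) ** 2 + (py - (p0[1] + tproj * seg[1])) ** 2
    img[y0:y1, x0:x1] += intensity * np.exp(-dist2 / (2.0 * half**2))


def render_frames(traces: list[DisplacementTrace], scene: SyntheticScene) -> FrameStack:
    """Render displacement traces into a frame stack per the scene parameters.

    Deterministic given ``scene.rng_seed``. Raises if a tip would leave the
    frame or the needle-separation invariant is violated.
    """
    if len(traces) != scene.n_needles:
        raise ValueError(
            f"got {len(traces)} traces for {scene.n_needles} needles"
        )
    n_frames = scene.n_frames
    for tr in traces:
        if tr.n_frames != n_frames:
            raise ValueError("trace length must equal scene duration * fps")

    d = np.stack([tr.d for tr in traces])  # (n_needles, n_frames)
    if np.isnan(d).any():
        raise ValueError("cannot render traces with missing samples")
    scene.check_separation(float(d.max()) if d.size else 0.0)

    h, w = scene.frame_shape
    tips = (
        scene.tip_rest_positions[:, None, :]
        + d[:, :, None] * scene.deflection_directions[:, None, :]
    )  # (n_needles, n_frames, 2)
    margin = 3 * scene.tip_sigma
    if (
        tips[..., 0].min() < margin
        or tips[..., 0].max() > w - 1 - margin
        or tips[..., 1].min() < margin
        or tips[..., 1].max() > h - 1 - margin
    ):
        raise ValueError("a needle tip is displaced outside the frame bounds; fix the scene")

    rng = np.random.default_rng(scene.rng_seed)
    info = np.iinfo(scene.dtype) if np.issubdtype(scene.dtype, np.integer) else None
    frames = np.empty((n_frames, h, w), dtype=scene.dtype)
    shaft_axis = np.array([0.0, 1.0])  # shaft hangs below the tip in the image
    for t in range(n_frames):
        img = np.full((h, w), scene.background, dtype=float)
        for k in range(scene.n_needles):
            tip = tips[k, t]
            base = scene.tip_rest_positions[k] + shaft_axis * scene.shaft_length
            # the shaft follows the bending tip but stops short of the blob
            direction = tip - base
            norm = np.linalg.norm(direction)
            end = tip - direction / norm * scene.shaft_gap if norm > scene.shaft_gap else base
            _add_shaft(img, base, end, scene.shaft_width, scene.shaft_intensity)
            _add_gaussian_blob(img, tip[0], tip[1], scene.tip_sigma, scene.tip_intensity)
        if scene.noise_sigma > 0:
            img += rng.normal(0.0, scene.noise_sigma, size=img.shape)
        if info is not None:
            img = np.clip(np.rint(img), info.min, info.max)
        frames[t] = img.astype(scene.dtype)
    return FrameStack(frames=frames, fps=scene.fps)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_frames(stack: FrameStack, path: str | Path) -> Path:
    """Write a frame stack to a multi-page TIFF (or a PNG sequence directory)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, stack.frames)
        return path
    import imageio.v3 as iio

    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        iio.imwrite(path / f"frame_{i:05d}.png", frame)
    return path


def write_traces_csv(traces: list[DisplacementTrace], path: str | Path) -> Path:
    """Traces as long-format CSV: needle_id, frame, time_s, displacement_px."""
    rows = []
    for tr in traces:
        times = tr.times
        for f in range(tr.n_frames):
            rows.append((tr.needle_id, f, times[f], tr.d[f]))
    df = pd.DataFrame(rows, columns=["needle_id", "frame", "time_s", "displacement_px"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def write_truth_beats_csv(truths: dict[int, GroundTruthBeats], path: str | Path) -> Path:
    """Ground-truth beats as CSV: needle_id, onset_s, peak_s, amplitude_px."""
    rows = []
    for needle_id, gt in truths.items():
        for onset, peak in zip(gt.onsets_s, gt.peak_times_s):
            rows.append((needle_id, onset, peak, gt.amplitude_px))
    df = pd.DataFrame(rows, columns=["needle_id", "onset_s", "peak_s", "amplitude_px"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path
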