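"""Needle-tip recognition and frame-to-frame tracking.

Two detection modes are provided, since the behaviour — recognise the tops of
the needles and track their movement — does not pin down an algorithm:

* ``seeded-template`` (default): the user (or a config file) marks each tip
  once on the reference frame; subsequent frames are located by normalized
  cross-correlation of the reference template inside a small search window,
  with the integer peak refined to sub-pixel precision by a 2-D parabolic fit
  of the 3x3 correlation neighbourhood. Robust to the shaft's low contrast.
* ``auto-blob``: unattended detection by top-hat filtering, thresholded local
  maxima and intensity-weighted centroids; blobs are ordered left-to-right
  within rows, rows top-to-bottom.

Identity maintenance is purely local: each needle is searched within
``search_radius`` of its previously accepted position, which the scene
invariant (inter-needle spacing much larger than deflection) makes sufficient
— no global assignment is needed. Frames whose best match falls below
``min_confidence`` are recorded as missing, never as a fabricated position,
and do not advance the search centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template, peak_local_max
from skimage.morphology import disk, white_tophat

from .core import MISSING, DisplacementTrace, FrameStack, TipTrack

__all__ = [
    "DetectionConfig",
    "Detection",
    "detect_tips",
    "track",
    "to_displacement",
]

# Fraction of missing frames above which a tracking-quality warning is attached.
MISSING_WARN_FRACTION = 0.25

# Minimum top-hat response (intensity units) for auto-blob detection; a blank
# or constant frame stays below this and yields an empty detection list.
AUTO_MIN_RESPONSE = 10.0


@dataclass
class DetectionConfig:
    """Tip detection/tracking parameters.

    ``template_half_size`` is the half-width of the square reference template
    (the template spans ``2*half+1`` pixels); ``search_radius`` bounds the
    per-frame motion in pixels. ``min_confidence`` is the acceptance threshold
    on the match score in [0, 1].
    """

    mode: str = "seeded-template"
    template_half_size: int = 6
    search_radius: int = 12
    min_confidence: float = 0.5
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.mode not in {"seeded-template", "auto-blob"}:
            raise ValueError(f"unknown detection mode {self.mode!r}")
        if self.template_half_size < 2:
            raise ValueError("template_half_size must be >= 2")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@dataclass
class Detection:
    """One detected tip on one frame."""

    needle_id: int
    x: float
    y: float
    confidence: float


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Sub-pixel offset of a peak from three samples; clamped to [-0.5, 0.5]."""
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a local maximum (flat or noise) — keep the integer peak
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def _weighted_centroid(frame: np.ndarray, x: float, y: float, radius: int, n_iter: int = 2) -> tuple[float, float]:
    """Background-subtracted intensity centroid in a window around (x, y)."""
    h, w = frame.shape
    for _ in range(n_iter):
        x0, x1 = max(0, int(round(x)) - radius), min(w, int(round(x)) + radius + 1)
        y0, y1 = max(0, int(round(y)) - radius), min(h, int(round(y)) + radius + 1)
        patch = frame[y0:y1, x0:x1].astype(float)
        weights = patch - patch.min()
        total = weights.sum()
        if total <= 0:
            return x, y
        ys, xs = np.mgrid[y0:y1, x0:x1]
        x = float((weights * xs).sum() / total)
        y = float((weights * ys).sum() / total)
    return x, y


def _extract_template(frame: np.ndarray, x: float, y: float, half: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Cut a (2*half+1)^2 template around (x, y).

    Returns the template and the sub-pixel offset of (x, y) from the template's
    centre pixel, so matched positions can be corrected back to the true tip.
    """
    h, w = frame.shape
    cx, cy = int(round(x)), int(round(y))
    if cx - half < 0 or cx + half >= w or cy - half < 0 or cy + half >= h:
        raise ValueError(f"template around ({x:.1f}, {y:.1f}) extends beyond the frame")
    template = frame[cy - half : cy + half + 1, cx - half : cx + half + 1].astype(float)
    return template, (x - cx, y - cy)


def _match_near(
    frame: np.ndarray,
    template: np.ndarray,
    center: tuple[float, float],
    radius: int,
    subpixel: bool,
) -> tuple[float, float, float] | None:
    """NCC of the template in a window around ``center``; (x, y, score) or None."""
    h, w = frame.shape
    half = template.shape[0] // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, x1 = cx - radius - half, cx + radius + half + 1
    y0, y1 = cy - radius - half, cy + radius + half + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    patch = frame[y0:y1, x0:x1].astype(float)
    if patch.shape[0] < template.shape[0] or patch.shape[1] < template.shape[1]:
        return None
    corr = match_template(patch, template)  # valid mode
    iy, ix = np.unravel_index(int(np.argmax(corr)), corr.shape)
    score = float(corr[iy, ix])
    dx = dy = 0.0
    if subpixel:
        if 0 < ix < corr.shape[1] - 1:
            dx = _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
        if 0 < iy < corr.shape[0] - 1:
            dy = _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    x = x0 + ix + half + dx
    y = y0 + iy + half + dy
    return x, y, min(max(score, 0.0), 1.0)


def _auto_detect(frame: np.ndarray, config: DetectionConfig) -> list[tuple[float, float, float]]:
    """Top-hat + local maxima + centroids; returns (x, y, confidence) tuples."""
    img = frame.astype(float)
    tophat = white_tophat(img, footprint=disk(3 * config.template_half_size // 2))
    peak = tophat.max()
    if peak < AUTO_MIN_RESPONSE:
        return []
    min_dist = max(2 * config.search_radius, 10)
    coords = peak_local_max(tophat, min_distance=min_dist, threshold_abs=0.5 * peak)
    dtype_max = np.iinfo(frame.dtype).max if np.issubdtype(frame.dtype, np.integer) else img.max()
    out = []
    for py, px in coords:
        x, y = _weighted_centroid(img, float(px), float(py), radius=config.template_half_size // 2 + 2)
        conf = float(min(img[py, px] / dtype_max, 1.0)) if dtype_max > 0 else 0.0
        out.append((x, y, conf))
    return out


def _order_blobs(blobs: list[tuple[float, float, float]], row_band: float) -> list[tuple[float, float, float]]:
    """Order left-to-right within rows, rows top-to-bottom (row height ``row_band`` px)."""
    return sorted(blobs, key=lambda b: (round(b[1] / row_band), b[0]))


def detect_tips(
    frame: np.ndarray,
    config: DetectionConfig,
    seeds: list[tuple[float, float]] | None = None,
    templates: list[np.ndarray] | None = None,
) -> list[Detection]:
    """Detect needle tips on a single frame.

    In ``seeded-template`` mode with ``templates`` given, each template is
    matched by normalized cross-correlation within ``search_radius`` of its
    seed; without templates (the reference frame itself) each seed is refined
    to the blob's intensity-weighted centroid. In ``auto-blob`` mode tips are
    found unattended and numbered in reading order. Detections with
    confidence below ``min_confidence`` are dropped (never fabricated).
    """
    frame = np.asarray(frame)
    if config.mode == "auto-blob":
        blobs = _order_blobs(_auto_detect(frame, config), row_band=4.0 * config.search_radius)
        return [
            Detection(needle_id=i, x=x, y=y, confidence=c)
            for i, (x, y, c) in enumerate(blobs)
            if c >= config.min_confidence
        ]
    if not seeds:
        raise ValueError("seeded-template mode requires one seed per needle")
    detections: list[Detection] = []
    for i, (sx, sy) in enumerate(seeds):
        if templates is not None:
            hit = _match_near(frame, templates[i], (sx, sy), config.search_radius, config.subpixel)
            if hit is None or hit[2] < config.min_confidence:
                continue
            detections.append(Detection(needle_id=i, x=hit[0], y=hit[1], confidence=hit[2]))
        else:
            x, y = _weighted_centroid(frame, sx, sy, radius=config.template_half_size)
            detections.append(Detection(needle_id=i, x=x, y=y, confidence=1.0))
    return detections


def track(
    stack: FrameStack,
    config: DetectionConfig | None = None,
    seeds: list[tuple[float, float]] | None = None,
) -> list[TipTrack]:
    """Track every needle tip across the stack.

    Frame 0 establishes the reference positions (refined seeds, or auto-blob
    detections when no seeds are given); each subsequent frame is matched by
    NCC within ``search_radius`` of the previously accepted position. Missing
    frames do not advance the search centre, and accepted motion is clamped to
    ``search_radius`` so tracks can never teleport.
    """
    config = config or DetectionConfig()
    frames = stack.frames
    if len(frames) == 0:
        raise ValueError("cannot track an empty stack")

    first = frames[0]
    if seeds is None or config.mode == "auto-blob":
        auto = _order_blobs(_auto_detect(first, config), row_band=4.0 * config.search_radius)
        if not auto:
            raise ValueError("no needle tips found on the reference frame; provide seeds")
        ref_positions = [(x, y) for x, y, _ in auto]
    else:
        ref_positions = [
            _weighted_centroid(first, sx, sy, radius=config.template_half_size)
            for sx, sy in seeds
        ]

    half = config.template_half_size
    templates: list[np.ndarray] = []
    offsets: list[tuple[float, float]] = []
    for x, y in ref_positions:
        tmpl, off = _extract_template(first, x, y, half)
        templates.append(tmpl)
        offsets.append(off)

    n_frames = len(frames)
    tracks: list[TipTrack] = []
    for nid, (ref, tmpl, off) in enumerate(zip(ref_positions, templates, offsets)):
        positions = np.full((n_frames, 2), MISSING)
        confidence = np.zeros(n_frames)
        positions[0] = ref
        confidence[0] = 1.0
        center = np.asarray(ref, dtype=float)
        for t in range(1, n_frames):
            hit = _match_near(frames[t], tmpl, (center[0], center[1]), config.search_radius, config.subpixel)
            if hit is None or hit[2] < config.min_confidence:
                continue  # missing: search centre stays put
            pos = np.array([hit[0] + off[0], hit[1] + off[1]])
            step = pos - center
            norm = float(np.linalg.norm(step))
            if norm > config.search_radius:  # clamp: no teleporting past the window
                pos = center + step * (config.search_radius / norm)
            positions[t] = pos
            confidence[t] = hit[2]
            center = pos
        warnings = []
        frac = float(np.isnan(positions).any(axis=1).mean())
        if frac > MISSING_WARN_FRACTION:
            warnings.append(
                f"tracking quality: {frac:.0%} of frames missing (confidence < {config.min_confidence})"
            )
        tracks.append(TipTrack(needle_id=nid, positions=positions, confidence=confidence, warnings=warnings))
    return tracks


def to_displacement(
    tptrack: TipTrack,
    fps: float,
    rest_quantile: float = 0.1,
) -> DisplacementTrace:
    """Convert a tip track to a displacement trace relative to rest.

    The rest position is re-estimated rather than taken from frame 0 alone
    (recordings may start mid-beat): displacements are first measured from the
    frame-0 position, then the reference is the median position over the
    lowest-``rest_quantile`` of those frames, and displacement is the Euclidean
    distance from that reference. Missing frames propagate as NaN.
    """
    present = ~tptrack.missing
    if not present.any():
        raise ValueError(f"needle {tptrack.needle_id}: track has no accepted positions")
    pos = tptrack.positions
    first_idx = int(np.flatnonzero(present)[0])
    d0 = np.linalg.norm(pos - pos[first_idx], axis=1)
    d0_present = d0[present]
    cutoff = np.quantile(d0_present, rest_quantile)
    calm = present & (d0 <= cutoff)
    reference = np.median(pos[calm], axis=0)
    d = np.linalg.norm(pos - reference, axis=1)
    return DisplacementTrace(
        needle_id=tptrack.needle_id,
        fps=fps,
        d=d,
        reference=(float(reference[0]), float(reference[1])),
    )
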