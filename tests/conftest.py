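"""Shared fixtures: synthetic scenes run through the full pipeline.

Everything is generated programmatically at test time; the heavier rendered
runs are session-scoped so multiple tests can reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import needlebeat as nb
from needlebeat.beat_analysis import detect_beats
from needlebeat.detect_track import DetectionConfig, to_displacement, track


@dataclass
class PipelineRun:
    """One simulate -> render -> track -> displacement run with its ground truth."""

    scene: nb.SyntheticScene
    true_traces: list[nb.DisplacementTrace]
    truths: list[nb.GroundTruthBeats]
    stack: nb.FrameStack
    tracks: list[nb.TipTrack]
    traces: list[nb.DisplacementTrace]

    @property
    def visible_onsets(self) -> list[int]:
        """Ground-truth onsets that fall within the sampled recording."""
        t_last = (self.stack.n_frames - 1) / self.stack.fps
        return [int((gt.onsets_s <= t_last).sum()) for gt in self.truths]


def run_pipeline(
    models: list[nb.TwitchModel],
    noise_sigma: float = 2.0,
    seed: int = 7,
    fps: float = 30.0,
    duration: float = 10.0,
    spacing: float = 80.0,
    detection: DetectionConfig | None = None,
) -> PipelineRun:
    scene = nb.grid_scene(
        len(models), spacing=spacing, noise_sigma=noise_sigma, rng_seed=seed,
        fps=fps, duration=duration,
    )
    rng = np.random.default_rng(seed)
    true_traces, truths = [], []
    for nid, model in enumerate(models):
        tr, gt = nb.simulate_trace(model, duration, fps, seed=rng, needle_id=nid)
        true_traces.append(tr)
        truths.append(gt)
    stack = nb.render_frames(true_traces, scene)
    tracks = track(stack, detection or DetectionConfig(), [tuple(p) for p in scene.tip_rest_positions])
    traces = [to_displacement(t, fps) for t in tracks]
    return PipelineRun(scene, true_traces, truths, stack, tracks, traces)


@pytest.fixture(scope="session")
def paced_1hz_run() -> PipelineRun:
    """Single needle paced at 1 Hz, noise sigma 2, 10 s at 30 fps."""
    return run_pipeline([nb.TwitchModel().paced(1.0)], noise_sigma=2.0, seed=7)


@pytest.fixture(scope="session")
def paced_2hz_run() -> PipelineRun:
    """Single needle paced at 2 Hz (incomplete relaxation), same twitch model."""
    return run_pipeline([nb.TwitchModel().paced(2.0)], noise_sigma=2.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_run() -> PipelineRun:
    """Single needle paced at 0.6 Hz, zero noise: the high-accuracy reference."""
    return run_pipeline([nb.TwitchModel().paced(0.6)], noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def four_needle_run() -> PipelineRun:
    """Four needles: two paced at 1.0 Hz, two at 0.8 Hz, independent phases."""
    rng = np.random.default_rng(11)
    models = []
    for i, f in enumerate([1.0, 1.0, 0.8, 0.8]):
        phase = float(rng.uniform(0.0, 1.0 / f)) if i > 0 else 0.0
        models.append(nb.TwitchModel().paced(f, phase_s=phase))
    return run_pipeline(models, noise_sigma=2.0, seed=11)


@pytest.fixture()
def beats_of():
    """Detect beats on the first trace of a run (convenience)."""

    def _beats(run: PipelineRun, needle: int = 0):
        return detect_beats(run.traces[needle])

    return _beats
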