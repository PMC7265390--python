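"""Drug/condition time courses: baseline normalization, washout recovery,
two-group statistics, and an optional deflection-to-force converter.

Amplitudes measured after an intervention are expressed relative to the same
construct's pre-intervention (baseline) amplitude, so constructs with
different absolute needle movements can be compared on one axis. A timepoint
with no detectable beats maps to normalized amplitude 0 — contraction arrest,
as seen at the 72 h endpoint of high-dose anthracycline exposure. Beating
rates are carried through unnormalized.

The converter from tip deflection to force uses the Euler-Bernoulli
end-loaded cantilever model, F = 3 E I delta / L^3 with I = pi d^4 / 64. It
requires the needle's Young's modulus, diameter and free length from the
user; without them the force is reported as unavailable rather than guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConditionTimeCourse, TimePoint

__all__ = [
    "ProtocolEvent",
    "TimepointSummary",
    "NeedleProperties",
    "TTestResult",
    "normalize_to_baseline",
    "washout_recovery",
    "compare_groups",
    "force_from_deflection",
]


@dataclass(frozen=True)
class ProtocolEvent:
    """One event of an experimental protocol (times in seconds)."""

    label: str
    time_s: float
    drug: str | None = None
    concentration: str | None = None


@dataclass
class TimepointSummary:
    """Raw per-timepoint measurements before normalization.

    ``mean_amplitude_px`` is None when the timepoint had no detectable beats.
    """

    label: str
    time_s: float
    beats_per_10s: float
    mean_amplitude_px: float | None


def normalize_to_baseline(
    timepoints: list[TimepointSummary],
    baseline_label: str = "baseline",
) -> ConditionTimeCourse:
    """Normalize per-timepoint amplitudes to the baseline timepoint.

    ``normalized_amplitude[t] = mean_amplitude[t] / mean_amplitude[baseline]``;
    the baseline maps to exactly 1.0 and a no-beats timepoint to 0.0. Rates
    pass through unnormalized.

    Raises
    ------
    ValueError
        If the baseline label is absent, or the baseline amplitude is zero or
        missing (normalization undefined).
    """
    if not timepoints:
        raise ValueError("no timepoints to normalize")
    baselines = [tp for tp in timepoints if tp.label == baseline_label]
    if not baselines:
        raise ValueError(f"no timepoint labelled {baseline_label!r}")
    base_amp = baselines[0].mean_amplitude_px
    if base_amp is None or base_amp <= 0:
        raise ValueError("baseline amplitude is zero or absent: normalization undefined")
    out = []
    for tp in timepoints:
        if tp.mean_amplitude_px is None:
            norm = 0.0
        elif tp.label == baseline_label:
            norm = 1.0
        else:
            norm = tp.mean_amplitude_px / base_amp
        out.append(
            TimePoint(
                label=tp.label,
                time_s=tp.time_s,
                beats_per_10s=tp.beats_per_10s,
                mean_amplitude_px=tp.mean_amplitude_px,
                normalized_amplitude=norm,
            )
        )
    out.sort(key=lambda tp: tp.time_s)
    return ConditionTimeCourse(timepoints=out)


def washout_recovery(
    timecourse: ConditionTimeCourse,
    band: float = 0.2,
    washout_label: str = "washout",
) -> tuple[bool, float | None]:
    """Did the normalized amplitude return to baseline after washout?

    Recovered iff any timepoint at or after the washout event has
    ``|normalized_amplitude - 1| <= band`` (default band: +/-20% of baseline).
    Returns ``(recovered, first_recovery_time_s)``.
    """
    washouts = [tp for tp in timecourse.timepoints if tp.label == washout_label]
    if not washouts:
        raise ValueError(f"time course has no {washout_label!r} event")
    t_wash = washouts[0].time_s
    for tp in timecourse.timepoints:
        if tp.time_s >= t_wash and abs(tp.normalized_amplitude - 1.0) <= band:
            return True, tp.time_s
    return False, None


@dataclass
class TTestResult:
    t: float
    p: float
    significant_05: bool
    significant_01: bool


def compare_groups(values_a, values_b, welch: bool = False) -> TTestResult:
    """Two-sided Student's t-test (pooled variance) between two groups.

    Flags significance at p < 0.05 and p < 0.01. ``welch=True`` switches to
    the unequal-variance form. Degenerate zero-variance input is handled
    explicitly: identical means give p = 1, separated means p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, significant_05=False, significant_01=False)
        return TTestResult(t=math.inf if a.mean() > b.mean() else -math.inf, p=0.0,
                           significant_05=True, significant_01=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t=t, p=p, significant_05=p < 0.05, significant_01=p < 0.01)


@dataclass(frozen=True)
class NeedleProperties:
    """Mechanical properties needed to convert deflection to force (SI units)."""

    youngs_modulus_pa: float | None = None
    diameter_m: float | None = None
    free_length_m: float | None = None

    def missing(self) -> list[str]:
        return [
            name
            for name, value in (
                ("youngs_modulus_pa", self.youngs_modulus_pa),
                ("diameter_m", self.diameter_m),
                ("free_length_m", self.free_length_m),
            )
            if value is None
        ]


class ForceUnavailableError(ValueError):
    """Raised when needle properties required for force conversion are missing."""


def force_from_deflection(
    deflection: float,
    needle: NeedleProperties,
    pixel_size_um: float | None = None,
    deflection_in_px: bool = True,
) -> float:
    """Estimate the tip force (N) from a deflection via the cantilever model.

    ``F = 3 E I delta / L^3`` with ``I = pi d^4 / 64`` (end-loaded
    Euler-Bernoulli beam). ``deflection`` is in pixels (converted with
    ``pixel_size_um``) unless ``deflection_in_px=False``, in which case it is
    metres. This is a model-based estimate that assumes uniform needle
    geometry; it is an opt-in utility, never part of default reports.

    Raises
    ------
    ForceUnavailableError
        If any needle property (or the pixel size, when needed) is missing.
    """
    missing = needle.missing()
    if deflection_in_px and pixel_size_um is None:
        missing.append("pixel_size_um")
    if missing:
        raise ForceUnavailableError(
            "force conversion unavailable; missing needle properties: " + ", ".join(missing)
        )
    delta_m = deflection * pixel_size_um * 1e-6 if deflection_in_px else deflection
    moment = math.pi * needle.diameter_m**4 / 64.0
    return 3.0 * needle.youngs_modulus_pa * moment * delta_m / needle.free_length_m**3
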