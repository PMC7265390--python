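# Methods

## The measurement problem

A beating cardiac construct skewered on a needle array transmits its
contractile force to the needles; each contraction deflects the needle tips by
a few pixels in a 30 fps microscopy recording. The quantities of interest are
the beating rate (counted per 10 s window), the per-beat tip excursion ("top
movement", the force proxy), beat synchrony across the array, and the change
of amplitude relative to a pre-intervention baseline under pacing, temperature
or drug protocols. The package implements the full chain from frames to those
quantities, plus a simulator that generates recordings with exact ground
truth so the chain can be validated quantitatively.

## Synthetic recordings

**Twitch kernel.** A single contraction is modelled as a difference of
exponentials,

    k(t) = A * (exp(-t/tau_r) - exp(-t/tau_c)) / k_max,   t >= 0,

with a fast contraction constant `tau_c` (default 0.05 s), a slow relaxation
constant `tau_r` (default 0.3 s) and amplitude `A` (default 8 px; the true
pixel scale of real recordings is figure-dependent, so the default is merely
a plausible few-pixel excursion and is fully configurable). The kernel is
zero at onset, peaks exactly at `A` (closed-form peak time
`tau_c*tau_r*ln(tau_r/tau_c)/(tau_r-tau_c)`, ≈0.11 s with the defaults), and
the degenerate `tau_c == tau_r` limit uses the analytic `t*exp(-t/tau)` form.

**Beat timing.** Paced mode places one onset per stimulation pulse (1:1
capture) from a `StimulationProtocol` whose invariant
`pulse_width + gap = 1000/frequency` ms is enforced at construction (10 ms
pulses at 1 Hz → 990 ms gap; at 2 Hz → 490 ms). With phase 0 a `D`-second
recording contains exactly `floor(D*f)` onsets. Spontaneous mode is a renewal
process: the first onset is uniform in `[0, 1/rate)` (avoiding phase-locking
artifacts in rate-recovery tests) and subsequent intervals are Gaussian with
mean `1/rate` and coefficient of variation `ibi_jitter_cv` (default 0.05,
floored at 10% of the mean interval to exclude non-physical values).
Overlapping twitches superpose additively with no saturation, so fast pacing
produces incomplete relaxation — and hence a reduced peak-to-trough
excursion — emergently rather than by special-casing. An optional linear
baseline drift can be added; the trace is clipped at zero.

**Rendering.** Each needle is drawn on a dark background (default 8-bit,
320×240, intensity 15) as a dim soft-edged shaft (the needle body, intensity
60) topped by a bright Gaussian blob (σ = 2 px, intensity 200) at the tip.
The tip moves from its rest position along a per-needle unit deflection
vector (horizontal by default) by the per-frame displacement; the shaft
follows the tip but stops 10 px short of the blob centre so the blob's
photometric centroid stays unbiased (the centroid error of a noiseless
rendered blob is below 0.05 px across sub-pixel displacements; the tested
bound is 0.25 px). Additive Gaussian pixel noise and quantization follow.
Scene validity is enforced: tips must stay inside the frame with a 3σ margin,
and rest positions must be separated by more than 4× the maximum deflection
so tracker identities cannot swap by construction.

**What the simulator does not emulate.** Real recordings contain the tissue
itself (large moving textured structures), illumination drift, focus changes,
needle shafts of varying brightness and length, and possibly camera shake.
Passing the synthetic suite therefore demonstrates correctness of the
geometry, timing and signal-processing chain — not robustness to arbitrary
real-world imaging artifacts. The seeded-template mode with a user-chosen
search radius is the intended tool for real footage precisely because those
artifacts are hard to model.

## Tip detection and tracking

Frame 0 establishes per-needle reference positions: either refined user seeds
(intensity-weighted centroid with background subtraction, two iterations) or
unattended detection (white top-hat filter, thresholded local maxima,
centroids, reading order). A square template (half-size 6 px, ≈3σ of the tip
blob — deliberately small enough to exclude the moving shaft end) is cut
around each reference position, remembering the sub-pixel offset of the true
tip from the template centre. Every subsequent frame is matched by normalized
cross-correlation inside a window of `search_radius` (default 12 px) around
the previously accepted position, the integer peak refined by a 1-D parabolic
fit per axis over the 3×3 correlation neighbourhood (clamped to ±0.5 px).
Matches below `min_confidence` (default 0.5 on the NCC peak) are recorded as
missing — never fabricated — and do not advance the search centre; accepted
steps are clamped to `search_radius`, so consecutive positions can never
teleport. Identity maintenance is purely local: no global assignment is
needed because inter-needle spacing is much larger than any deflection. A
track missing more than 25% of frames carries a tracking-quality warning.

The displacement trace is the Euclidean distance from a rest position
re-estimated as the median position over the lowest-decile-displacement
frames (first pass measured from the frame-0 position), because recordings
may start mid-beat. One consequence worth knowing: when relaxation never
completes (e.g. 1 Hz pacing with `tau_r` = 0.3 s leaves a ~0.5 px residual
between beats), no estimator that only sees the recording can place the rest
closer than that residual, so absolute displacements carry a constant offset
of that order while per-beat amplitudes (measured against local troughs) are
unaffected.

## Beat detection

Traces are smoothed with a 0.1 s moving average; gaps shorter than 3 frames
are linearly interpolated first, longer gaps split the trace into
independently analysed segments. Peaks are local maxima with prominence at
least `min_prominence` — by default 20% of the robust (5th–95th percentile)
displacement range, floored at 0.5 px so flat or noise-only traces yield zero
beats — separated by at least `min_interbeat` (0.2 s, admitting the assay's
2 Hz pacing maximum with margin). Tying the threshold to the trace's own
range makes a myosin-inhibitor-style amplitude loss shrink measured amplitude
without dropping the beat count until the signal nears the noise floor.

Per-beat amplitude is the peak minus the higher of its two flanking troughs
(`above-rest` is available as a config switch); onset and relaxation times
are the 10%-of-amplitude crossings on either flank.

**Window edges.** An onset after the last sampled frame produces no signal
and cannot be counted; validation therefore compares detected counts to
onsets *visible* in the sampled window. Conversely, a contraction still
rising at the final frame is a real beat that prominence-based peak picking
would miss (no local maximum exists yet), so a terminal rise exceeding the
prominence threshold — at least `min_interbeat` after the last peak — is
counted as one beat peaking at the final sample (`count_edge_beats`,
on by default, opt-out). Beats peaking within roughly half the smoothing
window of either edge remain the hardest case; at the assay's rates this
affects at most one beat per window.

The sync index averages, over ordered needle pairs (i, j), the fraction of
i's beats with a beat on j within ±0.15 s (~2× the twitch time-to-peak; well
below the shortest inter-beat interval at 2 Hz). It is 1.0 iff every beat
co-occurs within tolerance; a needle without beats contributes 0 to its
pairs.

## Condition time courses and statistics

Per-timepoint mean amplitudes are divided by the baseline timepoint's mean
(exactly 1.0 at baseline by construction); a timepoint without detectable
beats maps to 0 (contraction arrest). Rates pass through unnormalized —
that separation is what distinguishes a rate-sparing amplitude loss
(myosin inhibition) from a chronotropic response. Normalization is idempotent
and invariant to rescaling all raw amplitudes, and hour-scale toxicity
timepoints are converted to seconds at the boundary. Washout recovery is
declared when any timepoint at or after the washout event returns within a
±20% band of baseline (configurable; "returned to baseline" has no standard
quantitative criterion).

Two-group comparisons use the classical pooled-variance Student's t-test
(two-sided), with Welch's form behind a flag; significance is flagged at
p < 0.05 and p < 0.01. Zero-variance degenerate inputs are handled
explicitly (identical means → p = 1; separated means → p = 0) rather than
propagating NaNs. No multiple-testing correction is applied — the assay
performs single two-group comparisons.

The deflection-to-force converter implements the end-loaded Euler–Bernoulli
cantilever, `F = 3*E*I*delta/L^3` with `I = pi*d^4/64`. It refuses to run
unless the user supplies Young's modulus, diameter and free length (and the
pixel size): for real needle arrays these are typically unknown and
non-uniform, so forces are an opt-in, clearly model-based estimate, never a
default output.

## Problem sizes and numerical choices

Validation scenes are 10 s at 30 fps (300 frames of 320×240), the window
length in which rates are reported; the frame-rate invariance check renders
the same waveforms at 60 fps. The rate-recovery grid crosses spontaneous
rates {0.3, 0.6, 0.8, 1.0, 2.0} Hz with noise σ ∈ {0, 2, 5} intensity units
at fixed seeds and requires every cell to match the visible-onset ground
truth exactly (raw onset counts never off by more than 1). All simulator
randomness flows through a single seeded generator, so identical
seed + configuration yields bit-identical traces, frames and CSV outputs;
the pipeline writes a manifest (config hash, seed, version) alongside its
artifacts.

## Known limitations

* At 30 fps, contraction/relaxation velocities are not resolvable; only
  counts, amplitudes and timing at frame resolution are reported.
* The tracker assumes well-separated, roughly blob-like tips; it does not
  handle tips that occlude each other or leave the frame.
* The sync index is tolerance-based co-occurrence, not a phase-locking
  statistic; with very different rates it degrades gracefully but is not a
  substitute for proper phase analysis.
* Force estimates inherit every assumption of the uniform-cantilever model.
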