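# File formats

Conventions: CSV for tabular data, JSON for nested summaries, YAML for
configuration. Frame indices are 0-based; all times are seconds
(`time_s = frame / fps`); positions and displacements are pixels with the
origin at the top-left corner, x rightward, y downward. Floats are written
with 6 decimal places, so write-then-read round-trips reproduce in-memory
values to 1e-6.

## tracks.csv

One row per needle per frame.

| column     | meaning                                   |
|------------|-------------------------------------------|
| needle_id  | integer needle index                      |
| frame      | 0-based frame index                       |
| time_s     | frame / fps                               |
| x_px, y_px | tip position (empty when missing)         |
| confidence | match score in [0, 1]; 0 when missing     |
| missing    | 1 if no accepted detection for this frame |

## beats.csv

One row per detected beat: `needle_id, onset_s, peak_s, relax_s,
amplitude_px`. Onset/relax are the 10%-of-amplitude crossings; amplitude is
peak minus the higher flanking trough (see docs/methods.md).

## summary.json

Mirrors `ArraySummary`: the analysis `window` `[t0, t1]`, `sync_index`
(null for single-needle runs), and `per_needle` entries with
`beats_per_10s`, `mean_peak_amplitude`, `amplitude_cv`.

## timecourse.csv

One row per protocol timepoint: `label, time_s, beats_per_10s,
mean_amplitude_px, normalized_amplitude`. `mean_amplitude_px` is empty at
no-beat timepoints (whose normalized amplitude is 0).

## Simulator outputs

`simulate` writes `frames.tif` (multi-page TIFF), `traces.csv`
(`needle_id, frame, time_s, displacement_px` — the ground-truth
displacements) and `beats_truth.csv` (`needle_id, onset_s, peak_s,
amplitude_px` — the ground-truth beats).

## YAML configs

* Scene config (`simulate --config`): a `scene` mapping (either
  `tip_rest_positions` or `n_needles` + `spacing` for a grid; plus
  `frame_shape`, `fps`, `duration`, `noise_sigma`, rendering intensities)
  and a `needles` list of twitch models (`amplitude`, `tau_contract`,
  `tau_relax`, `rate` or `paced_hz`, `ibi_jitter_cv`, `drift_px_per_s`,
  `phase_s`).
* Seeds file (`track --seeds`): a YAML list of `[x, y]` tip positions on the
  reference frame.
* Protocol (`response --protocol`): a YAML list of events with `label`,
  `time_s` and optional `drug`/`concentration`; exactly one event must be
  labelled `baseline`.
* Run config (`run --config`): `input_path`, `fps_override`, `seeds`,
  `detection` (DetectionConfig fields), `beats` (BeatDetectionConfig
  fields), `protocol_path`, `out_dir`, `seed`.

## manifest.json

Written by `pipeline_run`: the full config, its SHA-256 hash (first 16 hex
digits), the seed, the package version, and per-stage status/timing.
Identical manifest hash on identical input implies byte-identical CSVs.
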