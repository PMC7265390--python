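# needlebeat

Contraction analysis for scaffold-free cardiac constructs on a needle array.

Tissue-engineered cardiac constructs — spheroids of iPSC-derived
cardiomyocytes, endothelial cells and fibroblasts printed onto a grid of fine
needles — bend the needle tips as they beat. The tip displacement per
contraction ("top movement", in pixels) is a practical proxy for contractile
force, and its time course under pacing, temperature change or drug exposure
is the readout of interest for drug-response and cardiotoxicity screening.
`needlebeat` is the measurement side of that assay: it tracks needle tips in
grayscale microscopy video, turns the tracks into displacement traces, detects
beats, and quantifies rate, amplitude, cross-needle synchrony and
baseline-normalized drug responses. A synthetic video generator with known
ground truth makes every stage verifiable without real recordings.

## What it measures

For each needle tip with resting position $\mathbf{r}$ and tracked position
$\mathbf{p}_t$ at frame $t$ (time $t/\mathrm{fps}$):

* **displacement** $d_t = \lVert \mathbf{p}_t - \mathbf{r} \rVert$ (px), with
  $\mathbf{r}$ re-estimated as the median position over the
  lowest-displacement decile of frames;
* **beats**: prominence-based peaks on the smoothed trace with a refractory
  spacing (default 0.2 s, admitting pacing up to ~4 Hz); the **beating rate**
  is the beat count rescaled to a 10 s window;
* **per-beat amplitude**: peak value minus the higher flanking trough, so
  incomplete relaxation under fast pacing reduces the measured movement;
* **sync index** $\in [0,1]$: mean over ordered needle pairs of the fraction
  of beats co-occurring within ±0.15 s;
* **normalized amplitude**: mean amplitude at each protocol timepoint divided
  by the pre-intervention baseline (1.0 at baseline, 0 at contraction arrest);
* optionally, **force** via the Euler–Bernoulli cantilever model
  $F = 3EI\delta/L^3$, $I = \pi d^4/64$, when the needle's Young's modulus,
  diameter and free length are known.

Tracking is normalized cross-correlation of per-needle reference templates
within a small search window, refined to sub-pixel precision by a parabolic
fit (position RMSE well under 0.1 px on rendered scenes); an unattended
blob-detection mode provides an independent cross-check.

## Worked example

Simulate a single needle paced at 1 Hz (10 ms pulses repeating every 990 ms),
render 10 s of 30 fps video with pixel noise, then run the analysis chain:

```bash
$ cat scene.yaml
scene:
  n_needles: 1
  noise_sigma: 2.0
  duration: 10
  fps: 30
needles:
  - paced_hz: 1.0

$ needlebeat --quiet simulate --config scene.yaml --out sim --seed 1
wrote 300 frames, 10 ground-truth beats to sim
$ needlebeat --quiet track --video sim/frames.tif --fps 30 --out tracks.csv
tracked 1 needles over 300 frames -> tracks.csv
$ needlebeat --quiet analyze --tracks tracks.csv --out summary.json --beats beats.csv
needle 0: 10.0 beats/10 s, mean amplitude 7.25 px
```

The detected 10 beats per 10 s match the 1 Hz pacing schedule 1:1. The mean
per-beat amplitude (7.25 px) sits slightly below the simulated 8 px twitch
amplitude because relaxation is not quite complete between 1 Hz beats and
amplitudes are measured against local troughs; pacing the same model at 2 Hz
lowers it further — the incomplete-relaxation signature of fast pacing. A
`response` subcommand normalizes per-timepoint summaries to a baseline for
drug-addition/washout and toxicity protocols, and `run` executes the whole
pipeline from one YAML config with a reproducibility manifest.

The library surface mirrors the CLI: `simulate_trace`/`render_frames`,
`track`/`to_displacement`, `detect_beats`/`summarize`,
`normalize_to_baseline`/`washout_recovery`/`compare_groups`. See
`docs/methods.md` for the model details and `docs/FORMATS.md` for the file
formats.

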