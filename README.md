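# batsync

**Do flying bats always echolocate?** Paired thermal-video / ultrasonic
monitoring can answer that only if the two sensor streams are detected,
measured and time-synchronized carefully. `batsync` is a tested pipeline
for exactly that analysis: it detects flying bats in thermal frame
stacks, extracts echolocation pulses and call metrics from full-spectrum
audio, matches the two event streams within a ±30 s window, and computes
the correspondence statistics — nightly synchronous proportions, Pearson
correlation of nightly counts, Fisher's exact tests on proximity × flight
contingency tables, and the sampled-airspace geometry of camera versus
microphone. A synthetic-data generator with full ground truth stands in
for field recordings, so the package can demonstrate that the pipeline
recovers a known silent-flight probability.

It is written for field ecologists and bioacousticians who use
off-the-shelf thermal cameras and bat detectors (e.g., 640×480 / 57° FOV
surveillance cameras and 192 kHz full-spectrum recorders) and want a
reproducible, scriptable version of the "seen but not heard" analysis.

## The model in brief

- **Video events**: blobs above a median background + 4σ threshold,
  ≥ 5 contiguous pixels, linked into tracks spanning ≥ 2 analyzed frames
  (every 10th frame ⇒ ≥ 1/3 s). Range from apparent size via the pinhole
  relation d = f·L/s (f ≈ 589.4 px, L = 0.35 m); proximity classes
  near ≤ 25 m < mid ≤ 50 m < far ≤ 80 m; flight classed
  straight/curved/erratic from heading changes.
- **Acoustic events**: spectrogram pulse detection (15 dB over the noise
  floor), trigger-file grouping (2.0 s window, 15 s cap), search-phase
  sequences (≥ 3 pulses, gaps ≥ 100 ms), and the standard call metrics
  (IPI, pulse rate n/span, duration, peak frequency, bandwidth,
  modulation = 100·bandwidth/fmax).
- **Correspondence**: a video event is *synchronous* if any call file
  starts within ±30 s; nightly proportion = 100·synchronous/visual.
  Exact r×c Fisher tests by full margin enumeration with Bonferroni
  control; Pearson r with t-based p.
- **Simulator**: Poisson bat passes (53/37/10% straight/curved/erratic
  mix), lognormal IPI call trains (217 ± 98 ms) at 29.3 kHz peak, an
  acoustic channel with spherical spreading + absorption + off-axis beam
  loss and an 18 dB trigger, and a controllable probability `p_silent`
  that a pass emits nothing.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Reproduce the published 20-night tally analysis from the packaged count
tables:

```python
from batsync import datasets
from batsync.stats import (average_nightly_proportion, pearson_correlation,
                           build_tables, fisher_exact, bonferroni,
                           sampling_volumes)
from batsync.camera import CameraModel

nights = datasets.nightly_counts()
print(nights[["acoustic_n", "visual_n", "synchronous_n"]].sum().to_dict())
print(round(average_nightly_proportion(nights), 1))
r, p = pearson_correlation(nights["acoustic_n"], nights["visual_n"])
print(round(r, 2), round(p, 4))

events = datasets.events_from_counts(datasets.proximity_flight_counts(), "flight")
tables = build_tables(events)
raw = {"proximity": fisher_exact(tables["proximity"].counts)}
raw.update({prox: fisher_exact(t.counts)
            for prox, t in tables["flight_by_proximity"].items()})
for t in bonferroni(raw):   # family of 4 tests
    print(t.name, round(t.p_raw, 4), round(t.p_adjusted, 4))

print(sampling_volumes(CameraModel(), 50.0))
```

prints

```
{'acoustic_n': 2535, 'visual_n': 784, 'synchronous_n': 383}
30.9
0.64 0.0024
proximity 0.0 0.0
near 0.0 0.0
mid 0.0003 0.0011
far 0.1173 0.4691
(36900.0, 261799.3877991494, 14.094761760218253)
```

i.e., 2,535 acoustic and 784 visual detections with 383 synchronous
matches; only ~31% of visual detections per night, on average, had a call
within ±30 s, even though nightly acoustic and visual totals correlate at
r = 0.64. Whether a near- or mid-range detection had acoustics depends
strongly on flight type (adjusted p ≤ 0.0011) but not at far range
(p = 0.4691 ≈ the published .4692). The camera images ~36,900 m³ at
50 m — about 14% of the 261,799 m³ hemisphere the omnidirectional
microphone samples.

And a simulation round trip — does the pipeline recover a 70%-silent
night as a ~30% synchronous proportion?

```python
from batsync.pipeline import recover_silent_fraction
print(recover_silent_fraction(0.7, n_passes=500, seed=1))
```

```
{'p_silent': 0.7, 'expected_pct': 30.000000000000004, 'measured_pct': 31.8,
 'n_passes': 500, 'n_near_events': 500, 'n_recorded_pulses': 1577,
 'n_emitted_pulses': 1577}
```

500 near-range passes rendered, detected, matched — 31.8% of events had a
call file within ±30 s, recovering the 30% vocal fraction to within
binomial error (±2% SE at this sample size).

## Command-line workflow

```bash
batsync simulate --config sim.yaml --out night1 --seed 7      # frames.tif, pulses.csv, audio/*.wav, truth.csv
batsync detect-video --in night1 --out video_events.csv --gate 160
batsync detect-audio --in night1/pulses.csv --out call_files.csv
batsync match --video video_events.csv --audio call_files.csv --out matched/
batsync stats --tally matched/nightly_tally.csv --out stats/
```

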