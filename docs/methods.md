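# Methods

`batsync` models a paired-sensor field design for monitoring flying bats:
a thermal surveillance camera (640×480 px, 57° horizontal field of view,
30 fps, 10 mm lens) aimed at open airspace, with a full-spectrum
ultrasonic detector (192 kHz sampling, 18 dB SNR trigger, 2.0 s trigger
window, 15 s maximum file length) alongside it. The question the analysis
answers is how often a bat *seen* on video is also *heard* acoustically —
and, through simulation, whether the pipeline can recover a known
silent-flight probability from the synchronous-detection rate.

## The measurement model

**Video.** Every 10th frame (3 analyzed frames/s) is segmented against a
per-pixel median background; pixels exceeding background + 4 robust
noise SDs are grouped by 8-connectivity, and components under 5 contiguous
pixels are discarded outright. Surviving blobs are linked into tracks by
greedy nearest-neighbor association within a displacement gate (default
60 px per analyzed frame, configurable; near-range bats can move >100
px/frame and need a wider gate), with one skipped frame tolerated. An
event must span at least two analyzed frames (≥ 1/3 s). Insects are
rejected when a track is both blurry (median border sharpness < 0.4) and
fast (median transit > 100 px/analyzed frame); ties favor bats. Border
sharpness is the mean, over boundary pixels, of the steepest single-pixel
intensity step, normalized by blob contrast — an ideal hard border scores
≈ 1, a heavily defocused target well below 0.4.

Range is estimated from apparent size by the pinhole relation
d = f·L / s, with focal length f = (W/2)/tan(hfov/2) ≈ 589.4 px and
characteristic bat extent L = 0.35 m; the event distance is the nearest
approach over the track. Proximity classes are near ≤ 25 m, mid
(25, 50] m, far (50, 80] m; beyond 80 m detections are outside the
calibrated range and dropped. Flight type uses per-step headings:
≥ 2 sign reversals among turns > 45° → erratic; net heading change
< 30° → straight; otherwise curved. Two temporally overlapping tracks
are agonistic when their estimated 3-D separation dips below 3 m while
both are turning.

**Audio.** Pulses are found on a short-time spectrogram (256-sample Hann
windows, 75% overlap ⇒ 1.33 ms windows, 0.33 ms hop): maximal runs of
frames whose spectral peak exceeds the file's noise floor (median
spectral magnitude) by 15 dB. Peak frequency is the maximum-energy bin
over the run; minimum/maximum frequency are the extreme bins reaching
within 15 dB of the pulse peak (the measurement threshold mirrors the
amplitude criterion; the recordings' own convention is not stated in
field reports). Onset and duration are refined on the band-limited
Hilbert envelope against −20 dB of the pulse's own peak, keeping onset
error below one hop. Pulses group into trigger files exactly as the
recorder would: a file stays open while quiet gaps are < 2.0 s and closes
at 15 s.

Per-pulse metrics: bandwidth = fmax − fmin; modulation = 100·bandwidth /
fmax (for a down-sweep fmax is the start frequency, so this reads as the
percent sweep of the start frequency). Search-phase sequences are runs of
≥ 3 pulses, all ≥ 15 dB, with every onset gap ≥ 100 ms; sub-100 ms gaps
(approach/terminal regime) break a run. Sequence metrics: IPIs are
successive onset differences; pulse rate = n / (end of last pulse −
onset of first). A feeding buzz is ≥ 5 consecutive pulses at IPI ≤ 50 ms;
a social flag requires ≥ 2 pulses below 20 kHz peak frequency lasting
> 10 ms.

**Matching.** A video event is synchronous when ≥ 1 call file starts
within ±30 s of the event start (the window is symmetric; reference times
are event start and trigger start). Nightly tallies report acoustic,
visual and synchronous counts with the proportion 100·synchronous/visual;
the across-night average is unweighted over nights with visual
detections.

**Statistics.** Fisher's exact test for r×c tables enumerates every table
with the observed margins, scores each by its multivariate
hypergeometric probability via log-factorials, and sums probabilities
≤ the observed table's (tie tolerance 1e-12). This matches R's
`fisher.test` to seven digits on the study's tables. Bonferroni control
multiplies by the number of tests (m = 4 here: one proximity test plus
three per-proximity flight tests); notably, the study's printed p-values
(.0011 mid-range, .4692 far-range) equal our raw enumerated p-values
times 4, so the package reports both raw and adjusted. Pearson
correlation uses the standard product-moment estimate with the two-sided
t-based p (n − 2 df). Sampled-airspace volumes: the camera images a
rectangular pyramid (W·H·d)/3 with the field-of-view dimensions quoted to
the nearest meter (54 × 41 m at 50 m ⇒ 36,900 m³), while the
omnidirectional microphone above ground samples a hemisphere
(2/3)·π·d³ ≈ 261,799 m³ at 50 m, a ≈ 14% ratio.

## The synthetic-data generator

The simulator emulates nights at the study's scale so that every stage is
testable without field recordings.

*Flight.* Pass counts are Poisson with the configured rate; trajectory
types follow the observed mix (53% straight, 37% curved, 10% erratic).
Each pass is built around a nearest-approach point in the camera frustum:
straight passes hold a constant heading, curved passes follow one
circular arc with 30–180° of single-signed heading change, erratic passes
make ≥ 2 heading reversals > 45°. Flight speed defaults to 7 m/s
(SD 1 m/s, truncated), the reported upper range for the species in
comparable settings; it is configurable.

*Thermal rendering.* Bats are sharp-bordered ellipses whose major axis is
the pinhole projection of L = 0.35 m at their range; insects are small
Gaussian-blurred blobs at close range, mostly under the 5-px size filter,
with an occasional larger, heavily defocused one. Sensor noise is
additive Gaussian (SD 8 counts on a 500-count background, 16-bit scale).
Targets beyond the camera's calibrated 80 m range fall below sensitivity
and are not drawn. Frames are float32 in memory and 16-bit TIFF on disk.

*Calls.* A pass is silent with probability `p_silent` — the parameter of
interest. Vocal passes emit a renewal train whose IPIs are lognormal
(positive support and right skew consistent with the observed 680 ms
maximum), moment-matched to mean 217 / SD 98 ms. Pulse durations are
lognormal (6.9 / 3.5 ms, clipped to the observed 1–21 ms range); peak
frequency is normal (29.3 / 5.0 kHz); bandwidth is lognormal
(10.1 / 6.7 kHz), split around the peak in the 6.3 : 3.0 ratio of the
observed start−peak / peak−end means. Terminal buzzes (≥ 5 pulses at
15–45 ms IPI) are appended with probability 0.10 and social pulses
(< 20 kHz, > 12 ms) inserted with probability 0.02, matching the observed
10% / 2% file shares.

A separate sampler draws *search-phase sequences* directly, for
validating the metric chain: sequence length is 3 + Poisson(1), and IPIs
are 100 ms + lognormal moment-matched to (117, 98) ms — the shift keeps
every gap ≥ 100 ms (so generated sequences satisfy the extraction rule by
construction) while preserving the 217 / 98 ms moments. The Poisson mean
of 1 was chosen analytically: with these IPI and duration models, the
expected per-sequence rate n/((n−1)·IPI + dur) averaged over the length
distribution equals ≈ 6.7 Hz, the observed mean pulse rate. (Long
uniform trains would give ≈ 5 Hz; the observed 6.7 Hz at 217 ms IPI
implies short sequences, ~3–4 pulses, as the 584 pulses / 109 files ratio
also suggests.)

*Acoustic channel.* Received level = source level (default 118 dB at 1 m)
− 20·log₁₀(d) spherical spreading − α·d absorption (default 0.3 dB/m,
typical of ~30 kHz in humid tropical night air) − k·(1 − cos θ) beam
loss, where θ is the angle between the bat's heading and the bat→mic
direction (k = 15 dB; the microphone itself is omnidirectional, mounted
at 2 m). A pulse is recorded iff its received SNR over the noise floor
clears the 18 dB trigger — strictly, so 17.9 dB is not recorded. Every
recorded pulse traces to exactly one emitted pulse in the ground-truth
log.

*Seeding.* One root seed spawns independent child streams (flight,
calls, noise, insects) via `numpy.random.SeedSequence`, so each subsystem
is reproducible in isolation.

## Validation experiments

**Silent-fraction recovery.** For p_silent ∈ {0, 0.3, 0.7}, 1,500
near-range passes (nearest approach 10–22 m) are scheduled one per
2-minute segment — twice the matching window, so a ±30 s match can only
come from the pass's own calls and the silence parameter is not
confounded by arrival clustering. Video is rendered at the
analyzed-frame cadence (the frames a 10:1 subsampled analysis would
examine) and run through the full detector; calls pass through an ideal
channel (no absorption, no beam loss) so every pulse is recorded. The
near-range synchronous proportion then estimates (1 − p_silent)·100%.
With 1,500 passes the binomial standard error is ≈ 1.2 points, so the
3-point check corresponds to ≈ 2.5 SEs. p_silent = 0 recovers 100%
exactly; raising p_silent can only lower the measured proportion.

**Call-metric recovery.** Sequences drawn from the call model (to ≥ 584
pulses, the study's measured sample) are packed into call files,
re-extracted, and summarized; recovered mean IPI, pulse rate and peak
frequency agree with the generating values (217 ms, 6.7 Hz, 29.3 kHz)
within 5%.

**Detector rates.** On 120 rendered passes at 8–45 m (where the
projected blob exceeds 5 px for ≥ 2 analyzed frames), event recall is
≥ 95%; 60 segments containing only sub-5-px targets yield no events at
all — the size filter is deterministic, so rejection is exact.

## What the simulator does and does not capture

The generator reproduces the study's *scale and structure*: trajectory
mix, call-structure moments, trigger behavior, sampling geometry, and a
controllable silent fraction. It does not attempt physically accurate
infrared radiometry, biologically mechanistic call production,
frequency-dependent atmospheric profiles, weather, clutter echoes, or
species mixtures. Passing tests therefore demonstrate that the *pipeline
measures what it claims to measure* under known conditions — not that
field recordings would be this clean. In real data, detection losses from
off-axis calls, humidity-dependent absorption and observer review would
fold into the "not heard" fraction, which is exactly why the study design
needs the ground-truthed simulation to separate channel loss from true
silence.

## Numerical choices and edge cases

- Background: upper median over ≤ 90 analyzed frames (single partition
  pass); noise SD from consecutive-frame differences (MAD/√2), which is
  independent of the background estimate.
- Proximity boundaries are inclusive on the near side (d = 25.0 m is
  near); distances come from the minimum over the track.
- Tracks with < 3 points default to straight flight; discrimination ties
  favor bats (conservative for the target species).
- Distance d = 0 in the channel clamps to 0.1 m; degenerate Fisher
  margins (an empty row/column leaves nothing to test) return p = 1;
  percentages print half-up, r to 2 decimals.
- Trigger files close when quiet ≥ 2.0 s *or* when the next pulse would
  end past 15 s from file start.
- The waveform synthesizer uses fast-attack Tukey envelopes (0.5 ms
  ramps), so "onset" is physically sharp and the detector's envelope
  refinement is meaningful at sub-hop precision.

## Known limitations

- The pinhole size-to-range calibration assumes a fixed characteristic
  size; real wing posture varies apparent extent roughly two-fold within
  a wingbeat, which would widen proximity-class confusion near
  boundaries.
- Greedy nearest-neighbor tracking can swap identities when two bats
  cross at similar ranges; events (which merge overlapping tracks) are
  unaffected, but per-track flight labels can be.
- The insect model spans only the regimes the discriminator needs
  (tiny/dim and large/defocused); slow blurry targets at middle distances
  would be labeled bats by design (ties favor bats).
- The acoustic channel is single-path; no ground reflection or
  frequency-dependent absorption curve.
- With the default 2:1 ellipse aspect and contrast, a rendered bat's
  above-threshold footprint drops below the 5-px filter beyond roughly
  55–60 m — a conservative version of the nominal 80 m sensitivity
  cutoff. Far-range (50–80 m) classification logic is exercised with
  constructed tracks; rendered end-to-end experiments stay within the
  near/mid regime.
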