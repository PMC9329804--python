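# Methods

This note documents the models, estimators, numerical choices and
limitations of the package in one place.

## The experimental paradigm being modelled

A cued left/right-hand motor-imagery (MI) session: four runs of 40
trials (160 total), each trial 3 s blank screen, 3 s movement-video
cue, 5 s imagery, recorded from a 64-channel 10-20 cap at 1,024 Hz.
Three physiological phenomena carry the analysis:

1. **Event-related desynchronization (ERD)** — alpha/beta power over
   the sensorimotor cortex contralateral to the imagined hand drops
   during imagery relative to a preparation interval.
2. **Mental fatigue** — theta power (and theta/beta ratios) rise over
   the session, most reliably on parietal channels.
3. **Frontal complexity and fronto-parietal coupling** — the Shannon
   entropy of the frontal rhythm spectrum and the phase locking
   between parietal and frontal alpha reflect cognitive engagement;
   young and elderly subjects show opposite entropy trends and
   different coupling strength.

## Synthetic session generator

Per channel the signal is

```
x(t) = A_pink · pink(t) + Σ_b A_b · g_b(t) · o_b(t) + w(t)
```

with `pink` a unit-RMS 1/f-power background (flat below 1 Hz),
`o_b` unit-RMS band-limited Gaussian oscillators synthesized in the
frequency domain for θ = 4–7 Hz, α = 8–13 Hz, β = 14–30 Hz, `g_b` a
deterministic amplitude envelope and `w` white sensor noise.  Sums of
narrowband oscillators suffice because every downstream statistic is
a band-power or phase functional.

Defaults (chosen once as plausible resting-EEG magnitudes, in µV
RMS): pink 5, θ 3, α 6, β 2, white noise SD 1.  With these values the
alpha oscillator carries ~95% of the 8–13 Hz band power, so a planted
attenuation `a` appears in measured relative band power as ≈ 0.95·a.

Planted effects, all parameterized in `SessionConfig`:

* **ERD** — from 1 s to 5 s after imagery onset (0.1 s raised-cosine
  ramps) the α and β envelopes of the configured contralateral
  channels are scaled by `sqrt(1 − a)`, so band power drops by
  exactly `a`.  The first second of imagery is left unattenuated as
  the preparation/reference interval.  `erd_channels` maps each class
  to one channel (default C3/C4) or to a channel set;
  `strongly_separable_config()` uses the whole contralateral
  sensorimotor region, emulating a subject with textbook regional
  rhythm suppression.
* **Fatigue drift** — on `drift_channels` the band-b power of trial
  `t` is scaled by `1 + slope_b · t` (linear in trial index; other
  shapes can be composed by callers).  Defaults: θ +0.008, α +0.003,
  β −0.002 per trial — a gentle drift; recovery tests use steeper,
  clearly supra-threshold slopes.
* **Coupling** — for each `(parietal, frontal, s)` pair the frontal
  alpha oscillator is `sqrt(s)`·(parietal oscillator) +
  `sqrt(1−s)`·(independent oscillator), making PLV a monotone
  function of `s` (verified by Monte-Carlo in the tests).

Rest periods are part of the event schedule but zero-length by
default to keep arrays small.  Same seed ⇒ bit-identical sessions.

What the generator does **not** emulate: volume conduction / head
geometry, ocular and muscular artifacts (the artifact-rejection stage
is therefore a pass-through hook), non-stationary alpha bursting,
inter-subject variability.  Passing tests show the estimators recover
what was planted under this model — not that real recordings satisfy
the model.

## Preprocessing

* Band-pass 1–35 Hz: odd-length Hamming-window FIR (transition
  ≈ 1 Hz, ~3.3·fs taps) applied as a centered convolution — exactly
  zero phase for a symmetric filter, so ERD latencies are unshifted.
  Stopband (≥ 50 Hz) is below −50 dB, which also removes mains
  interference without a separate notch.  Sessions carry 2 s lead-in
  and lead-out so filter edge effects stay outside the trials.
* Resampling to 512 Hz: `scipy.signal.resample_poly` (anti-aliased
  polyphase); event indices are rescaled and rounded.
* Epochs: [0, 5] s from imagery onset; the per-channel mean over the
  [0, 1] s baseline is subtracted from the whole epoch (idempotent).
* The classification branch consumes epochs at the native 1,024 Hz:
  the sliding-window augmentation's decimation-by-4 *is* its
  downsampling, and the augmentation arithmetic (2 s → 2,048 points →
  512-point samples) is consistent only at that rate.

## ERD quantification

Complex Morlet wavelets (5 cycles, 4–35 Hz at 1 Hz steps, via MNE),
per-trial power averaged within a class.  Epochs are
reflection-padded by `n_cycles/f_min` before the transform so the
baseline interval at the epoch edge is not biased low by zero
padding.  ERD in a (band × window) box is the mean of
`(P − P_ref)/P_ref` with `P_ref` the per-frequency-row mean power
over the baseline interval; it is ≥ −1, negative under
desynchronization, and invariant to amplitude scaling.

Group comparison uses the two-sample, two-tailed, pooled-variance
t-test (df = n₁+n₂−2) — the test form that reproduces the published
worked-example significance values (0.021975815 and 0.036622313) from
the printed per-run ERD triples exactly; those triples are inputs to
the test, not quantities the synthetic pipeline claims to reproduce.

## Fatigue index and channel selection

Band energies for the index come from a Welch PSD (1 s Hann segments,
50% overlap) integrated over the band edges; the standalone
`band_decompose` uses wavelet-packet analysis (db8) with
frequency-ordered node selection at ~2 Hz resolution, because the
θ/α/β edges are not dyadic and plain DWT levels cannot represent
8–13 Hz.  The fused index is the unweighted mean of (θ+α)/β and θ/β
(`weight` exposes the fusion as a convex combination).  A channel is
fatigue-sensitive when the Pearson correlation of its per-trial index
with trial order exceeds 0.75 — one-sided, since fatigue indices are
expected to rise; constant series are treated as r = 0.  "Experiment
time" is trial index in acquisition order.

## Rhythm entropy

Per trial and channel: reconstruct the three rhythm bands (same
wavelet-packet decomposition), take energies `Power_j = Σ S_j(i)²`,
normalize to shares `P_j`, and compute `En = −Σ P_j log₂ P_j`
(bits, `0·log 0 := 0`, bounded by log₂ 3 ≈ 1.585).  The awake/fatigue
contrast averages En over the six frontal channels for the first 20
and last 20 trials in acquisition order.  Entropy falls when power
concentrates into one rhythm (the young-adult signature) and rises
when an alpha-dominant spectrum flattens (the elderly signature).

## Phase locking

Alpha-band FIR filtering (transition half the bandwidth), Hilbert
analytic-signal phase, 10% of samples discarded at each edge.  PLV is
computed per trial and averaged over trials, avoiding phase jumps at
trial boundaries.  All-zero signals raise an error (the phase is
undefined) rather than returning an arbitrary value.  For independent
phases at n samples the PLV concentrates around `sqrt(π)/(2·sqrt(n))`
(≈ 0.0089 at n = 10⁴); for narrowband signals within a 4 s trial the
effective sample count is ~2·bandwidth·duration, so the per-trial
chance level is correspondingly higher (~0.15 in the alpha band).

## The CNN classifier

Implemented in NumPy (im2col + BLAS forward, kernel-offset scatter
backward), deterministic given its seeds.  Layer table (input
1 × 32 × 512):

| layer | maps | out | kernel | stride | pad | weights |
|---|---|---|---|---|---|---|
| conv1 | 16 | 32×256 | 1×24 | 1×2 | 0×11 | 400 |
| conv2 | 32 | 16×256 | 2×11 | 2×1 | 0×5 | 11,296 |
| pool1 (avg 2×4) | 32 | 8×64 | | | | |
| conv3 | 32 | 4×64 | 2×5 | 2×1 | 0×2 | 10,272 |
| pool2 (avg 2×4) | 32 | 2×16 | | | | |
| flatten | | 1,024 | | | | |
| dense | | 2 | | | | 2,050 |

Each convolution is followed by batch normalization and ELU; spatial
(feature-map) dropout 0.25 follows each pooling stage; softmax
cross-entropy on the two logits.  Construction verifies every shape
and the four weight counts and raises on the first inconsistent
layer.  Notes on the reference table: the conv paddings above are the
ones that reproduce the printed output sizes (a no-padding reading is
arithmetically inconsistent with them); a parameter-free softmax is
used, so the model total is the sum of the counts above plus the
batch-norm scale/shift parameters.  Dropout is channel-wise
("spatial"), matching the table's wording.

Sample preparation: channels reordered to the 32-label spatial order
(left hemisphere → midline → right hemisphere; C3 in row 8, counting
from 1); per trial, three 2 s windows starting at 0/1/2 s, each
decimated by 4 at all four phases ⇒ 12 samples of 32 × 512 containing
only original data points; each sample globally standardized to mean
0, SD 1.  160 trials ⇒ 1,920 samples.  The train/test split is
trial-grouped (all 12 children on one side — no augmentation
leakage) and class-stratified, giving 1,536/384 at 80/20.

Training: Adam (lr 10⁻³), batch 64, cross-entropy; all settings
configurable.  The label-permutation control uses a session with
erd_attenuation = 0: with no planted class difference the labels are
pure noise and a class-stratified test split pins chance at 0.5; a
permutation of labels on a *separable* session is not a clean null,
because the network can learn the true regional ERD feature and score
wherever the drawn permutation happens to agree with the true labels.

Problem sizes in the test-suite and acceptance runs: ERD recovery
uses full 160-trial sessions on a 4-channel montage (the estimator's
trial-averaged baseline needs ~80 trials per class for a ±0.05
spread); channel selection uses 80 trials; classifier runs use
24-trial sessions on the 32-channel montage with a few training
epochs, which the strongly separable preset saturates.

## I/O

The internal container is a `.npz` array plus a JSON sidecar (fs,
labels, events, true sample count) — lossless.  EDF export writes
16-bit samples against a symmetric per-channel physical range
(quantization step `2·max|x|/65535`), 1 s records, zero-padded tail;
events stay in the JSON sidecar rather than an EDF+ annotation
stream, and reading goes through MNE's EDF parser.  A file whose
payload is shorter than the sidecar's sample count is reported as
truncated instead of yielding a partial recording.

## Known limitations

* The generator's linear drift and stationary oscillators are a
  deliberately minimal model; cohort-level empirical quantities
  (accuracies, group means) of real studies are emulated only
  directionally by the young-like/elderly-like presets.
* Wavelet-packet band edges are quantized to ~2 Hz bins, so the
  effective β band is 14–30 Hz exactly but θ spans 4–8 Hz.
* The Morlet map still smears the attenuation onset by the wavelet
  support (~0.1 s at 10 Hz), biasing recovered ERD slightly toward
  zero; the recovery tolerance (±0.1) absorbs this.
* EDF export quantizes to 16 bits; round trips are exact only in the
  internal container.
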