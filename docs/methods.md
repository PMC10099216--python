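# Methods

## The system

`mmldms` scores polysomnography simultaneously for **sleep stage**
(W, S1–S4, R — the six-class Rechtschaffen–Kales scheme) and **sleep
disorder** (N, B, I, Na, Nf, P, Rd, S — eight recording-level diagnostic
groups).  It is a two-level, decision-fused architecture:

1. **First level — six CNN assessors.**  For each of the three sensor
   modalities (EEG, ECG, EMG) one CNN classifies the sleep stage and one
   the sleep disorder, each from log-frequency spectrogram RGB images of
   10-s signal windows.  Every assessor sees a single modality and a
   single label type.
2. **Second level — arbitration.**  The assessors' softmax probability
   vectors for one window are concatenated classifier-by-classifier,

   `C_i = [p_i,1,1 … p_i,1,K, p_i,2,1 … p_i,M,K]`,

   and passed to a shallow fully connected network (input → 128 → 128 →
   K, ReLU hidden layers, softmax output) that produces the final label.
   Three wirings are implemented: per-modality baselines (no fusion),
   per-task fusion of the three same-task assessors (stage input 3×6 =
   18, disorder 3×8 = 24), and full multilabel fusion where both
   decision networks consume all six blocks (3×6 + 3×8 = 42), letting
   disorder evidence inform the stage decision and vice versa.  For
   comparison the arbitration NN can be swapped for three classical
   rules: maximum probability, majority vote (falling back to maximum
   probability when all assessors disagree, and restricted to the tied
   classes on vote ties), and average probability.  All exact ties break
   toward the lowest class index so every decision path is deterministic.

## Preprocessing

All channels are brought to a common 512 Hz (256 Hz bandwidth) by
polyphase resampling with a high-attenuation Kaiser anti-alias filter.
Each annotated 30-s epoch is cut into overlapping 10-s windows with a
1-s stride (90% overlap, 21 windows per epoch); windows never cross an
epoch boundary and inherit the epoch's stage label and the record's
disorder label.

Each window is turned into a magnitude STFT (Hann taper; defaults:
256-sample segments, hop 128, 512-point FFT, i.e. ~2 Hz resolution —
enough to resolve the delta band while giving ~40 frames per window),
interpolated onto geometrically spaced frequency-bin centres in
[0.5 Hz, 256 Hz] (log-frequency axis; the time axis stays linear),
converted to dB as `20·log10(|S| + 1e-10)`, normalised, and mapped
through the classic piecewise-linear jet colormap into an 8-bit RGB
image with low frequencies at the bottom.  The dB step is a deliberate
choice: min/max normalisation of raw magnitudes would be dominated by
single peaks, and spectrogram imaging conventionally works in dB.

Normalisation is per modality: the range is the *mean of per-image
minima* to the *mean of per-image maxima*, computed on **training
images only** and frozen for validation and test rendering.  Values
outside the range clamp to the colormap endpoints.

## Training

All networks train from scratch with plain mini-batch SGD on
cross-entropy and validation-loss early stopping (best-validation
weights are restored).  Reference hyperparameters: CNNs — learning rate
0.001, batch 10, max 100 epochs; decision NNs — learning rate 0.001,
batch 3, max 10 epochs.  Early-stopping patience (not part of the
reference description) defaults to 5 epochs for CNNs and 2 for decision
NNs.  No momentum or weight decay is applied unless configured.  Class
imbalance is left to the system design — no loss re-weighting.  The
decision networks are trained on probability vectors produced on the
CNNs' *validation* partition and evaluated on test-partition vectors,
which avoids the optimistic bias of reusing CNN training outputs.
"Pre-trained" decision networks are supported as checkpoint
initialisation (`DecisionNnConfig.init`).

Because the environment ships no deep-learning framework, the network
engine (im2col convolution, max pooling, dense layers, ReLU, softmax
cross-entropy, SGD, early stopping) is implemented in numpy inside the
package (`mmldms.nets`).  Two backbones exist: `vgg16` (13 conv + 3
fully connected, the fidelity configuration) and `small_test` (3 conv +
2 dense with the identical I/O contract), which trains on one CPU in
minutes and is used for the desk-scale study.

## Splitting and repetition

For every (participant, stage) group, window keys are split 90%
train/validation and 10% test; the three folds' test chunks are pairwise
disjoint, and within train/validation a further 90/10 split feeds early
stopping.  Every participant appears in both training and test
(closed-set protocol); a strict leave-participants-out split is a
one-line variation on `split_by_participant_stage` but is not the
evaluated protocol.  Experiments are repeated three times on distinct
folds and metrics are averaged.  A provenance audit runs on every fold:
no test window may reach normalisation fitting, CNN training, or
decision-NN training — the run aborts if it does.

Groups smaller than the fold count contribute all their windows to
training (with a warning) rather than producing empty partitions.

## Metrics

Accuracy is the confusion-matrix trace fraction; precision, recall and
F1 are one-vs-rest per class; the summary F1 is the unweighted macro
mean — chosen because the F1's role here is to show how evenly accuracy
distributes across imbalanced categories (micro-F1 would collapse into
accuracy).  Undefined ratios (a class never predicted or never present)
are set to 0 with a logged warning so reports are total.

## Synthetic cohort

The generator emulates the *class structure* of clinical
polysomnography, not its waveform morphology:

* **EEG** per stage: band-limited Gaussian oscillations (white noise
  shaped by a Gaussian band mask, unit RMS per component) at the
  conventional bands — W: alpha 10 Hz + beta 20 Hz; S1: theta 6 Hz;
  S2: sigma 13 Hz; S3/S4: delta 1.3/1.0 Hz; R: theta 6 Hz + weak beta.
* **ECG**: Gaussian beat kernels (20 ms sd) at RR-controlled instants;
  RR mean 0.80–1.10 s by stage, jittered per beat.
* **EMG**: broadband noise scaled by a stage tonic amplitude (wake 1.0
  → REM atonia 0.02).  The tone is additionally jittered per epoch by a
  lognormal factor (ln-sd 0.35), so adjacent stages' EMG distributions
  genuinely overlap the way muscle tone does across a night.
* **Disorders**: one additive periodic burst signature each, in a
  designated modality (e.g. 25 Hz jaw-muscle bursts for bruxism, 15 Hz
  periodic leg bursts for P, alpha/theta/spike intrusions in EEG for
  I/Na/Nf, cardiac bursts for S); normal sleep adds nothing.  All
  burst periods are ≤ 10 s so every analysis window of a disordered
  record contains evidence, and all carriers lie inside the imaged
  band.

Two properties are designed in deliberately.  First, two stage pairs
are ambiguous in EEG alone (S3/S4: near-identical delta peaks; S1/R:
both theta-dominated) but separable through EMG tone — so multimodal
fusion has something real to gain.  Second, the insomnia and narcolepsy
EEG intrusions mimic other stages' band templates (alpha ~ wake, theta
~ S1/R), so the identity of the disorder carries stage-relevant
information — which is exactly the mechanism by which multilabel fusion
can beat per-task fusion.  Conversely, each modality sees only its own
disorders' signatures, capping single-modality disorder accuracy well
below the fused ceiling (an EEG assessor cannot distinguish the five
disorders that leave EEG untouched).

All randomness flows from explicit integer seeds through SeedSequence
spawning: per-record, per-epoch and per-modality substreams, with the
disorder signature on its own substream so changing the disorder never
perturbs the base stage waveforms at a fixed seed.  Identical (config,
seed) gives bit-identical waveforms, spectrograms and PNGs.

What passing tests on this cohort do **not** show: performance on real
polysomnography.  Real EEG microstructure (spindle trains, K-complexes,
CAP A-phases), artifacts, electrode variability and inter-subject
spectra are absent; the synthetic classes are cleaner than clinical
ones.  The cohort validates the *machinery* — preprocessing contracts,
no-leakage splitting, fusion arithmetic, and the qualitative orderings
that follow from its designed information structure.

## Desk-scale study conditions

The end-to-end study runs the full suite on 8 disorders × 2 records ×
40 epochs (16 records, ~11 h of tri-modal signal) with the
`small_test` backbone on 64×64 images, three repeats on distinct
folds.  The window stride is widened to 10 s (3 disjoint windows per
epoch, 1 920 windows per modality) and SGD budgets are rescaled for the
~100× smaller training set: CNN learning rate 0.01 with max 8 epochs,
decision-NN learning rate 0.01 with max 60 epochs (the reference epoch
counts assume ~10^5-image training sets; at ~10^3 images the same
counts would leave the optimisers far from convergence).  The
reference values remain the defaults of `CnnConfig`/`DecisionNnConfig`.

## Numerical notes and limitations

* EDF stores 16-bit integers; written channels are recovered to within
  their quantization step (physical range / 2^16), which round-trip
  tests assert.  The EDF writer lives in this package (1-s data
  records, symmetric physical range, unit dimension `au`); reading goes
  through mne, keeping the two paths independent.
* The jet colormap is defined in-repo by its classic piecewise-linear
  control points and evaluated continuously; it matches the common
  256-entry LUT rendering to within LUT quantization.
* STFT edge frames are zero-padded; tone-localization checks therefore
  inspect interior frames.  Resolving a tone requires a segment long
  enough for at least one cycle — localization tests at 1 Hz use 4-s
  segments.
* `standardize_sampling` refuses non-finite samples; `summarize`
  refuses all-zero confusion matrices; degenerate normalisation ranges
  (min = max) raise rather than divide by zero.
* Probability vectors are renormalised after float32 softmax so the
  unit-sum invariant holds to 1e-6 downstream.
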