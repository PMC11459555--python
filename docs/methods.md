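# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `emgdisc`.

## The discrete recognition problem

A *discrete* myoelectric gesture is one event: the user starts at rest,
transitions through a dynamic contraction, and returns to rest within one to
two seconds. The classifier's input is the whole segmented template — an
8-channel integer time series at 200 Hz, typically 150–400 samples — and its
output is one label plus a per-class confidence vector. This differs from
continuous myoelectric control, where a prediction is emitted for every
200 ms window; the majority-vote pipeline below bridges the two by
discretizing a continuous decision stream.

## Synthetic cohort generator

The generator emulates the statistical structure of multi-user armband
collections so that cohort-scale analyses (cross-user generalization, bias,
confounds, rejection) can be run without any external dataset.

**Signal model.** Surface EMG is approximated as amplitude-modulated,
zero-mean Gaussian noise:

    s[c, t] = round( clip( g_c · e_c(t) · z_t + σ_rest · z'_t , −128, 127) )

with independent standard-normal draws per sample, per-channel gains `g_c`,
a deterministic activation envelope `e_c(t)` and additive baseline noise
(σ_rest = 2 integer units by default). Quantization to signed 8-bit mirrors
raw armband samples. This reproduces the first-order property practitioners
exploit — the windowed RMS/MAV tracks `g_c · e_c(t)` — while remaining
analytically checkable (the tests verify RMS tracking and expected-trace
threshold crossings in closed form).

**Envelopes.** Each gesture class has a per-channel peak-amplitude pattern
(a coarse muscle-synergy topography over the 8 circumferential channels) and
a time course that is a sum of 1–2 raised-cosine bumps; the double-tap
analogue has two bumps. The rest class has zero amplitude everywhere.
Peak amplitude is 35 integer units, ~17 dB above baseline noise.

**Durations.** Active-segment durations are drawn from N(1.3 s, 0.25 s),
truncated at 30% of the mean, multiplied by a per-user speed factor and the
condition's speed multiplier, and placed uniformly inside a 5-s recording.
True bounds are recorded as metadata (0-based, half-open).

**Inter-user variability** has three components, all drawn once per user:
log-normal channel gains (log-sd 0.35), a log-normal speed factor
(log-sd 0.15), and a continuous circular rotation of the channel pattern
(sd 0.75 channels) emulating electrode-placement differences. These
dispersions were calibrated once so that the 40-training-user zero-shot study
operates in the realistic ~75–95% accuracy band reported for cross-user
myoelectric models of that scale, rather than saturating at ceiling; they are
the package defaults and are not adjusted per study.

**Confounds and demographics.** Day and limb-position conditions multiply
the user's gains by per-level log-normal perturbation vectors (log-sd 0.15);
speed conditions scale duration only. Demographic attributes are drawn from
configurable proportions (default 66/34), and a `GroupEffect` can attach a
duration scale and an extra pattern rotation to one group to emulate
systematic physiological/behavioural group differences. Out-of-set gesture
classes are ordinary specs flagged `out_of_set` and excluded from training
by the split logic.

**Randomness.** All draws flow from one root seed through named substreams
keyed by (stream, user, gesture, repetition, condition), so any recording can
be regenerated in isolation and cohorts are byte-identical across runs.

**What the generator does not emulate** (so what passing tests do *not*
show about real data): non-Gaussian and non-stationary EMG microstructure,
motor-unit firing statistics, crosstalk and motion artifacts, electrode-skin
impedance drift, behavioural pattern changes at different speeds (see
Limitations), and within-user learning effects across days.

## Segmentation

- *Index-based*: crop `samples[:, start:end]` from metadata.
- *Active thresholding*: the channel-summed absolute amplitude is smoothed
  with a 15-sample moving average; the active region is the longest run
  (ties: earliest) above `k = 3` times the summed per-channel rest baseline
  (mean |x| of the user's rest recordings) lasting at least 40 samples
  (200 ms). With smooth envelopes the detected run is the supra-threshold
  region, which is strictly inside the envelope support; tests therefore
  compare against the expected-trace crossing points, not the raw bounds.
- *Rest cropping*: rest templates are center-cropped to a target length so
  their lengths match the active-class distribution.

## Features and windowing

Windows start at multiples of the increment; a window is emitted iff it fits
entirely, giving `⌊(T−L)/I⌋ + 1` windows. Feature definitions are normative
for this package: RMS, MAV, WL, MNP (mean two-sided periodogram power, which
equals mean squared amplitude by Parseval), WENG (total squared-coefficient
energy of a 4-level db4 wavelet decomposition, depth reduced for short
windows), ZC and SSC with a dead-band ε (default 0), L-scale (second sample
L-moment, computed from order statistics), MFL (log10 of the root of the
summed squared first differences, floored at 1e-12 to stay finite on
constant windows), MSR, and WAMP (|Δx| > 5 by default). HTD = {MAV, ZC, SSC,
WL}; LS4 = {LS, MFL, MSR, WAMP}. Column order is channels-major,
features-minor, fixed for model reproducibility.

## Classifiers

**MVLDA.** Windows of 200 ms with 25 ms increments are z-scored with
training statistics and classified by a linear discriminant (per-class
means, pooled within-class covariance normalized by n−k, ridge added only if
singular); the template's label is the mode of the window stream, with vote
fractions as the confidence vector. An `exclude_rest` variant takes the mode
of the non-rest votes (falling back to rest). All ties break toward the
lowest class index.

**1NN-DTW.** Templates are reduced to RMS sequences over non-overlapping
25 ms windows, z-scored, and compared with classic unconstrained DTW
(Euclidean local cost, steps {(1,0),(0,1),(1,1)}, boundary-anchored, no
band). Confidence is a softmin (temperature 1 in standardized-feature units)
over per-class minimum distances. Template reduction: *closest* keeps the
per-class DTW medoid; *mean* linearly resamples all templates of a class to
a common length (per-class median by default) and averages them.

**Temporal network.** The reference architecture is 3 LSTM layers of 128
units and a head of 128/64 linear units with per-sample instance
normalization (no affine) and ReLU after each of the first two layers; the
64-d post-activation is the embedding; a final linear layer gives class
scores. Training uses softmax cross-entropy at each template's true final
window (zero padding beyond it cannot reach the gathered state), Adam with
initial learning rate 1e-4, a step scheduler (step 5, gamma 0.9), batch size
1000 (200 in the small-data variant), and early stopping when validation
accuracy fails to gain 0.1% for 5 epochs (armed only after 50 epochs in the
small-data variant); the best-validation weights are kept. The network is
implemented directly in numpy; gradient correctness is pinned by central
finite-difference tests and padding inertness by an explicit test. The head
trains on raw final-layer scores with softmax cross-entropy, and reported
confidences are softmax probabilities — the standard-consistent reading of a
classification head, adopted here deliberately.

The cohort *studies* use a scaled variant (1 LSTM layer of 32 units, 32/16
head, learning rate 3e-3, ≤25 epochs; smaller batches and ≥20 epochs in the
leave-one-repetition-out ceiling study where training folds are small).
These sizes are the package's choice for commodity single-core runs; the
directional findings are insensitive to them, absolute accuracies are not.

## Transfer learning

Both procedures freeze the recurrent block (whose states are therefore
precomputed once per batch) and tune the head for 400 epochs with initial
learning rate 1e-2 and a step scheduler (step 25, gamma 0.9), holding out
the highest-index repetition per class for validation and keeping the
best-validation iterate. *Traditional* transfer minimizes cross-entropy on
the new user's templates. *Contrastive* transfer minimizes
`Σ_i ‖g_i − c_{y_i}‖₂` where the per-class centroids `c` are the mean
embeddings of the cross-user training templates; the centroids are anchors
and are never updated (asserted bit-exactly in tests). Prediction after
contrastive transfer is an unweighted Euclidean kNN vote over the transfer
batch's embeddings with k = repetitions per gesture; the full batch (N ≤ a
few dozen templates) is used per step, so no mini-batching is needed.

## Evaluation harness

Splits: leave-one-repetition-out (each repetition tested exactly once),
cross-user (train/test user sets must be disjoint; asserted), and condition
holdout. The subjects×repetitions sweep draws each fold's training users
once per user count and holds them constant across repetition counts. The
window/increment sweep skips (with a warning) cells whose window exceeds the
shortest template. Bias slicing groups the per-template prediction table by
a metadata attribute; Cohen's d uses the (n₁−1, n₂−1)-weighted pooled
standard deviation. Rejection compares the prediction's top confidence to a
threshold; rejection rate is exactly monotone in the threshold by
construction, and an empty accepted set is reported as missing, never
imputed. Significance testing is left to external tools; reports expose
per-template predictions for that purpose.

## Numerical and design choices

- 0-based, half-open `[start, end)` index convention everywhere.
- Every tie (vote, distance, medoid, argmax) breaks toward the lowest class
  or template index — all pipelines are deterministic given their seed.
- Feature standardization (per-dimension z-score from training data) is
  applied before LDA, DTW and the network and stored with each model.
- LDA ridge: `1e-8 · trace/dim` always, escalated ×100 until invertible.
- DTW uses a numba-compiled dynamic program; distances are exact (no band,
  no normalization), verified against exhaustive path enumeration.
- The instance normalization is per-sample across features without learned
  affine parameters, placed after each of the first two head layers.
- Model bundles serialize as JSON config + npz weights + standardization
  constants; reloading reproduces predictions to float tolerance.

## Limitations

- The amplitude-modulation signal model makes per-window features
  informative by construction; absolute accuracies on synthetic cohorts are
  not predictions of real-data accuracy — only the orderings and mechanisms
  are meaningful.
- Speed conditions scale gesture duration only. Because all three
  architectures are nearly invariant to uniform time scaling under this
  signal model (window statistics unchanged, DTW absorbs the warp, the
  recurrent net generalizes over length), slowing a gesture degrades
  synthetic accuracy only weakly — the sign of the effect can flip between
  seeds and only the multi-seed mean shows the degradation seen strongly in
  real cross-user models, where slow elicitation changes the activation
  pattern itself. Reproducing that effect at realistic magnitude would
  require a behavioural model of speed, which this generator does not claim.
- Synthetic amplitude scales are free parameters, not calibrated to any real
  device's distribution; only relative structure (gains, rotations, noise
  floor) is meaningful.
- The scaled study network trades absolute accuracy for single-core runtime;
  the full-size configuration is provided but not exercised by the default
  studies.
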