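# emgdisc — discrete myoelectric gesture recognition at cohort scale

`emgdisc` is a library for studying **discrete (event-based) myoelectric
control**: instead of emitting one prediction per sliding window, a classifier
consumes the entire evolution of a dynamic gesture — a variable-length,
8-channel surface-EMG template recorded at 200 Hz — and emits a single label
with a confidence vector. This is the interaction model behind gesture-driven
wearables (e.g., a forearm band recognizing *hand open*, *wrist flexion*,
*double tap* as one-shot commands).

The package provides every stage of such a study:

- **`emgdisc.synth`** — a generative multi-user cohort simulator. Surface EMG
  is modelled as amplitude-modulated Gaussian noise,
  `s[c,t] = round(clip(g_c · e_c(t) · z + σ_rest · z'))`, with per-gesture
  raised-cosine activation envelopes `e_c(t)`, gesture durations
  `~ N(1.3 s, 0.25 s)` embedded in 5-s rest-padded recordings, per-user
  log-normal channel gains and speed factors, continuous electrode-rotation
  offsets, day/position gain perturbations, speed conditions, demographic
  attributes with optional group-level generative shifts, and out-of-set
  gesture classes.
- **`emgdisc.dataio`** — manifest/CSV round-trip, index-based segmentation,
  automatic active-threshold segmentation against a rest baseline, rest
  cropping.
- **`emgdisc.features`** — sliding windows (`n = ⌊(T−L)/I⌋ + 1`) and the
  standard myoelectric features: RMS, MAV, WL, MNP, WENG, ZC, SSC, L-scale,
  MFL, MSR, WAMP, plus the HTD and LS4 feature sets.
- **`emgdisc.classifiers`** — majority-vote LDA over a continuous decision
  stream (mode of per-window predictions); 1NN dynamic time warping with
  per-class medoid ("closest") or resampled-mean template reduction.
- **`emgdisc.temporal`** — a stacked-LSTM sequence classifier (implemented in
  numpy with hand-derived backpropagation) trained with cross-entropy at each
  template's true final step, zero-padding inert by construction.
- **`emgdisc.transfer`** — head-only fine-tuning to a new user: traditional
  (cross-entropy) and contrastive, which minimizes
  `L = Σ_i ‖g_i − c_{y_i}‖₂` against *fixed* cross-user class centroids and
  classifies by kNN in the embedding space.
- **`emgdisc.evaluate` / `emgdisc.studies`** — leave-one-repetition-out and
  cross-user splits, subjects×repetitions sweeps, window/increment sweeps,
  demographic bias slicing with Cohen's d, confound evaluation, and
  confidence-based rejection (in-set and out-of-set).

A thin `emgdisc` command-line tool wraps the stages
(`simulate`, `segment`, `featurize`, `train`, `evaluate`, `sweep`,
`transfer`, `reject`); the `examples/` scripts are the best starting point.

## Worked example

```bash
python examples/03_compare_classifiers.py
```

trains the three architectures on 12 synthetic users and evaluates on 4
held-out users:

```
mvlda      held-out-user accuracy:  75.0% (240 templates)
dtw_mean   held-out-user accuracy:  95.8% (240 templates)
lstm       held-out-user accuracy:  76.2% (240 templates)
```

Each number is zero-shot accuracy on users the model never saw. At this small
training-cohort size the reduced-template DTW model leads; the recurrent
network overtakes it once a few dozen training users are available (the
40-user study in `emgdisc.studies.run_crossuser_study` typically lands around
95% for the temporal model vs. 93% for DTW-mean and 75% for MVLDA). The
transfer example shows an outlier user recovering from 33% zero-shot to >90%
after head-only adaptation with 6 labeled repetitions per gesture.

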