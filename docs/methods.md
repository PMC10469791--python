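# Methods

## The classification problem

Motor imagery (MI) — the mental rehearsal of a movement — modulates the
sensorimotor mu (~8-12 Hz) and beta (~13-30 Hz) rhythms, most strongly over
the hemisphere contralateral to the imagined limb (event-related
desynchronisation, ERD). A MI brain-computer interface must decode these
band-limited, spatially lateralised, non-stationary signatures from epoched
EEG, typically with only a few hundred trials per subject and with
distribution drift between recording days ("sessions").

## Preprocessing

Trials are epoched as `trials x channels x samples`. The pipeline is:

1. **Channel selection** to a motor-cortex montage. The default 20-label set
   is the C/CP/FC rows (C5...C6, CP5...CP6, FC5...FC6, plus Cz and CPz).
   Montages are partitioned by the 10-20 convention: odd suffixes left,
   even right, `z` midline; left and right index lists are ordered so that
   `left[i]` and `right[i]` are homologous mirror pairs (C3<->C4).
2. **Downsampling** by an integer factor (1000 -> 250 Hz for raw
   recordings) with a zero-phase FIR anti-alias low-pass before decimation
   (`scipy.signal.decimate`). Rational-ratio resampling is deliberately
   unsupported.
3. **Band filtering.** Three views of every trial: the raw broadband
   signal, mu (7-12 Hz) and beta (13-32 Hz). Filters are zero-phase
   (forward-backward) Butterworth of order 4, applied within each 4-s
   epoch. Edge transients at epoch borders are accepted — no padding
   beyond the trial, a documented limitation.
4. **Z-scoring** per trial and per channel, `z = (x - mean) / sd` with the
   population (divide-by-N) standard deviation; a zero-variance channel is
   an error that names the trial and channel. Per-trial normalisation keeps
   trials i.i.d. across cross-validation folds; computing statistics over
   the training set instead would be a reasonable alternative and is noted
   as a sensitivity-analysis candidate.

## Architecture

Three identical, independently parameterised branches — one per band —
each consisting of:

**Temporal block.** Two parallel paths over each channel's time series,
sharing one receptive-field size `k` (default 25 samples = 0.1 s at
250 Hz):

* a 1-D convolution with `F` temporal filters (default 8), and
* a *local transformer encoder*: each sample is a token, lifted to an
  embedding of width `E` (default 16) by a shared linear map, summed with
  the sinusoidal positional encoding
  `PE(pos, 2i) = sin(pos / 10000^(2i/E))`,
  `PE(pos, 2i+1) = cos(pos / 10000^(2i/E))`, then one post-norm encoder
  layer (h = 2 heads, d_k = d_v = E/h, feed-forward width 2E) whose
  self-attention is *banded*: a query at position t attends only to keys
  within `(k-1)/2` samples. The encoder output is projected back to `F`
  channels per token.

The two paths are fused by **addition** (a `temporal_fusion="concat"`
switch exists; the sources describing the block are ambiguous between the
two and addition is the reading consistent with the block diagram), then
batch-normalised, passed through the activation, and average-pooled over
time (default pool 75, stride 15).

The banded attention is implemented twice: as a boolean band mask over the
full score matrix (transparent; used at test scale) and as a fused
per-diagonal sliding-window kernel with a hand-derived backward pass (O(n·w)
memory; used in the model). The two agree to 1e-6 and are cross-checked in
the tests against a brute-force softmax loop.

**Spatial block.** Three depthwise (per-feature-map) linear maps across
channels: one over all C channels, and one over each hemisphere's channels
(midline electrodes excluded). The left-path minus right-path difference
explicitly encodes lateralisation; the output is the concatenation of the
all-channel features and the difference features, batch-normalised and
activated.

**T-Dense block.** Two densely connected branches of 3 layers each — a CNN
branch (kernel 5, growth g = 8 feature maps per layer) and a
global-transformer branch (pointwise projection to width g, positional
encoding, one global encoder layer per dense layer) — where every layer
receives the concatenation of the block input and all earlier layer
outputs (layer i input width = D0 + (i-1)g). Branch outputs are
concatenated and reduced by a pointwise convolution to `R` (default 16)
feature maps.

**Head.** Branch outputs are flattened, concatenated and classified by a
single fully connected softmax layer.

Defaults everywhere: ELU activation, dropout 0.5, batch normalisation after
each convolution *before* the activation, Glorot-uniform initialisation
with zero biases, all draws from one seeded generator (two builds from the
same seed are bit-identical). Dropout is applied to the output of each
encoder layer and after each T-Dense layer; it is disabled in evaluation
mode. With the 20-channel reference configuration the full model has
~95k trainable parameters.

### Ablation variants

* `wo_trans` — removes both the local and the global transformer paths;
* `wo_diff_hemi` — removes the hemisphere paths (all-channel path only);
* `wo_tdense` — replaces each dense unit by a plain CNN stack of equal
  depth and constant width.

Parameter counts (`count_parameters`, batch-norm running statistics
excluded, scale/shift included) strictly decrease for the first two.

## Training

Cross-entropy loss `L = -mean_batch sum_m y_true,m log y_pred,m`
(predicted probabilities clamped at 1e-12), Adam (beta1 0.9, beta2 0.999,
eps 1e-8). Full-scale defaults: learning rate 1e-4, at most 800 epochs,
minibatch 32, seeded reshuffle each epoch. Early stopping monitors
validation loss with patience 100 (any strict decrease resets the
counter); the weights (and batch-norm statistics) of the
best-validation-loss epoch are restored. No learning-rate schedule, weight
decay or augmentation.

The network and its gradients run on a small reverse-mode automatic
differentiation engine written on numpy (`lgct.autodiff`): a tape of
array operations with per-op backward closures, float32 by default for the
model (float64 elsewhere), verified against central finite differences in
the test suite. This keeps the package dependency-light and every numeric
choice inspectable.

## Evaluation scenarios

* **within_session** — stratified 10-fold CV on one session. The
  evaluation protocol needs a validation set for early stopping that the
  fold layout alone does not provide; one of the nine non-test folds
  rotates in as validation, leaving the test folds exactly as defined. A
  design that validated on the test fold would leak; the non-leaking
  layout is used.
* **cross_session_case1** — train on all of session 1; session 2 is split
  in *recorded order* into a validation phase and a test phase (order
  preserved so within-session drift stays realistic).
* **cross_session_case2** — train and validate (stratified 80/20) on
  session 1 only; all of session 2 is the test set.
* **two_session** — both sessions pooled, stratified 10-fold CV with the
  same rotating-validation layout.

Session-2 trials never enter a training set in the cross-session
scenarios; `ScenarioSplit.check_no_leakage` asserts disjointness and the
session rule programmatically and runs inside `make_splits`. Fold
accuracies are aggregated as mean and sample SD (n-1; a single fold
reports SD 0). `paired_ttest` provides the two-sided paired t-test with
the Pearson correlation of the paired vectors for cross-subject
comparisons.

## Synthetic data

The generator emulates the regime of a two-class (optionally four-class)
MI study: 250 Hz, 4-s trials, 200 trials per session, one or two sessions,
the 20-channel motor montage. Each trial is:

* per-channel 1/f background noise (spectrally shaped white noise,
  exponent 1, RMS `background_amp` = 10 uV),
* ongoing mu (10 Hz +- jitter, 10 uV peak) and beta (20 Hz +- jitter,
  5 uV peak) oscillations with random phases and a slow (0.1-0.5 Hz,
  depth 0.3) amplitude envelope,
* ERD: the oscillation *power* over the hemisphere contralateral to the
  imagined hand is multiplied by `1 - erd_depth` (amplitude by its square
  root). At `erd_depth = 0` the class label has no effect on the
  distribution. Four-class mode attenuates midline beta ("feet") and
  global mu ("tongue") — a documented toy convention, not physiology.
* per-subject channel gains (SD 0.1), and for session 2 a per-channel gain
  jitter (SD 0.2) plus a mu centre-frequency shift (SD 0.5 Hz) emulating
  between-day drift.

What the generator does **not** emulate: volume conduction and realistic
spatial mixing, ocular/muscle artifacts, non-stationarity within a
session, 1/f knee behaviour, or realistic class overlap. Passing the
simulation study therefore shows that the implementation can recover a
known lateralised band-power contrast end to end — not that it attains any
particular accuracy on real recordings.

## Desk-scale protocol

The published protocol is GPU-scale. For CPU-sized runs (the simulation
study in `scripts/acceptance.py` and the heavier tests) the package
freezes one reduced protocol in `lgct.presets`: the four hand-area
electrodes C3/C4 and CP3/CP4; decimation 250 -> 125 Hz (beta stays
below Nyquist; 125 is the largest integer divisor of 250 that allows the
13-32 Hz band); the `small_config` architecture (4 temporal filters,
kernel 13, embedding 8, growth 4, reduction 8, dropout 0.25); Adam at
1e-3 for at most 30 epochs with patience 10; and 5-fold (rather than
10-fold) within-session CV, i.e. 120/40/40 train/validation/test trials
per fold of a 200-trial session. These are package-level design choices
for the simulation study; the full-scale defaults remain the reference
configuration.

## Numerical choices

* Softmax is stabilised by row-max subtraction; masked score positions
  receive an additive -1e30, which underflows to exactly zero weight.
* Every attention row over an all-masked set is a construction error
  (masks must allow the diagonal), not a NaN.
* Argmax ties in prediction break to the lowest class index.
* Checkpoints store parameters and batch-norm statistics in a flat
  little-endian binary with a JSON index (name, shape, dtype, offset);
  `load(save(m))` reproduces outputs bit for bit.
* The trials-bundle fixture format is `manifest.json` plus a flat
  little-endian `data.bin` (float32 by default, float64 supported);
  round trips are bit-exact in the stored dtype.

## Known limitations

* Filter family/order for the band-pass stage and several architecture
  constants (kernel sizes, filter counts, pooling, embedding width) are
  not uniquely determined by the published description; the reference
  values here follow shallow-CNN conventions for MI-EEG (0.1-s temporal
  kernel etc.) and are all config knobs. No claim is made that the
  reference configuration reproduces any externally reported parameter
  count.
* The numpy engine trains small models at CPU scale only.
* GDF and BrainVision readers are out of scope; real data enters via EDF
  (`preprocess.read_edf`, requires `mne`) or the trials-bundle format.
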