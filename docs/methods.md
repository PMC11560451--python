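# Methods

`seizuregraph` classifies 3-second windows of 22-channel scalp EEG as ictal
(during a seizure) or interictal. Channels are treated as nodes of a graph;
three complementary adjacency structures feed three graph-convolutional
branches whose outputs are fused by a separable multi-head attention block
and a small convolutional classifier. This note documents the model, the
preprocessing and evaluation protocols, the synthetic data the package is
validated on, and the numerical and design choices that were genuinely
open.

## Signal model and preprocessing

Input is a continuous recording `X ∈ R^{n×T}` (n = 22 bipolar derivations
of the 10–20 system, sampling rate 256 Hz) with annotated seizure
intervals. Preprocessing:

1. **Channel selection.** Channels are matched case-insensitively (with
   whitespace and `-0`/`-1` duplicate suffixes normalized and T3/T4/T5/T6
   aliases unified) and reordered to the fixed 22-derivation longitudinal
   montage (FP1-F7 … FT10-T8). A missing derivation is an error, never a
   zero-fill.
2. **Band-pass 0.5–70 Hz**, fifth-order Butterworth. The application scheme
   is forward–backward (`sosfiltfilt`), i.e. zero-phase with the magnitude
   response squared; this is standard offline-EEG practice and avoids phase
   distortion at the cost of doubling the effective order.
3. **Windowing.** 3-s windows; ictal stretches are windowed with 50 %
   overlap (stride 1.5 s) to oversample the rare class, interictal
   stretches without overlap. A window is labeled ictal only if it lies
   entirely inside a seizure interval ([onset, offset), half-open);
   windows that would straddle a boundary are not generated, avoiding
   label noise.
4. **5:1 rebalancing.** All ictal windows are kept; the interictal pool is
   subsampled (seeded, without replacement) to at most five per ictal
   window.

## Graph construction

Three n×n adjacencies, all with zero diagonal (the single self-loop is
added by the GCN normalizer, preventing double self-connections):

* **Spatial distance** `A1`: each derivation sits at the midpoint of its
  two electrodes on a standard top-view head schematic (unit head circle,
  circumferential electrodes at the textbook 36° spacing, FT9/FT10 on an
  inferior ring at radius 1.2; coordinates are unitless — only relative
  geometry matters). Pairwise Euclidean distances are normalized by the
  maximum distance, the kernel bandwidth δ is the population standard
  deviation of the normalized unique-pair distances, and
  `A1_ij = exp(−d_ij² / (2δ²))` for `d_ij ≤ R1`, else 0 (default
  R1 = 0.4). The `2δ²` heat-kernel convention is the default; a flag drops
  the factor 2. Note the montage reuses one electrode pair in two chains
  (T7-P7 and P7-T7), so one coincident node pair with weight 1 is
  expected, not a bug. Distance normalization to [0, 1] is what makes an
  R1 grid of 0.2–0.7 meaningful.
* **Functional connectivity** `A2`: Pearson correlation between channel
  feature vectors, affinely mapped to [0, 1] via `(ρ+1)/2` (an `|ρ|`
  alternative sits behind a flag), thresholded at R2 (default 0.25). In
  the model the correlation is computed per segment on the intrachannel
  extractor's output (not the raw window) and carries no gradient; a fixed
  per-fold adjacency can be supplied instead.
* **Adaptive graph** `A3`: a free n×n parameter (i.i.d. uniform(0, 1/n) at
  initialization, no symmetry imposed) learned by backpropagation. Before
  use it is standardized over all entries (population std, ε = 1e-5 guard),
  passed through a learnable scalar affine (identity at init) and ReLU —
  keeping it nonnegative and well-scaled even when the raw matrix is
  constant. Because the parameter has no batch axis this whole-matrix
  standardization is the natural reading of "batch normalization" here and
  behaves identically at train and eval time.

## Network

* **Intrachannel extractor**: k = 2 depthwise convolutions, kernel (1, 2),
  stride 2, no padding and no cross-channel mixing, turning a (22, 768)
  window into graph signals N of shape (22, 192). Depthwise structure
  guarantees channel independence (perturbing one channel changes only its
  own row), which the test suite verifies by finite differences.
* **GCN branches**: three structurally identical branches with unshared
  parameters, one per adjacency. Each of m = 2 layers computes
  `BN(ReLU(D̃^{−1/2}(A+I)D̃^{−1/2} H Θ))` with width P (package default 64).
  BN is per-feature over batch × nodes, so it preserves node-permutation
  equivariance.
* **Separable attention**: the branch outputs are stacked into
  Z ∈ R^{b×n×P} (b = enabled branches). Three unshared 1×1 convolutions
  over the branch axis produce Q (h maps), K and V (h·d maps each),
  default h = 3 heads of dimension d = 1. Per head, a softmax over the
  flattened n·P positions of Q yields context scores; their weighted sum
  of K is a single context vector, broadcast-multiplied with ReLU(V) —
  cost linear in n·P rather than quadratic (the analytic MAC counter in
  `attention_flops` is exactly linear in P, and tested to be). Heads are
  concatenated, fused by a 3×3 convolution + BN + ReLU, added residually
  to Z, and BN'd again. The softmax axis and the operator order in the
  gating product are genuinely open choices; this package follows the
  separable-attention semantics of the mobile vision transformers that
  inspired the design: softmax over positions, then
  `ReLU(V) ⊙ Σ(softmax(Q) ⊙ K)`.
* **Classifier**: two 3×3 conv + ReLU layers (16 then 32 maps, shape
  preserved), global average pooling, dropout 0.5 (train only), a linear
  layer to 2 units and an element-wise sigmoid. The decision is the argmax
  over the two unit probabilities; an exact tie resolves to interictal.

The head geometry deserves one remark: a constraint tying d to the branch
axis (d = m/h with m = 3 branches) would force h ∈ {1, 3}; because that
appears to be an inconsistency rather than a design intent, h and d are
independent configuration fields (defaults h = 3, d = 1).

## Training

Loss is binary cross-entropy on the ictal-unit probability, clamped to
[1e-7, 1−1e-7]. By default the same form is summed over both output units
with one-hot targets (`two_unit_ce = True`): with single-unit CE the
interictal output unit never receives gradient and remains an untrained
random projection, which measurably injects noise into argmax decisions;
the single-unit form remains available for exactness. The l2 penalty
τ‖Ω‖ over all parameters is realized through Adam's decoupled weight decay
(1e-3) rather than an explicit loss term, avoiding double regularization;
an explicit global-norm term can be enabled via `tau`.

Optimization: Adam, lr 3e-4, weight decay 1e-3, batch size 64 (32 in the
scaled studies). Every epoch draws a fresh class-balanced subset of the
training indices — all ictal windows plus an equally sized random draw of
interictal ones — so every batch stream is balanced (audited by the
tests). Early stopping monitors validation loss with patience 10 and
restores the best-epoch weights including BN running statistics. At lr
3e-4 and desk-scale step counts there is a conditioning plateau of roughly
eight epochs before the loss moves; patience below that window would stop
inside the plateau, which is why the default patience is not lower.

Everything is seeded: one global seed fans out to named per-stage
substreams (SHA-256 of `seed:stage`), so simulation, rebalancing, fold
initialization and per-epoch resampling are each independently
reproducible. On a single CPU thread repeated runs are bit-identical.

The network and its training loop run on a small reverse-mode automatic
differentiation engine over NumPy written for this package
(`autodiff.py`): a tape of primitive operations (broadcast arithmetic,
matmul, indexing, reductions, ReLU/sigmoid/exp/log, an im2col 2-D
convolution) from which all layers are composed. Gradients of every
primitive and of the trainable adjacency path are verified against central
finite differences in the test suite. All computation is float64.

## Evaluation protocols

* **Patient-specific**: stratified 5-fold over one subject's segments;
  fold i is the test set, the next fold the validation set, the remaining
  three train. Rebalancing to 5:1 happens before splitting (a flagged
  alternative applies it after).
* **Patient-independent**: leave-one-subject-out; each patient in turn is
  the test set, one randomly chosen (seeded) held-in patient serves as the
  validation set for early stopping, the rest train.

Metrics: accuracy, sensitivity (ictal recall), specificity, F1 and ROC
AUC, the latter by the rank (Mann–Whitney) formulation with ties counting
½, computed from the ictal-unit probability. Metrics whose denominator is
empty are reported as NaN and flagged, never as 0. Tables print one row
per fold/case plus a mean row, in percent with two decimals.

## Synthetic data

The generator emulates the statistical structure this pipeline is
sensitive to, not the physiology of EEG. Interictal background is pink
noise (spectral slope ≈ −1, flattened below a small knee so short-window
statistics are well behaved) mixed with a shared component at weight
`background_corr` (default 0.2) — giving a controllable baseline pairwise
correlation. Seizures add a frequency-modulated sinusoid (center frequency
default 6 Hz, ±10 % smooth jitter, random phase per seizure, 0.5-s
cosine on/off ramps): a fraction `ictal_sync` (default 0.8) of the added
power is a rhythm common to all channels, the rest is independent
band-limited noise. The added amplitude is `(ictal_gain − 1)` times the
background RMS — so `ictal_gain = 1` adds exactly nothing (the degenerate
no-effect control) — scaled per channel: 1.0 on a focal subset (default
the left temporal chain), 0.4 elsewhere. Amplitude units are arbitrary
(nominal µV); no calibration is attempted.

Defaults were chosen as what a practitioner would call a clearly visible
scalp seizure: theta-band rhythm, threefold focal amplitude, strong
synchrony against a weakly correlated background. Cohorts perturb
frequency and gain per patient by a relative uniform factor and redraw the
focal subset.

What passing tests on this data do show: the pipeline's stages are
individually correct, the graphs encode the synchrony contrast, and the
model can learn to separate the two classes end to end from realistic
window counts. What they do not show: robustness to artifacts
(eye-blink/EMG), spike-wave morphology, inter-patient drift of real EEG,
or any clinical performance level — real-data results require the real
corpus and are out of scope here.

## Scaled studies (what `scripts/acceptance.py` runs)

Full-corpus training is far outside a desktop budget, so the package's
end-to-end claims are validated on scaled surrogates whose sizes are
stated here as the package's own choices:

* **Patient-specific study**: one 20-minute recording with six 40-s
  seizures (gain 3, synchrony 0.8), 5-fold patient-specific training,
  three model/training seeds — 15 fits of a width-32 model (the narrower
  width keeps a fold's training under ~20 s on one CPU core and
  conditions slightly better than 64 at this scale), 15 epochs, batch 32.
  Reported: mean held-out accuracy, sensitivity, specificity, F1, AUC.
* **Ablation study**: on the same segments and fold, the full model versus
  the three single-branch variants (distance / connectivity / adaptive
  only), three seeds each; reported as best-epoch validation accuracy per
  variant.
* **LOSO study**: three synthetic patients (8 min, three seizures each,
  15 % parameter variability), leave-one-subject-out; reported as mean
  test accuracy and AUC.
* **Graph diagnostics**: edge count and mean weight of the canonical
  distance graph at R1 = 0.4 (deterministic).

## Known limitations

* The EDF writer emits plain EDF (16-bit, one-second records); seizure
  annotations travel in a TSV sidecar, not an EDF+ annotation channel.
* The electrode schematic is a 2-D top-view approximation; absolute
  distances are not anatomical.
* Per-segment connectivity graphs make inference cost grow with the
  correlation computation; a per-fold averaged adjacency is available but
  changes the model's inductive bias.
* The engine is CPU/float64 only; wall-clock cost, not memory, bounds
  problem sizes.
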