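# Methods

This note records the models, the numerical choices, and the points where
the design was genuinely open, so that results produced with `ppgqc` can be
interpreted and reproduced.

## The task

Five-second PPG segments carry a quality class: 1 (good — clear trendline,
little interference), 2 (fair — usable despite moderate noise), 3 (poor —
too noisy for analysis).  Classes 2 and 3 are merged, and the classifiers
solve the binary problem *good* (label 1) versus *fair/poor* (label 0).
The positive class for all metrics is *good*.

## Preprocessing

Four stages, applied in order to each segment independently:

1. **Anti-aliased downsampling.**  The source rate must integer-divide the
   target rate; the default 512 → 128 Hz (factor 4) keeps the
   post-decimation Nyquist frequency (64 Hz) above the 50 Hz filter cutoff,
   which is what makes the downstream low-pass realizable.  Decimation uses
   an order-8 Chebyshev-I anti-aliasing filter applied forward-backward
   (scipy's `decimate`), preserving peak/trough timing.
2. **Moving average.**  Centred window, truncated at the edges (the window
   shrinks to the available samples, so output length is unchanged).
   Default 5 samples at 128 Hz (~39 ms): enough to suppress sample noise
   without flattening a ~0.1 s systolic peak.  The window must be odd.
3. **Butterworth low-pass.**  Cutoff 50 Hz, order 4, zero-phase
   (forward-backward) by default.  A single pass has gain 1/√2 at the
   cutoff; the zero-phase double pass squares the magnitude response (gain
   1/2 at the cutoff) and removes phase distortion.  Since neither the pass
   convention nor the order is intrinsic to the task, both are exposed in
   `PreprocessConfig`.  Note that the digital (bilinear-transform) design
   matches the analog magnitude 1/√(1+(f/f_c)^{2n}) only well below
   Nyquist; near Nyquist, frequency warping attenuates faster than the
   analog formula predicts.
4. **Min-Max scaling**, per signal, onto [0, 1].  Per-signal (rather than
   dataset-global) scaling makes each segment scale-free, which is the
   point of the stage; it also means absolute amplitude cannot be used as a
   feature.  A constant signal maps to the lower bound with a warning
   rather than dividing by zero.

Only stage 1 changes the signal length; 5 s × 128 Hz = 640 samples enter
the classifiers.

## Classifiers

All three networks output a scalar; probabilities are obtained through a
sigmoid.  Internally the networks are logit machines — the sigmoid is fused
into the loss for numerical stability, and `predict_proba`/`scores` apply
it at inference (clipped to the open interval so saturated logits still
yield probabilities strictly inside (0, 1)).

### CNN-LSTM

conv(1→8 channels, kernel 15, stride 4) → batch-norm → 2 × bidirectional
LSTM (hidden 56 per direction) → global average pooling over time → dense
[112, 64] with ReLU → dense → 1.  Total: 124,929 trainable parameters.

Structural choices not dictated by the selected hyperparameters (kernel 15,
hidden 56, head [112, 64]):

* **Stride 4 in the convolution.**  It cuts the recurrent sequence from
  626 to 157 steps.  This is a compute choice; the parameter count is
  stride-independent.
* **Two LSTM layers, bidirectional.**  A single-layer network would carry
  fewer parameters than the CNN-KAN, inverting the documented complexity
  ordering of the three families (MLP < KAN < CNN-LSTM); the stacked
  bidirectional form restores it and feeds the [112, 64] head a
  112-dimensional pooled feature, matching the head width.
* **LSTM bias convention:** one bias vector per direction (a second,
  torch-style bias is redundant at inference and would only double-count
  parameters).  Forget-gate biases start at 1.

### CNN-MLP

conv(1→5 channels, kernel 5) → max-pool 4 → average across channels →
dense [100, 50, 25, 10] with ReLU → dense → 1.  The pooled sequence length
is 159, giving 22,626 trainable parameters.

### CNN-KAN

Same trunk as the CNN-MLP; the head is two Kolmogorov–Arnold layers
[159 → 80 → 1].  Each edge (j, i) carries an activation
φ_{j,i}(t) = Σ_m c_{j,i,m} B_m(t) over a shared spline space with grid
G = 3, degree k = 5 (basis size G + k = 8), so the head holds
80·159·8 + 1·80·8 = 102,400 coefficients; with the trunk, 102,430
trainable parameters.

KAN-specific choices:

* **Pure spline edges.**  No residual base function (e.g. a SiLU term) and
  no per-edge scaling parameters are added; the activation is exactly the
  spline combination.  Implementations in the wild often add 1–2 extra
  parameters per edge; with such a +2-per-edge parameterization this head
  would count 127,200 extra-plus-coefficients parameters instead — worth
  knowing when comparing parameter counts across KAN codebases.
* **"Order" means polynomial degree** (k = 5 ⇒ degree-5 pieces); "width"
  means the hidden layer size (80), the standard usage.
* **Spline domain.**  Standalone spline layers default to [0, 1] (matching
  Min-Max-scaled inputs); inside the CNN-KAN the layers use [−1, 1]
  because the conv/pool trunk emits roughly zero-centred features.  Inputs
  outside the domain are clamped to the boundary — the bounded-domain
  premise of the Kolmogorov–Arnold representation — with zero input
  gradient there (coefficient gradients remain, via the boundary basis
  values).
* **Initialization:** coefficients drawn i.i.d. normal with sd 0.1, so
  initial edge functions are near zero.
* Dynamic grid refinement during training is deliberately not implemented.

### Parameter counting

`count_trainable_parameters` sums the sizes of all trainable tensors:
conv and dense weights and biases, batch-norm affine terms (γ, β), LSTM
matrices and biases, and spline coefficients.  Batch-norm running
statistics are buffers, not parameters.  The count is additive over layers,
and the family ordering **22,626 (MLP) < 102,430 (KAN) < 124,929
(CNN-LSTM)** holds for the defaults.  The unstated structural details
(channel counts, strides, layer multiplicity) are this package's own
completions; the counts above are exact properties of these completions,
not of any other implementation.

## Training

* Loss: binary cross-entropy with probabilities clipped to
  [10⁻⁷, 1−10⁻⁷].
* Optimizer: Adam (lr 10⁻³, β = (0.9, 0.999), ε = 10⁻⁸), batch size 32.
  Learning rate and batch size are conventional for datasets of a few
  hundred to a few thousand segments.
* Early stopping: at most 200 epochs, patience 50.  "Improvement" means a
  strictly lower validation loss; ties do not reset the counter.  The
  returned model always carries the weights of the minimum-validation-loss
  epoch (validation loss is computed in inference mode after each epoch).
* Splitting: stratified 40/30/30 train/validation/test on the binary
  label, deterministic per seed, per-class proportions within one sample
  of the global ones.
* Grid search trains every configuration once (single seeded run per
  configuration), ranks by validation AUC, and breaks ties by fewer
  trainable parameters, then enumeration order.  A configuration that
  fails to train is recorded on the leaderboard and skipped.
* Decision threshold for accuracy/precision/recall/F1: 0.5.  Ratios with a
  zero denominator evaluate to 0 with a warning.  AUC integrates the
  empirical ROC with the trapezoidal rule over distinct score thresholds,
  which equals the Mann–Whitney pair-counting statistic with ties counted
  half.
* Reproducibility: every stochastic component (generation, splitting,
  initialization, batch shuffling) is a pure function of its seed.

## Synthetic data

The generator emulates the statistical structure the classifiers must
separate, not the physiology of any device's output:

* **Clean morphology:** each beat is two Gaussians — systolic (amplitude
  1.0, centred at 25% of the period, width 9% of the period) and dicrotic
  (amplitude 0.3 at 55%, width 14%) — with the per-beat period jittered
  ±3% uniformly.  Heart rates are drawn uniformly from 50–110 bpm.
* **Corruption modes** (strengths relative to the clean peak-to-peak
  range): additive white noise; sinusoidal baseline wander (~0.3 Hz,
  random phase); motion spikes placed by a Poisson process with
  exponentially decaying shape (τ = 20 ms) and random sign; symmetric
  clipping at a fraction of the corrupted signal's dynamic range.
* **Class strengths:** class 1 — noise sd 0.02; class 2 — noise 0.15 plus
  wander 0.35; class 3 — noise 0.4, wander 0.6, spikes (1.5/s, amplitude
  1.5) and clipping at 0.8.  These mirror the verbal class definitions
  (little / moderate / a lot of interference).  The boundaries are a
  design choice: they are *not* calibrated against any manually labeled
  device data, and results on this synthetic benchmark must not be read as
  performance on real recordings.
* A dataset seed expands into per-signal seeds through a counter
  (`SeedSequence((seed, index))`), so generation is order-independent and
  parallel-safe.

What the generator does **not** emulate: inter-subject morphology
variability, heart-rate variability structure beyond white jitter,
respiratory amplitude modulation, sensor transfer functions, or the
ambiguity of human labeling near class boundaries.  Consequently the
synthetic benchmark is much easier than real data — the default classes
are separable nearly perfectly — and passing it demonstrates that the
pipeline, gradients and training loop work, not that the models would
reach any particular accuracy on device recordings.

## Benchmark problem sizes

The standard synthetic benchmark used by the acceptance script and the
end-to-end test: 600 segments (300 good, 150 fair, 150 poor → 300 vs 300
after the merge) at 512 Hz, preprocessed to 640 samples at 128 Hz,
stratified 40/30/30.  Training epochs per family: CNN-LSTM 12, CNN-MLP 50,
CNN-KAN 50 (the recurrent model converges in a handful of epochs; the
feed-forward heads benefit from more).  All three families reach test AUC
≥ 0.99 on this benchmark across seeds.

## Known limitations

* The networks run on CPU in float64 numpy; training scales to thousands,
  not millions, of segments.
* The KAN layers use a fixed spline grid; inputs drifting far outside the
  domain saturate at the boundary.
* Metrics assume binary labels; the 3-class problem is only reached
  through the fixed merge rule.
* The dataset file format stores one signal per row and requires uniform
  segment length within a file.
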