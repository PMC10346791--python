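# Methods

## Scope and data model

The package classifies whole EEG recordings as normal or abnormal from
their leading fixed-length segment.  A `Recording` is a channels × samples
array in microvolts with a sampling rate, ordered electrode labels, and a
recording-level class label.  Class labels are never read from EDF headers;
they come from a sidecar manifest (`path,label` CSV) or from the simulator,
because label-in-directory conventions of clinical archives cannot be
assumed portable.  EDF is read through `mne`; a minimal in-package 16-bit
EDF writer exists for fixtures and simulator output (classic EDF, 1-s
records, per-channel physical scaling — quantization error is bounded by
(phys range)/65534 per channel).

Channel labels are normalized by stripping the `EEG ` prefix and
`-REF`/`-LE` suffixes, upper-casing, and mapping the modern temporal-chain
names T7/T8/P7/P8 to the legacy T3/T4/T5/T6.  The alias map is deliberately
restricted to those four: wider remapping (e.g. M1→A1) risks silently
mislabeling montage inputs.  Normalization is idempotent; unknown labels
pass through and are only rejected when the montage actually needs them.

## Preprocessing

The abnormal-detection profile (`tuab`) applies, in order: a fourth-order
Butterworth high-pass at 1 Hz; a 60 Hz IIR notch (Q = 30); the 20-channel
TCP bipolar montage; polyphase resampling to 250 Hz; extraction of the
first 60 s plus a time-reversed copy of the second 60 s; per-segment,
per-channel standardization.  The epilepsy-corpus profile (`tuep`) applies
a second-order 0.5–49 Hz Butterworth bandpass, keeps the first 30 channels,
resamples to 250 Hz, and uses the first 30 s without augmentation.

Choices worth stating explicitly:

* **Zero-phase filtering.**  All filters run forward–backward
  (`sosfiltfilt`/`filtfilt`), so the effective magnitude response is the
  squared single-pass response and no group delay is introduced.  Offline
  clinical review conventionally uses zero-phase filtering; the tests
  verify both the absence of lag and the squared attenuation against the
  designed transfer function.
* **TCP pair list.**  The 20 pairs are the standard TUH TCP chains
  (left/right temporal, left/right parasagittal, transverse) with the two
  ear-reference chains omitted — the unique standard variant with exactly
  20 derived channels.  Montage derivation is linear and commutes with
  filtering; both properties are tested.
* **Notch Q = 30.**  A second-order IIR notch needs a quality factor; 30
  gives a −3 dB width of 2 Hz at 60 Hz, narrow enough to spare the beta
  band.
* **Resampling length rule** is `round(n·target/fs)` with polyphase
  anti-aliasing; resampling at the native rate returns the input
  unchanged.
* **Segmentation** starts at sample 0, no sliding windows; a recording in
  [1×, 2×) segment lengths yields one segment.  The reversed copy is taken
  from the *second* segment interval so the augmented sample is genuinely
  new data, not a mirrored duplicate of the first.
* **Standardization is per segment, per channel** (zero mean, unit SD); a
  zero-variance channel gets a unit denominator and a warning rather than
  NaNs.  Per-segment rather than corpus-wide statistics make inference
  independent of training-set bookkeeping.
* The 30-channel selection of the `tuep` profile takes the first 30
  channels in recording order, and `tuep` data are resampled to 250 Hz for
  model-shape consistency; both are interpretation choices where the
  protocol is underspecified.

## Architecture

Gated layer: `z = tanh(conv_f(x)) ⊙ σ(conv_g(x))` with causal dilated
convolutions (left zero-padding of `(k−1)·d`, so position `t` never sees
the future — verified by perturbation probes).  A 1×1 convolution projects
the layer input to the filter count and is added to `z` to form the input
of the next layer; the *block* output is the unweighted sum of the gated
outputs of its layers.  There are no skip connections from layers to the
head; the accumulation-within-block plus residual-chaining design is the
point of the "modified" WaveNet.  Receptive field per block is
`1 + (k−1)·Σd`, confirmed in tests by delta-response probing.

Defaults (all `ModelConfig` fields, not constants): 32 filters, kernel 3,
pool factor 4, block dilations `[1..128]/[1..64]/[1..32]/[1..16]`, path-1
LSTM 64, window length 250 samples (1 s), window encoder LSTM 32, path-2
LSTM 64 with dropout 0.2, dense 16, softmax head.  With 20 input channels
and 60-s inputs this totals 244,882 trainable parameters, inside the
244,992 budget.  The budget is enforced at construction for the full
variant.

The "flipping" in path 2 is time-axis reversal: the windowing that follows
is temporal, so a channel-axis transpose would be dimensionally
inconsistent.  Attention uses a softmax so the channel weights are a
proper distribution (they sum to 1; uniform when the attention weights are
zero; permutation-equivariant — all tested).

Ablation variants: `baseline` = path 1 with its LSTM replaced by global
temporal averaging, no path 2; `ablation1` = path 1 with LSTM only;
`ablation2` = both paths with the path-1 LSTM replaced by averaging;
`ablation3` = path 2 alone; `full` = everything.  The closed-form counter
walks the same component list as the builder, and `build_model` asserts
the two agree, so parameter accounting cannot drift silently.

LSTMs follow the single-bias convention (`4·((in+units)·units + units)`
parameters) and contribute their final hidden state.  Initialization:
Glorot-uniform convolutions and dense layers, orthogonal recurrent
kernels (per-gate square blocks), zero biases.

## Numerical core

There is no external deep-learning framework dependency: the network runs
on a small reverse-mode autodiff engine over numpy arrays
(`eegwavenet.autodiff`).  Convolutions are evaluated as `k` shifted
matrix products (im2col), the LSTM backward is a hand-written BPTT
specialized to final-state outputs, and float32 is the default compute
dtype (float64 is used in gradient tests).  Every operation's gradient,
and the end-to-end gradients of each model variant, are checked against
central finite differences at 1e-5–1e-6 relative tolerance.  Softmax and
cross-entropy use max-subtraction and a 1e-12 probability floor.

## Training protocol

70/30 stratified split — stratified over classes at the *source-recording*
level, so a segment and its time-reversed twin never straddle folds (a
leakage guard).  Balanced batches of 17: the majority class is chunked
from a per-epoch shuffle (each sample seen at least once per epoch), the
minority resampled with replacement, per-batch class counts differing by
at most one; the optimizer therefore sees a 0.5 class prior regardless of
corpus imbalance.  Adam starts at 1e-3; after 5 epochs without validation
improvement the rate is halved, floored at 1e-4 (decay factor and plateau
patience are conventional choices satisfying the 1e-3 → 1e-4 endpoints);
training stops after 10 epochs without improvement and the best epoch's
weights are restored.  Everything is seeded; two runs with the same seed
produce identical loss traces.

## The synthetic corpus

The generator emulates the statistical contrast the classifier exploits,
not biophysics.  Background activity per channel is a sum of band-limited
filtered Gaussian noise in the delta/theta/alpha/beta bands (relative
amplitudes 1.0/0.7/1.5/0.5 of a 10 µV base, alpha doubled on posterior
electrodes to mimic the posterior-dominant rhythm) plus 2 µV broadband
noise.  Abnormal recordings add: Poisson-timed spike-and-wave bursts
(6/min, 3 Hz repetition, 1–3 s duration, biphasic ~70 ms spike + slow
half-sine, scaled so the burst's 2–4 Hz RMS is 3× the local background's
2–4 Hz RMS — an in-band margin that keeps discharges detectable over the
slowed background; focal on a random
quarter of channels with probability 0.5, otherwise generalized); diffuse
slowing (×2.5 on delta/theta amplitudes); and a 0.7 right/left amplitude
ratio.  Event ground truth is logged.  Default rates/amplitudes were
chosen once as round numbers a reader of clinical EEG would accept as
"textbook" abnormal findings; with them the slowing statistic
(θ+δ)/(α+β) separates the classes with AUC ≈ 1, which the suite asserts
(≥ 0.9) before any training.

What the synthetic experiments therefore show: that the pipeline is
wired correctly end to end and that the architecture can learn a strongly
separable spectral/transient contrast quickly.  What they do not show:
performance on real clinical EEG, where class overlap, artifacts,
inter-rater ambiguity, and recording heterogeneity make the task far
harder.  Published accuracies on clinical corpora are not reproducible
here because those corpora are access-restricted; the package instead
verifies the *arithmetic consistency* of the published rate/count/accuracy
triples via `reconstruct_accuracy` (nearest-integer confusion counts,
since counts in a finite evaluation set are integers).

## Problem sizes used in tests

The end-to-end experiment trains the reduced reference configuration
(10-s segments, dilation schedules truncated at 32, 223,090 parameters)
on 120 synthetic recordings (seed 7; 240 segments after augmentation,
168/72 train/validation) and requires ≥ 90% validation accuracy within 30
epochs; in practice it converges in the first epochs, and training halts
once the threshold is met.  These sizes were chosen to keep a single-CPU
run comfortable while leaving the learning task non-trivial.

## Known limitations

* The EDF writer emits classic EDF only (integer sampling rates, whole
  seconds); it is a fixture/simulator utility, not an archival exporter.
* Evaluation is per-segment on the first segment of each recording;
  multi-segment voting is out of scope.
* No artifact rejection or ICA — the pipeline deliberately mirrors a
  raw-input design.
* The numpy compute core is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not corpus-scale training.
* Determinism is guaranteed within a fixed BLAS/thread configuration;
  across platforms, bit-level traces may differ while remaining
  statistically equivalent.
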