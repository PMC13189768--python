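# Methods

`pulseforge` estimates the blood-volume-pulse (BVP) waveform, and from it the
heart rate (HR), from short clips of facial video. This note documents the
model, the training objective, the synthetic data the package is validated
on, and the numerical and design choices a maintainer would want to know.

## Problem setting

Cardiac activity modulates skin color by a fraction of a percent of the pixel
dynamic range, concentrated in well-perfused regions (forehead, cheeks) and
strongest in the green channel. The modulation is buried under sensor noise,
illumination drift, and motion — the signal-to-noise ratio of a single pixel
is far below one. An estimator therefore has to pool spatially, exploit
temporal quasi-periodicity, and suppress non-pulsatile structure.

## Network

The regressor maps a clip `X ∈ R^{D×C×H×W}` (pixels in [0, 1], `D` frames at
`fps` Hz) to a wave `ŝ ∈ R^D`. It has three parts.

### Multi-scale difference fusion stem

For temporal scales `s ∈ {1, 2, 3}` the stem forms difference streams

    Δs[t] = X[t] − X[t−s]  (t ≥ s),   Δs[t] = 0  (t < s),

keeping the original frames as a fourth stream. Differencing cancels static
appearance; using several scales samples the pulse derivative at several
effective lags, so at least one stream keeps a clean gradient of the pulse
under a given noise regime. Each stream runs through its own branch — two
stride-2 3×3 convolutions (C → C_mid → C_mid) with batch normalization and a
ReLU between them — giving per-frame maps of size `C_mid × H/4 × W/4`. Branch
outputs are regularized with whole-channel (2-D) dropout and combined with a
softmax over four learnable scalars (`w = softmax(δ)`, computed with max
subtraction so extreme logits cannot overflow), followed by a ReLU:

    out = ReLU( Σ_i w_i · f̃_i ).

Degenerate modes used by the ablations: `original_only` keeps only the
raw-frame branch; `fixed` keeps all four streams but fuses them with constant
weights (uniform 1/4 by default).

The branch architecture inside the stem is the minimal structure meeting the
`H/4 × W/4` output contract; the four branches and their batch-norm
statistics are independent, and dropout masks are drawn independently per
stream with survivor scaling `1/(1−rate)` at train time.

### SCOPE refinement blocks

Each block refines per-frame feature maps `X ∈ R^{B×C×Hm×Wm}` in three steps:

1. **Spatial-aware channel attention.** Viewing the map as `B×(Hm·Wm)×C`, a
   shared two-layer bottleneck MLP (C → C/r → C, ReLU inside, sigmoid out)
   yields a channel-weight vector at *every spatial location*:
   `X_chan = X ⊙ σ(MLP(X_perm))`. Pulse strength varies across the face, so
   per-location channel weighting preserves region-specific responses that a
   single pooled channel vector would average away.
2. **Large-kernel spatial attention.** Two consecutive channel-preserving 7×7
   convolutions with batch norm and ReLU produce a per-channel spatial map
   `A_spa ≥ 0` (no terminal sigmoid; a config switch can add one), and
   `X_spa = X_chan ⊙ A_spa`. The 49-pixel receptive field per layer spans
   distributed perfusion regions at the stem's resolution.
3. **Gated residual fusion.** A channel gate from global context,
   `g = σ(Conv1×1(ReLU(Conv1×1(GAP(X_spa)))))`, controls how much refinement
   enters the output: `X̂ = g ⊙ X_spa + X`. The identity path is always
   preserved; as the gate closes the block degenerates to a no-op, which
   bounds the harm refinement can do under severe noise.

Ablation variants swap exactly one design element: `channel_only`,
`spatial_only`, `no_gate`, and a standard CBAM block (shared-MLP channel
attention over average/max pooled descriptors, single 7×7 spatial convolution
over channel statistics) wrapped in the same outer residual for
insertion-point parity.

Choices the block's description leaves open, fixed here: the channel MLP uses
a ReLU between its two layers; the gate bottleneck reuses the channel
reduction ratio `r` (default 8); the gate pools the refined map `X_spa`
(pooling the raw input instead is available via `gate_input="input"`).

### Temporal backbone and head

The backbone is deliberately a plain, exchangeable temporal model behind a
narrow interface (frame-feature sequence in, wave out): after the stem and
each of the `stages` stride-2 convolution stages (channels doubling, one
SCOPE block after the stem and after each stage by default), per-frame global
average pooling produces one feature vector per frame.

Two token-construction choices make this backbone trainable at small step
budgets. First, the pooled conv features are augmented with *multi-scale
global color traces*: the per-frame spatial mean of each stem input stream
(the raw frames, and each difference stream when the stem uses them). The
whole-frame mean is a high-SNR, translation-invariant carrier of the
pulsatile color modulation — it is exactly the quantity classical
channel-combination methods operate on — and the difference-stream traces
cancel static appearance and slow illumination drift the same way the stem's
difference branches do. Because the traces follow the stem's mode, ablating
the stem to its original-frames-only form removes the difference traces
along with the difference branches. Second, each clip's token sequence is
standardized per channel over the frame axis (temporal instance
normalization): pooled convolutional features are dominated by static
appearance, which carries no temporal information; standardizing over time
removes it exactly, letting the temporal model spend its capacity on the
within-clip variation where the pulse lives.

A linear projection to `embed_dim`, learned additive position
embeddings, `depth` pre-norm transformer encoder blocks (full self-attention
over the D tokens, MLP ratio 4), a layer norm, and a linear head produce one
wave sample per frame.

## Training objective

The loss is a weighted hybrid of a time-domain and a frequency-domain term:

    L = α · (1 − ρ(s, ŝ)) + CE_freq(s, ŝ),      α = 0.2.

`ρ` is the sample Pearson correlation; the time term is scale- and
offset-invariant, so the network only has to match waveform shape. For the
frequency term the in-band (0.6–3.3 Hz) periodogram of the standardized
prediction — computed as an explicit DFT matrix product so the whole loss is
differentiable — is normalized to a distribution over bins,
`p_k = P_k / Σ_j P_j`, and the loss is `−log p[k*]` with `k*` the in-band
argmax bin of the ground-truth spectrum. Two alternatives were considered
and rejected: raw powers as softmax logits saturate (powers reach O(D²/2)
for unit-scale sinusoids) and are quadratic in amplitude near zero, which
stalls training from small-amplitude initializations; the ratio form is
amplitude-invariant, strictly positive off the optimum, and monotone in the
target-bin power. The spectral grid length `n_fft` defaults to the clip
length; training configurations may zero-pad (e.g. `n_fft = 4D`) to
supervise at finer frequency resolution than the clip's natural Rayleigh
limit — at D = 60, fps = 30 the natural grid is 30 BPM per bin, too coarse
to pin the rate.

Optimization uses AdamW (learning rate 9e-3 by default, weight decay 0.01),
batch size 4, a constant learning-rate schedule, no early stopping: the
final-epoch checkpoint is evaluated. Gradient clipping is off by default and
available as a max-norm option.

## Heart-rate readout and metrics

A wave's one-sided periodogram is computed on a grid zero-padded to 512
bins, and HR = 60 × the peak frequency within 0.6–3.3 Hz (ties toward the
lower frequency). Reference HR is read from the ground-truth wave through
the *same* readout, so prediction and reference share grid quantization.
No filter is applied before the readout: the in-band argmax already
restricts the band, and on short noisy waves the edge transients of a
zero-phase IIR pre-filter can inject low-frequency power that dominates the
spectrum and drags the argmax to the band edge (a failure mode measured
during development: filtered readout degraded held-out MAE by an order of
magnitude). A zero-phase 4th-order Butterworth band-pass (applied after
removing mean and linear trend) is still provided for the GREEN baseline
trace and for time-domain visualization, where actual signal cleaning — not
peak localization — is the goal.

Reported metrics over HR pairs: MAE, RMSE, MAPE, Pearson ρ, and the rPPG SNR
— the ratio (dB) of spectral power within ±0.1 Hz of the reference
fundamental and its first harmonic to the remaining in-band power, computed
with a Hann window so off-grid tones do not leak power out of the signal
windows. Bland–Altman statistics (bias and 1.96·SD limits of agreement)
accompany every report. ρ is computed over per-clip HR pairs.

## Synthetic data

The generator renders the signal structure of pulsatile facial video at
arbitrary size, with known ground truth:

* **Pulse wave**: `a(t)·[sin(2πf t) + 0.3·sin(4πf t + φ)]`, `f = HR/60` with
  HR ∈ [40, 180] BPM; `a(t)` is a lognormal slowly-varying amplitude
  (log-SD 0.1, ~1 s knot spacing) emulating beat-to-beat variability.
* **Face field**: a smooth skin-toned oval (skin RGB ≈ 0.72/0.55/0.45 with
  low-order shading) on a dark background.
* **Perfusion map**: two cheek blobs plus a forehead band (Gaussian), so the
  modulation is spatially structured rather than uniform.
* **Modulation**: peak pixel amplitude 1% of dynamic range, green-dominant
  channel gains (0.6/1.0/0.4).
* **Corruptions**: per-pixel Gaussian sensor noise (default SD 0.02),
  a global illumination drift sinusoid (amplitude 0.01, 0.1 Hz), and an
  integer-pixel bounded random walk (±1 px) for translational jitter —
  integer shifts keep interpolation out of the ground-truth path.

Subjects draw one base HR each (clips vary by ±1.5 BPM around it), so
subject-level split protocols are meaningful. All randomness derives from a
single seed through `default_rng([seed, subject, clip])` spawning.

What the generator does **not** emulate: photorealistic appearance, skin-tone
optics, waveform morphology (dicrotic notch), rotation or non-rigid motion,
specular highlights, and compression artifacts. Passing tests on this data
shows the pipeline recovers a spatially-structured quasi-periodic modulation
under additive noise, drift, and translational jitter — not that it matches
benchmark performance on real corpora.

## Desk-scale study conditions

CPU-scale runs used by the test suite and the acceptance script:

* clips 32×32 pixels, D = 60 frames at 30 fps; stem width C_mid = 16;
  stages = 2; embed_dim = 96, 4 heads, transformer depth 4;
* training corpus 160 clips (40 subjects × 4 clips), held-out test set of
  40 clips from 10 unseen subjects; HR ∈ [50, 150] BPM, noise SD 0.02,
  jitter ±1 px; 5 epochs, batch 4, learning rate 3e-3; spectral loss on an
  `n_fft = 240` (4×D) zero-padded grid;
* the ablation comparison (full stem vs original-frames-only) runs the same
  recipe over three seeds and compares seed-averaged MAE.

These sizes are the package's desk-scale choice: large enough for the
qualitative claims (sub-5-BPM held-out MAE, multi-scale differences
outperforming single-stream input under noise), small enough to run on one
CPU core in minutes.

## Numerical notes

* All network arithmetic is float32; reductions used in metrics are float64.
* Softmax and log-softmax use max subtraction; at logit spreads beyond ~80
  the smaller weights underflow float32 to exact zero (the mathematical
  positivity is preserved up to representability).
* Batch-norm running statistics use momentum 0.1 and the unbiased variance
  correction; eval mode uses them verbatim.
* The spectral-loss target bin uses the lowest-frequency bin on ties
  (argmax convention), matching the HR readout's tie-break.
* Degenerate inputs: constant waves are rejected by the Pearson loss
  (zero-variance error) and flagged invalid by the evaluation harness rather
  than aborting the run; clips shorter than the largest difference scale are
  rejected at stream construction.

## Known limitations

* The temporal backbone is a stand-in by design; results transfer to other
  backbones only through the shared interface, not architecturally.
* The spectral loss supervises only the peak bin, not the full spectral
  shape; harmonically rich predictions can sit near the optimum as long as
  the fundamental dominates in band.
* Training at desk scale is sensitive to initialization seed; the acceptance
  runs average ablations over seeds for that reason.
* Real-data effects (rigid/non-rigid motion, lighting spectra, compression)
  are out of the generator's scope; no claim is made about benchmark
  numbers on PURE/UBFC-rPPG/MMPD-class corpora.
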