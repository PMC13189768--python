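# pulseforge

Remote photoplethysmography (rPPG): estimating the cardiac blood-volume-pulse
(BVP) waveform — and from it the heart rate — from plain facial video, no
contact sensor required. Cardiac activity modulates skin color by well under
1% of the pixel range, buried beneath sensor noise, illumination drift and
motion; `pulseforge` is a tested, CPU-only implementation of a deep
estimator built for exactly that low-SNR regime, together with a synthetic
pulsatile-video generator so every stage runs and is verified without
dataset downloads or a GPU.

It is aimed at researchers and students who want a transparent, hackable
rPPG stack: every component — including the reverse-mode autodiff the
network trains with — is plain numpy/scipy inside this package.

## The model

A clip `X ∈ R^{D×C×H×W}` (D frames) is mapped to a wave `ŝ ∈ R^D`:

1. **Multi-scale difference fusion stem.** Zero-padded frame differences
   `Δs[t] = X[t] − X[t−s]` for `s ∈ {1,2,3}` plus the raw frames form four
   streams; each passes its own convolutional branch (down to `H/4 × W/4`),
   and branch outputs are fused with learnable softmax weights
   `w_i = e^{δ_i} / Σ_j e^{δ_j}` followed by a ReLU. Differencing cancels
   static appearance; learning the fusion picks the temporal scale with the
   cleanest pulse under the current noise.
2. **SCOPE refinement blocks** (spatial-channel optimized pulse
   enhancement), interleaved with the conv stages:
   spatial-aware channel attention `X_chan = X ⊙ σ(MLP(X_perm))` applied
   per location, large-kernel spatial attention from two 7×7 conv layers
   `X_spa = X_chan ⊙ A_spa`, and gated residual fusion
   `X̂ = g ⊙ X_spa + X` with a global-context gate `g ∈ (0,1)` that bounds
   how much refinement can inject noise.
3. **Temporal transformer backbone** over per-frame pooled tokens
   (augmented with multi-scale global color traces and standardized over
   time), with a linear head reading out one wave sample per frame.

Training minimizes the hybrid objective `L = α(1 − ρ(s, ŝ)) + CE_freq`
(α = 0.2): negative Pearson correlation for waveform shape plus a
cross-entropy that concentrates the predicted in-band power spectrum on the
true spectral-peak bin. Heart rate is read out as 60× the in-band
(0.6–3.3 Hz) periodogram peak; evaluation reports MAE, RMSE, MAPE, Pearson
ρ and the rPPG signal-to-noise ratio, with Bland–Altman agreement limits.
All eight ablation variants from the design study (no-SCOPE, SCOPE-CBAM,
channel/spatial-only, no-gate, original-frames-only stem, fixed fusion)
are first-class configurations.

## Worked example

Train on synthetic pulsatile video and evaluate held-out heart-rate error
(about four minutes on one CPU core):

```python
import pulseforge as pf
from pulseforge.pipeline import TrainConfig
from pulseforge.losses import LossConfig

# 200 clips: 50 subjects x 4 clips, 60 frames of 32x32 at 30 fps,
# sensor noise SD 0.02, +-1 px motion jitter, HR in [50, 150] BPM
samples, manifest = pf.synth_dataset(
    50, 4, pf.SynthConfig(d=60, h=32, w=32, noise_sd=0.02, jitter_px=1,
                          hr_range=(50, 150)), seed=11)

model = pf.RPPGModel(samples[:160], config=pf.ModelConfig.desk_preset(d=60),
                     seed=0)
results = model.fit(TrainConfig(epochs=5, lr=3e-3, seed=0,
                                loss=LossConfig(n_fft=240)))
results.evaluate(samples[160:])
print(results.summary())
```

Output from this exact script:

```
Pulse-estimation model fit
========================================
stem: mode=full, c_mid=16, scales=(1, 2, 3), dropout=0.1
scope: variant=full x3 insertions (r=8)
backbone: 2 conv stages, transformer depth=4, embed=96, heads=4
clip_len: 60
parameters: 1,025,793
----------------------------------------
epochs: 5
train loss: 1.9177 -> 1.7066
----------------------------------------
held-out clips: 40
MAE     2.29 BPM
RMSE    3.14 BPM
MAPE    3.38 %
rho    0.995
SNR    -5.12 dB
Bland-Altman bias 1.05 BPM, LoA [-4.75, 6.86]
```

Held-out MAE of ~2.3 BPM against ground truth, with HR correlation 0.99:
the model recovers the pulse rate of unseen synthetic subjects to within a
couple of beats per minute under noise, drift and jitter. The classical
GREEN baseline (spatial mean of the green channel) on the same clips is the
package's sanity reference:

```python
from pulseforge.pulsesignal import estimate_hr, green_baseline
err = [abs(estimate_hr(green_baseline(s.clip), 30.0)
           - estimate_hr(s.bvp.wave, 30.0)) for s in samples[96:]]
```

A command-line interface mirrors the library
(`pulseforge synth | ingest | build | train | eval | ablate`); run
`pulseforge --help` for the verbs and options.

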