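# Methods

## Model and objective

The package trains a binary clinical-outcome classifier `f_θ` on log-Mel
spectrograms of single-channel heart audio and regularizes *where in the
spectrum* the model looks.  Attribution is gradient × input: for a batch,
the summed true-class logit `s = Σ_i z_{i,y_i}` is differentiated with
respect to the input, and `A = |∂s/∂X ⊙ X|`.  Summing `A` over time and
normalizing over four fixed mel bands gives a per-sample distribution
`p_i` on the 4-simplex; the regularizer is the batch-mean KL divergence
from `p_i` to the class prior `π(y_i)`, added to cross-entropy with
weight `λ_sca`.  Because samples are independent, the gradient of the
summed score with respect to sample `i`'s input equals the gradient of
that sample's own logit, so one backward pass attributes the whole batch
(verified against per-sample passes in the tests).

Assumptions worth stating plainly:

- **The priors are ordinal, not spectral truth.**  [0.7, 0.2, 0.1, 0] and
  [0.15, 0.35, 0.5, 0] encode "normal = low-frequency, murmur =
  mid-to-high, top band = noise", not measured energy ratios.
- **Band 4 has exactly zero prior mass in both classes.**  Any attribution
  there is penalized through the ε-guard (`log(p/ε)` can reach ~18 nats at
  ε = 1e-8).  The priors are deliberately not smoothed; this hard noise
  penalty is the intended mechanism and in practice dominates early
  training, which first drains the noise band.
- **Training requires second-order gradients.**  The loss depends on
  `∂s/∂X`, so its parameter gradient differentiates through a gradient
  (double backpropagation).  The `differentiable` flag on `SCAConfig`
  switches between the training-time higher-order graph and a detached
  evaluation artifact; `|·|` uses subgradient 0 at 0, and ReLU selection
  masks are treated as constants (second derivative zero almost
  everywhere).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_sca` | 0.3 | alignment weight; grid {0.05, 0.1, 0.2, 0.3, 0.5} |
| `epsilon` | 1e-8 | stability constant in the normalization and prior denominators (exactly where the definitions place it; no extra smoothing) |
| learning rate / weight decay | 1e-3 / 1e-4 | Adam, full-scale protocol defaults |
| batch size | 32 | unstated at full scale; configurable |
| window / hop / FFT | 50 ms / 25 ms / 256 | STFT at 2 kHz (win = 100, hop = 50 samples) |
| `n_mels`, range | 128, 25–1000 Hz | structural: the band partition slices 128 bins into 4 × 32 |
| `log_floor` | 1e-6 | natural log of (mel power + floor) |

KL uses natural logarithms throughout (values quoted in nats).

## Numerical and convention choices

- **Mel scale**: HTK (`2595·log10(1 + f/700)`); Slaney available via
  config.  The conventional Hz labels of the band edges (≈175/390/660 Hz)
  correspond to an HTK grid anchored at 0 Hz; with the 25 Hz filterbank
  floor the recomputed edges are ≈197/410/673 Hz.  The annotations are
  informational — the partition is defined on mel *indices*.
- **STFT**: Hann window, no centering, frames start at sample 0, so
  `T = ⌊(n − win)/hop⌋ + 1` exactly.  128 triangular filters on a 129-bin
  FFT grid leave some low-frequency filters empty; they output the log
  floor and a one-time warning rather than silently shrinking F.
- **Padding** is applied to spectrograms, not waveforms, and is exactly
  zero, which makes padded frames attribution-free (`G⊙X = 0` there) —
  no masking is needed anywhere downstream.
- **Resampling** is polyphase/windowed-sinc (anti-aliased); naive
  decimation would alias murmur-band energy.  Order: resample, then peak
  normalize, then log-Mel.
- **All-zero saliency rows** (a dead model) are left as near-zero band
  mass with a warning; renormalizing would hide the pathology.
- **Cross-entropy reduction** is the batch mean, matching the 1/B factor
  of the alignment term so the two losses share a scale.
- **Wrong priors** are the class-swapped clinical table — the minimal
  inversion under which the wrong abnormal prior puts its maximum weight
  (0.7) on band 1; arbitrary user tables are accepted for other
  inversions.
- **ΔKL>0 baseline pairing**: per-sample KL under the CE baseline minus
  KL under the evaluated model, on the shared ordered evaluation set.
- **McNemar**: exact two-sided binomial below 25 discordant pairs,
  continuity-corrected chi-square otherwise; bootstrap resamples
  recordings (not patients), 10,000 replicates, percentile 95% CIs.
- **Grid-search ties** break toward lower mean validation KL, then
  smaller λ.  Model selection reports the last epoch (fixed-epoch
  protocols).  SCA-long continues with the same optimizer state for its
  fine-tuning half (no restart).

## The synthetic generator

`synth.py` emulates just enough physiology to exercise every stage:
S1/S2 as Gaussian-enveloped tone bursts (carriers inside 20–150 Hz, S2 at
35% of the cardiac cycle, ±1% timing jitter), high-frequency band-limited
nuisance noise 15 dB below the heart sounds, and — for abnormal records —
a systolic band-limited noise murmur (200–600 Hz) at equal power to the
heart sounds, confined to the S1→S2 interval with a raised-cosine
envelope.  Records are 3–6 s at 60–100 bpm, deterministic per
`(seed, index)`, and an abnormal record shares its template with the
same-index normal record (murmur gain −∞ dB reproduces it exactly).

What it does **not** model: stethoscope transfer functions, pediatric
physiology, diastolic murmurs (config option, off by default), gallops,
splitting, real ambient noise.  Passing end-to-end tests therefore shows
the *mechanism* works — the regularizer reshapes attributions as intended
on data where the priors are approximately true — not that any accuracy
level carries over to clinical recordings.

## The desk-scale study

`study.py` is the package's headline computation, sized for a single CPU:
400 records (prevalence 0.5), 9:1 split, the small 3-block CNN, and 50
epochs at learning rate 3e-3 for every arm (CE baseline, prior-aligned
λ = 0.3, wrong-prior λ = 0.5).  The small CNN tolerates a higher learning
rate than the full-scale backbones, and the regularizer needs enough
optimizer steps for its second-order signal to reorganize the ReLU gating
— a conv-plus-global-pool network is translation-invariant along
frequency, so suppressing a band's attribution works through
data-dependent activation patterns rather than any per-frequency weight;
cleaning the last few percent of noise-band mass is the slowest phase
because the ε-guarded `log(p/ε)` gradient acts through those gates.
Both arms always share every hyperparameter, so arm differences isolate
the regularizer.  The wrong-prior arm uses the strongest grid value
because it demonstrates steering, which is what λ controls.  Training
runs in single precision (standard deep-learning practice; the engine's
`default_dtype` context); all evaluation metrics are computed in double
precision.

What to expect from the fidelity (sanity-check) arms: steering toward a
replacement prior succeeds wherever it does not conflict with
discrimination.  Under the class-swapped wrong priors the normal class
follows its new target closely and the noise band empties for both
classes, but abnormal-sample attribution keeps its murmur-band dominance
— the cross-entropy term needs that evidence, and the alignment loss
plateaus against it rather than inverting the physiological focus.  The
regularizer aligns explanations where physiology and discrimination
agree; it does not force a classifier to explain itself with features it
cannot use.

## Known limitations

- No heart-sound segmentation (S1/S2/systole detection); the priors are
  coarse band-level constraints only.
- Gradient × input on log-compressed features weights quiet bins by the
  magnitude of their log value; the floor (1e-6) therefore influences how
  much silent regions can attract attribution.
- The engine is NumPy on one CPU: desk-scale protocols train in minutes,
  but full-scale (thousands of recordings, 60 epochs, ResNet-18) is out
  of its intended range, and full-scale dataset results are
  correspondingly out of scope for the test suite.
- Uniform/wrong sanity checks rescore attributions; they do not by
  themselves certify clinical usability.
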