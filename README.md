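# cardialign

Prior-aligned frequency-band attribution for heart-sound classification.

Deep phonocardiogram (PCG) classifiers can reach high accuracy while
relying on spectral regions that make no physiological sense — equipment
noise, respiratory artifacts — which undermines clinical trust.
`cardialign` implements a training-time remedy: a **scale-consistent
attribution regularizer** that pushes the model's own explanation of its
decisions toward auscultation physiology, for anyone building or auditing
murmur-screening models on log-Mel spectrograms.

## The method

A record `x` (single-channel heart audio) becomes a log-Mel spectrogram
`X ∈ R^{1×T×F}` with `F = 128` mel bins over 25–1000 Hz, split into four
contiguous 32-bin bands: the S1/S2 fundamental zone (≈25–175 Hz), a
transitional zone (≈175–390 Hz), the murmur/pathological zone
(≈390–660 Hz), and a noise zone (≈660–1000 Hz).  Clinical consensus is
encoded as class-conditional band priors

    π(0) = [0.70, 0.20, 0.10, 0.00]   (normal)
    π(1) = [0.15, 0.35, 0.50, 0.00]   (abnormal)

During training, for each batch the model's saliency is computed by
gradient × input: with `s = Σ_i z_{i,y_i}` the summed true-class logits,

    A = |∂s/∂X ⊙ X|,    Ã_f = Σ_t A_{t,f},
    p_k = Σ_{f∈band_k} Ã_f / (Σ_j Σ_{f∈band_j} Ã_f + ε),

and the joint objective is

    L = L_CE + λ_sca · (1/B) Σ_i KL(p_i ‖ π(y_i) + ε).

Because the penalty is a function of an input gradient, optimizing it
requires second-order derivatives (double backpropagation); the package
ships its own compact NumPy reverse-mode autodiff engine with
higher-order gradient support, plus single-channel ResNet-18,
MobileNetV2, DenseNet-121, and a desk-scale small CNN built on it.

Also included: the full preprocessing chain (2 kHz resampling, peak
normalization, 50 ms/25 ms Hann STFT, dynamic zero-padding), the
CE-30/CE-60/SCA-long/SCA-all training protocols with λ grid search and an
L2-feature baseline, evaluation with bootstrap CIs and McNemar's test,
explanation metrics (KL, cosine, ΔKL>0 fraction, band masses), uniform
and wrong-prior sanity checks, a hard band-masking ablation, and a
synthetic PCG generator whose class structure matches the priors.

## Worked example

```python
import numpy as np
from cardialign import (SynthConfig, synth_records, prepare_record,
                        FeatureConfig, clinical_priors, make_band_partition)
from cardialign.training import RunConfig, run_protocol
from cardialign.evaluation import explanation_metrics, band_mass_report

recs = synth_records(SynthConfig(n_records=200, prevalence=0.5, seed=5))
data = [(prepare_record(r), r.label) for r in recs]
train, val = data[:180], data[180:]

ce,  _ = run_protocol(RunConfig(protocol="CE-60",  total_epochs=15), train, val)
sca, _ = run_protocol(RunConfig(protocol="SCA-all", total_epochs=15,
                                lambda_sca=0.3), train, val)

part, table = make_band_partition(), clinical_priors()
for name, model in [("CE", ce), ("SCA", sca)]:
    kl = explanation_metrics(model, val, table, part)["mean_kl"]
    print(name, {k: round(v, 3) for k, v in kl.items()})
```

Output from one run of the above (15 epochs at the full-scale learning
rate 1e-3):

```
CE {'normal': 1.463, 'abnormal': 2.018}
SCA {'normal': 1.226, 'abnormal': 1.699}
```

Both models classify the held-out synthetic records perfectly; the
regularized model's attributions are already closer to the clinical
priors, and the gap widens as training proceeds (see the desk-scale study
below, which trains longer at a learning rate suited to the small CNN).
`band_mass_report` shows where the mass goes: the regularizer drains the
noise band and shifts abnormal-sample attribution into the murmur bands.

## Command line

```bash
cardialign synth --n 400 --seed 7 --out data/
cardialign train --manifest data/manifest.csv --protocol SCA-all --lambda 0.3 --out runs/sca
cardialign gridsearch --manifest data/manifest.csv
cardialign evaluate --model runs/sca/model.npz --manifest data/manifest.csv \
    --prior clinical --mask none --out report.json
```

## Layout

- `src/cardialign/autodiff.py` — NumPy autodiff engine (double backprop)
- `src/cardialign/features.py` — WAV I/O, resampling, log-Mel, batching
- `src/cardialign/priors.py` — band partition and prior tables
- `src/cardialign/sca.py` — saliency, band aggregation, KL loss
- `src/cardialign/backbones.py` — CNN backbones (single-channel)
- `src/cardialign/training.py` — protocols, splits, grid search
- `src/cardialign/evaluation.py` — metrics, CIs, ablations
- `src/cardialign/synth.py` — synthetic PCG generator
- `src/cardialign/study.py` — the end-to-end desk-scale study
- `src/cardialign/cli.py` — the `cardialign` command-line interface
- `docs/methods.md` — modeling assumptions and design choices
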