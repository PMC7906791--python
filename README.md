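# slowosc

Prediction of the slow (<0.1 Hz) resting-state hemodynamic oscillation
with a recurrent network, validated against surrogate controls and a
linear baseline, and used as a brain-state index.

## The problem

Vessel-specific rs-fMRI time courses carry a coherent slow oscillation
(0.01–0.1 Hz in humans, 0.01–0.05 Hz in anesthetized rats) buried in
heavy noise. `slowosc` trains a gated recurrent unit (GRU) to predict the
band-limited oscillation **10 s into the future** from the raw trace:

    r(t) = σ(W_ir x(t) + b_ir + W_hr h(t−1) + b_hr)
    z(t) = σ(W_iz x(t) + b_iz + W_hz h(t−1) + b_hz)
    n(t) = tanh(W_in x(t) + b_in + r(t) ⊙ (W_hn h(t−1) + b_hn))
    h(t) = (1 − z(t)) ⊙ n(t) + z(t) ⊙ h(t−1),      y(t) = w_out · h(t)

The prediction score — Pearson correlation (CC) between prediction and
target over post-washout samples — is compared against IAAFT surrogate
controls (same amplitudes and spectrum, randomized Fourier phases: the
linear-statistics null) and an ARMAX baseline, and serves per session as
a brain-state index that relates global slow-fluctuation strength
inversely to intrinsic default-mode-network (DMN) correlation.

The package is aimed at researchers analysing slow hemodynamic dynamics
(vessel-resolved fMRI, ROI time courses) who need a reproducible
prediction pipeline with proper nulls, and at anyone who wants a
fully-seeded synthetic testbed for such pipelines. Everything — GRU
training included — runs in NumPy on one CPU.

## Worked example

```python
import numpy as np
from slowosc import (BandSpec, GRUForecaster, HUMAN_PRESET, iaaft,
                     make_target_pair)
from slowosc.evaluation import paired_fisher_test
from slowosc.synth import VesselTrialSpec, generate_vessel_trial

band = BandSpec(0.01, 0.1)

# 4 training + 4 held-out trials of 12 noisy vessels sharing a slow component
trials = [generate_vessel_trial(VesselTrialSpec(seed=s)) for s in range(8)]
pairs = [[make_target_pair(ts, band, shift=10.0) for ts in tr] for tr in trials]
train = [p for fold in pairs[:4] for p in fold]

results = GRUForecaster(train, HUMAN_PRESET).fit(params_init_seed=11)
print(results.summary())

real, control = [], []
for tr, fold in zip(trials[4:], pairs[4:]):
    for ts, pair in zip(tr, fold):
        real.append(results.predict(pair).cc)
        sur = iaaft(ts, seed=1).surrogate
        control.append(results.predict(make_target_pair(sur, band)).cc)
t, p = paired_fisher_test(real, control)
print(f"real CC {np.mean(real):.3f}  surrogate CC {np.mean(control):.3f}  "
      f"t = {t:.2f}, p = {p:.1e}")
```

Output from this exact script (seeds as shown):

```
GRU slow-oscillation forecaster
===============================================
layers                                        1
hidden size                                  88
loss                                         cc
learning rate                           0.00121
L2                                       0.0221
residual readout                          False
batch size                                   10
epochs                                       69
washout (samples)                           250
init seed                                    11
final training loss                     -0.3805
===============================================
real CC 0.399  surrogate CC 0.325  t = 7.31, p = 2.8e-09
```

The trained network predicts the real held-out traces clearly better than
their phase-randomized surrogates: the slow oscillation carries temporal
structure beyond its power spectrum, and the network exploits it. A
prediction's cross-correlation lag near 0 s means the model genuinely
anticipates the signal by the full 10 s rather than echoing the filtered
input.

The `slowosc` command-line tool exposes the same pipeline
(`slowosc simulate / surrogate / train / predict / cv / armax / classify`).

## Layout

| module | contents |
| --- | --- |
| `slowosc.timeseries` | `TimeSeries`, `TrialSet`, `SessionData`, `BandSpec`, delimited-text I/O |
| `slowosc.preprocess` | Welch PSD, frequency normalisation, zero-phase band-pass, resampling, 10-s target pairs, PSD FWHM |
| `slowosc.surrogate` | IAAFT surrogates and per-trial surrogate sets |
| `slowosc.gru` | the GRU forecaster (NumPy forward/BPTT/Adam), presets, cross-validation, random hyperparameter search, hidden-state PCA |
| `slowosc.armax` | ARMAX estimation (Hannan–Rissanen + prediction-error refinement), forecasting, simulation, order grid search |
| `slowosc.evaluation` | CC, cross-correlation lags, sliding-window scores, Fisher-z tests, BH-FDR |
| `slowosc.brainstate` | session scoring, percentile groups, difference maps, intrinsic-DMN index, binned curves, variance groups, spectral reordering, spectral probing |
| `slowosc.imaging` | vessel localisation on 2-D images, mask combination, time-course extraction, spatial ICA |
| `slowosc.synth` | seeded generators: vessel trials, network sessions, spectral probes, vessel images |
| `slowosc.study` | the canonical desk-scale experiment used by the acceptance script |

See `docs/methods.md` for the model details, the synthetic-data design
and its limitations, and all numerical conventions.
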