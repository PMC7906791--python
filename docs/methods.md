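# Methods

## The prediction problem

Resting-state hemodynamic recordings carry a slow oscillation — below
0.1 Hz in awake humans, below 0.05 Hz in anesthetized rodents — that is
strongest in vessel-specific (venous) voxels and tracks global brain-state
fluctuations. `slowosc` models the task of *predicting* that oscillation:
given the raw, noisy time course of one vessel up to time t, output the
band-limited slow component at t + 10 s. Prediction quality (Pearson CC
between prediction and target over post-washout samples) is then used in
three ways: to test whether the signal carries temporal structure beyond
its linear statistics (against IAAFT surrogate controls), to compare the
recurrent model against a classical linear system-identification baseline
(ARMAX), and as a per-session brain-state index.

## Preprocessing

Every trace is normalised by its high-frequency noise floor: the mean
Welch PSD above 0.2 Hz (1024-point DFT, Hann window of length 128, 50%
overlap) is computed, and the mean-removed trace is divided by the square
root of that mean. Power scales with the square of amplitude, so the
square root is what actually brings the high-frequency PSD to a unit
baseline; the convention makes the normalisation idempotent and scale
invariant, and a `literal_division` switch exists for comparison. The
same Welch settings are used everywhere a PSD is needed.

Targets are produced by a zero-phase Butterworth band-pass
(forward–backward `sosfiltfilt`, order 4 per pass) over 0.01–0.1 Hz
(human-like) or 0.01–0.05 Hz (rat-like), advanced by the 10 s prediction
interval. Zero-phase filtering means the target is time-aligned with the
input; the 10 s shift is therefore the entire prediction burden. Data at
other sampling rates (e.g. 0.72 s TR) are brought to 1 s by polyphase
resampling (anti-aliasing; linear interpolation available via config).

## The GRU forecaster

The predictor is a gated recurrent unit with reset gate r, update gate z
and candidate state n,

    r(t) = σ(W_ir x(t) + b_ir + W_hr h(t−1) + b_hr)
    z(t) = σ(W_iz x(t) + b_iz + W_hz h(t−1) + b_hz)
    n(t) = tanh(W_in x(t) + b_in + r(t) ⊙ (W_hn h(t−1) + b_hn))
    h(t) = (1 − z(t)) ⊙ n(t) + z(t) ⊙ h(t−1)

with a linear readout y(t) = w_out·h(t) (+ b). An optional residual
connection concatenates the raw input to the readout features. Layers can
be stacked, with inter-layer dropout (one mask per sequence and unit).

Forward pass, backpropagation through time and the Adam optimiser are
implemented directly in NumPy; gradients are verified against central
finite differences in the test suite. Training minimises, over
post-washout samples only, one of: mean squared error, the negative
Pearson correlation (−CC), or their unweighted sum. The washout (default
250 samples) only drives the hidden state into an input-specific regime;
those samples never enter the loss or any reported score. L2 weight decay
is added to the gradients; optional gradient clipping bounds the global
gradient norm. All randomness (initialisation, batch order, dropout) is
seeded; two runs with the same seeds produce bit-identical loss
trajectories.

Two tuned configurations ship as presets. Human-like: 1 layer, hidden
size 88, CC loss, learning rate 1.21e-3, L2 2.21e-2, no clipping, no
dropout, no residual, batch 10, 69 epochs, washout 250. Rat-like:
2 layers, hidden 290, CC loss, learning rate 1e-3, L2 3e-4, dropout
0.128, residual readout, batch 22, 87 epochs, washout 250. The optimiser
is Adam (the tuning that produced these values did not record the
optimiser; Adam is the conventional choice and is recorded in the saved
config). Parameter initialisation is uniform in ±1/√hidden_size.

Hyperparameter search is a seeded random search over the documented
ranges (layers 1–5, hidden 10–500, loss ∈ {MSE, CC, MSE+CC}, log-uniform
learning rate 1e-5–1, L2 0–10, clipping on/off, dropout 0–0.2, residual
on/off, batch 3–32, epochs 1–100), scored by mean cross-validated CC;
diverging configurations score −inf and every evaluation is logged.
Cross-validation is leave-one-subject-out (or leave-one-trial-out within
a subject): each fold's vessels are scored exactly once, and the training
order is canonicalised so fold scores do not depend on subject ordering.

## Surrogate controls

The null hypothesis is that prediction quality is explained entirely by
the signal's linear statistics (amplitude distribution + power spectrum).
IAAFT surrogates realise that null: starting from a seeded random
permutation of the source, the algorithm alternates imposing the source's
Fourier magnitudes (keeping current phases) and rank-remapping the values
onto the source's sorted amplitudes, stopping below a relative spectral
RMS error of 1e-8 or after 1000 iterations, whichever comes first; the
amplitude step runs last, so the value multiset is preserved exactly and
the spectrum approximately (typically to a few times 1e-3 on 900-sample
band-limited traces). Ties in the rank remapping are broken by stable
sort order. One surrogate is generated per vessel, with per-vessel seeds
derived deterministically from the set seed.

## ARMAX baseline

The linear baseline is the ARMAX model

    y(t) + a₁y(t−1) + … + a_na y(t−n_a)
      = b₁u(t−n_k) + … + b_nb u(t−n_k−n_b+1)
      + c₁e(t−1) + … + c_nc e(t−n_c) + e(t)

with u the normalised raw trace, y the band-passed trace (not shifted)
and n_k = 10, so that the input terms at time t involve u only up to
t − 10. Estimation is Hannan–Rissanen (long-ARX innovation proxies, then
least squares including lagged residuals) refined by Levenberg–Marquardt
minimisation of the recursively computed one-step prediction errors;
multi-record fits stack all records' regression rows into one least
squares problem. Unstable or non-invertible estimates are flagged on the
result object. Coefficients are stored in the left-hand-side sign
convention above and the convention is serialised with the model.

Two evaluations exist and they answer different questions. The rolling
h-step *forecast* conditions on the true output history (for AR(1) with
y(t) = φy(t−1)+e the h-step forecast is φ^h·y_last); it is the classical
forecasting notion and the default for the order grid search. The
noise-free *simulation* ŷ = (B/A)u is driven by the input alone and is
the evaluation used for the GRU comparison: both methods then predict
from exactly the same information, the raw input up to t − 10. Comparing
against the forecast evaluation instead would hand the linear model the
recent true output — with a band-limited target that makes the task
nearly one-step and the comparison meaningless. Order search is an
exhaustive grid over (n_a, n_b, n_c) scored by leave-one-record-out CC;
the desk-scale default grid is 1–10 × 1–10 × 0–5 (the full 1–150 grid is
available but is cluster-scale).

## Synthetic data

The generator produces the regimes the pipeline assumes, so every stage
is testable without acquisition data. Its defaults are the package's
reference study conditions.

**Vessel trials.** Each trial has one shared slow component s(t) mixed
into `n_vessels` traces at weights drawn uniformly from [0.5, 1.5], plus
1/f colored noise (sd 0.7) and white noise (sd 0.7) per vessel — overall
SNR ≈ 1. The component is a wandering-frequency anharmonic oscillation:
the instantaneous frequency drifts slowly (drift process band-limited to
0.0005–0.004 Hz) between 1.5×band.low and 0.45×band.high (0.015–0.045 Hz
for the human-like band), and the waveform carries phase-locked 2nd and
3rd harmonics (amplitudes 0.7 and 0.35, fixed phase offsets 1.0 and 2.0
rad) under a slow amplitude modulation (depth 0.4). The fixed harmonic
phases encode a species-level waveform shape — vasomotor oscillations
have an asymmetric, fast-rise/slow-recovery profile — and this
phase-coupled structure is precisely what IAAFT surrogates destroy while
preserving spectrum and amplitudes. A Gaussian band-limited component
(`gaussian=True`) is available; note that for such a process surrogates
are statistically equivalent to the source and no real-vs-surrogate
separation exists even in principle. More than 90% of the component's
power lies inside its nominal band in either mode.

**Network sessions.** ROI traces mix a global component g(t) (the same
anharmonic process, so a vessel-trained model can predict it) and an
independent DMN-internal component d(t) (Gaussian band-limited) at
separately tunable couplings, plus unit white noise. Both components are
returned as ground truth; d(t) doubles as the DMN-ICA-like component
trace for the intrinsic-DMN index.

**Probes and images.** Spectral probes are white noise shaped by a
Gaussian envelope at (f0, width), unit variance. Vessel images are a
bright background with dark discs placed by rejection sampling (minimum
center distance 3× radius), with ground-truth masks.

What the generator does *not* emulate: cardiac/respiratory quasi-periodic
confounds, head motion, MRI physics, spatial autocorrelation of noise,
inter-subject variability of the waveform shape. Passing tests therefore
show that the pipeline recovers the intended structure under its stated
assumptions, not that those assumptions exhaust real data.

## Brain-state classification

A trained forecaster is applied to a named ROI trace of every session;
the per-session CC is the brain-state index. Sessions are grouped by
score percentiles (default top/bottom 5%, ties broken by stable order)
and compared via seed-correlation difference maps: per-node two-sample
t-tests on Fisher-z values, Benjamini–Hochberg FDR masking at q = 0.05.
The intrinsic DMN index of a session is the mean over DMN voxels/ROIs of
their correlation with a DMN component trace — the mean of correlations,
not the correlation with the mean. Score–index relationships are
summarised by percentile-binned curves (bin size ⌊n·bin_pct⌋ sessions,
remainder to the last bin). An alternative classification by
global-signal variance (unweighted ROI mean) is provided for contrast,
including natural-log variance curves with zero-variance sessions
excluded.

Correlation matrices are reordered by the graph Laplacian's Fiedler
vector with affinity A = (corr+1)/2, zeroed diagonal, the vector's sign
fixed by its first entry and ties broken by stable sort; disconnected
affinity graphs are ordered per connected component with a warning.

Spectral preference of a trained model is probed by predicting synthetic
narrow-band signals over a grid of peak frequencies and widths, averaging
CC over seeds; a model trained on band-limited data should peak inside
its training band.

## Vessel localisation

Venules are dark dots on anatomical images. The localisation pipeline is
a 3×3 local-minimum filter (reading "1 voxel-wide neighborhood" as center
±1 voxel — the literal 1×1 window would be a no-op), a 10×10 normalised
box filter (a rank-sum divided by the filter size equals a moving
average), and a dark-quantile threshold (default 2%, a package choice).
An ICA component map (FastICA on the spatial dimension after PCA
reduction, 10 components, automatic selection by sub-0.1 Hz power
fraction with manual override) can be thresholded and intersected with
the vessel mask. Time courses are means over connected mask components,
labelled by centroid; extraction conserves the masked data exactly
(sum over components of pixels × trace equals the masked sum).

## The reference study and its sizes

The canonical desk-scale experiment (`slowosc.study`, also what
`scripts/acceptance.py` runs) generates 8 trials × 12 vessels, trains the
human-preset GRU on the first half (48 traces), and scores the held-out
48 traces and their matched surrogates; the ARMAX comparison uses a
reduced 5×5×3 grid; the session sweep uses 60 sessions in which global
coupling rises linearly from 0.4 to 1.6 while DMN coupling falls from
1.4 to 0.4. These sizes give stable statistics (paired surrogate tests
at p « 0.01) while keeping a full run in a few minutes on one CPU.
Doubling the training epochs does not change held-out CC (checked), so
the preset trains to convergence at this scale.

One property of this suite deserves an honest statement. The converged
CC-optimal predictor concedes a fraction of the 10 s horizon: the
sub-sample (parabolic) cross-correlation peak of the better-predicted
half of held-out traces sits at about +0.6 s on average across study
seeds (range ~0 to +1.2 s), so the integer-lag median lands on 0 s or
+1 s depending on the realization. This is neither an alignment bug
(the same pipeline measures exactly 0 lag on a trained sinusoid model)
nor undertraining (tripling the epochs leaves it unchanged): it is the
optimum's trade of ~0.5–1 s of anticipation for amplitude fidelity at
SNR ≈ 1 on this generator. On vessel recordings the analogous median is
reported as exactly 0; whether a given dataset makes full anticipation
optimal is a property of its signal-to-noise regime.

## Numerical choices and edge cases

* CC is undefined for zero-variance vectors: explicit errors everywhere,
  and |cc| = 1 is rejected before Fisher z-transforms.
* The paired Fisher test returns t = 0, p = 1 when all pairwise
  differences vanish (identical inputs), rather than 0/0.
* Sliding-window CC: centered 31-sample window at dt = 1 (half-width
  round(window/2dt)); truncated at the edges; values with fewer than 3
  usable samples or zero variance are NaN.
* Cross-correlation lags: both series z-scored; positive lag = delayed
  prediction. The lag search is unbounded by default because poorly
  predicted traces can lock a full cycle late (observed at ±15 s and
  beyond).
* `filtfilt` edge handling uses odd-reflection padding (scipy default);
  spectra of short traces are rejected rather than zero-padded silently.
* IAAFT on constant traces raises (ranks undefined); fewer than 16
  samples raises.
* Unstable ARMAX simulation/forecast recursions raise FloatingPointError
  (caught and recorded as NaN cells during grid search) instead of
  returning silent infinities.
* Forecast horizons beyond n_k would need future inputs and raise.

## Known limitations

* The NumPy GRU is single-threaded and CPU-bound; it trains the
  desk-scale suite in minutes but is not meant for cluster-scale sweeps.
* Hyperparameter search is random search; with an external TPE library a
  guided search over the same space would typically need fewer
  evaluations.
* The vessel-trained model transfers to session ROI traces only insofar
  as the session's global component resembles the vessel slow component;
  this mirrors the cross-dataset transfer assumption of the original
  design and is a modelling assumption, not a guarantee.
* Group-ICA derivation of component traces is out of scope; with real
  data the user supplies them. Only the correlation-with-supplied-trace
  step of dual-regression-style analysis is implemented.
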