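"""IAAFT surrogate controls.

A surrogate control shares the source trace's amplitude distribution
(exactly — the output values are a permutation of the input values) and its
Fourier amplitude spectrum (to high accuracy), but has randomised Fourier
phases. Any temporal structure beyond the autocorrelation function — in
particular the phase coupling that makes the slow hemodynamic oscillation
predictable beyond its linear statistics — is destroyed, which makes the
surrogate the appropriate null control for prediction scores.

The iterative amplitude adjusted Fourier transform (IAAFT) alternates two
projections starting from a random permutation of the source:

1. spectrum step — impose the source Fourier magnitudes, keep current phases;
2. amplitude step — rank-remap the values onto the source's sorted values.

Iteration stops when the relative RMS error between the surrogate's and the
source's Fourier magnitudes falls below ``tol`` or after ``max_iter``
rounds; the amplitude step is applied last, so the amplitude distribution
is exact and the spectrum approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries, TrialSet

__all__ = ["SurrogateResult", "iaaft", "surrogate_set"]


@dataclass
class SurrogateResult:
    """An IAAFT surrogate plus convergence diagnostics."""

    surrogate: TimeSeries
    n_iterations: int
    spectral_error: float
    source_label: str

    def to_dict(self) -> dict:
        return {
            "source_label": self.source_label,
            "n_iterations": self.n_iterations,
            "spectral_error": self.spectral_error,
        }


def _spectral_rms_error(candidate: np.ndarray, target_mag: np.ndarray) -> float:
    mag = np.abs(np.fft.rfft(candidate))
    denom = np.sqrt(np.mean(target_mag**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.mean((mag - target_mag) ** 2)) / denom)


def iaaft(
    ts: TimeSeries,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> SurrogateResult:
    """Generate one IAAFT surrogate of ``ts``.

    Raises on constant input (amplitude ranks undefined) and on traces
    shorter than 16 samples (too few Fourier bins to match meaningfully).
    """
    x = ts.values
    if len(x) < 16:
        raise ValueError("IAAFT requires at least 16 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant input: amplitude ranks undefined")

    sorted_amplitudes = np.sort(x)  # stable ascending; ties keep sort order
    target_mag = np.abs(np.fft.rfft(x))

    rng = np.random.default_rng(seed)
    current = rng.permutation(x)

    n_it = 0
    err = _spectral_rms_error(current, target_mag)
    for n_it in range(1, max_iter + 1):
        # spectrum step: impose source magnitudes, keep current phases
        spec = np.fft.rfft(current)
        phases = np.angle(spec)
        candidate = np.fft.irfft(target_mag * np.exp(1j * phases), n=len(x))
        # amplitude step: rank-remap onto the source's sorted values
        ranks = np.argsort(np.argsort(candidate, kind="stable"), kind="stable")
        current = sorted_amplitudes[ranks]
        err = _spectral_rms_error(current, target_mag)
        if err < tol:
            break

    surrogate = TimeSeries(
        current,
        dt=ts.dt,
        label=f"{ts.label}_surrogate" if ts.label else "surrogate",
        meta={**ts.meta, "surrogate": True, "surrogate_seed": seed},
    )
    return SurrogateResult(
        surrogate=surrogate,
        n_iterations=n_it,
        spectral_error=err,
        source_label=ts.label,
    )


def surrogate_set(
    trial: TrialSet,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[TrialSet, list[SurrogateResult]]:
    """One surrogate per trace; per-trace seeds derived from (seed, index).

    Per-trace failures are re-raised with the trace label attached.
    """
    if len(trial) == 0:
        raise ValueError("empty trial")
    child_seeds = np.random.SeedSequence(seed).spawn(len(trial))
    results = []
    for i, ts in enumerate(trial):
        sub_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
        try:
            results.append(iaaft(ts, seed=sub_seed, max_iter=max_iter, tol=tol))
        except ValueError as exc:
            raise ValueError(f"IAAFT failed for trace {ts.label!r}: {exc}") from exc
    controls = TrialSet(
        [r.surrogate for r in results],
        name=f"{trial.name}_surrogates" if trial.name else "surrogates",
    )
    return controls, results
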