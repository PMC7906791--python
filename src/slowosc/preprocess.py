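"""Spectral estimation, frequency normalisation, band-pass filtering,
resampling, and construction of shifted prediction targets.

The prediction pipeline feeds a *raw but normalised* vessel trace into the
recurrent network and asks it to output the *band-passed* trace advanced by
``shift`` seconds (default 10 s). This module owns every step of that data
preparation:

* Welch power spectral density with the project's standard segmentation
  (1024-point DFT, Hann window of length 128, 50% overlap);
* frequency normalisation — remove the mean and scale the trace so its mean
  PSD above a high-frequency cutoff (default 0.2 Hz) equals one, putting
  trials of different overall signal strength on a common noise baseline;
* zero-phase Butterworth band-pass (forward-backward filtering, so no group
  delay enters the target);
* polyphase resampling for data acquired at a different TR;
* assembly of :class:`TargetPair` objects (input trace, shifted target).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .timeseries import BandSpec, TimeSeries

__all__ = [
    "SpectralConfig",
    "Spectrum",
    "TargetPair",
    "welch_psd",
    "frequency_normalize",
    "bandpass",
    "resample_to_dt",
    "make_target_pair",
    "psd_fwhm",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimator settings: DFT length, window, overlap."""

    n_dft: int = 1024
    window: str = "hann"
    window_length: int = 128
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_length > self.n_dft:
            raise ValueError("window length must not exceed n_dft")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass
class Spectrum:
    """One-sided PSD: nonnegative increasing frequencies (Hz) and densities."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.psd = np.asarray(self.psd, float)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have equal shape")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValueError("freqs must be nonnegative and increasing")

    def band_power(self, band: BandSpec) -> float:
        """Integrated power inside ``band`` (trapezoidal)."""
        mask = (self.freqs >= band.low) & (self.freqs <= band.high)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(self.psd[mask], self.freqs[mask]))

    def total_power(self) -> float:
        return float(np.trapezoid(self.psd, self.freqs))


@dataclass
class TargetPair:
    """Input trace (normalised) and its band-passed, time-advanced target.

    ``target.values[t]`` equals the filtered input at ``t + shift/dt``; both
    members share dt and length (the common valid range after the shift).
    """

    input: TimeSeries
    target: TimeSeries
    shift: float = 10.0

    def __post_init__(self) -> None:
        if len(self.input) != len(self.target):
            raise ValueError("input and target must have equal length")
        if self.input.dt != self.target.dt:
            raise ValueError("input and target must share dt")


def welch_psd(ts: TimeSeries, cfg: SpectralConfig = SpectralConfig()) -> Spectrum:
    """Welch PSD of a trace with the standard segmentation.

    Frequency resolution is ``1/(n_dft * dt)``; the window is shorter than
    the DFT length, so segments are zero-padded.
    """
    if len(ts) < cfg.window_length:
        raise ValueError(
            f"trace of length {len(ts)} shorter than window {cfg.window_length}"
        )
    noverlap = int(cfg.overlap_fraction * cfg.window_length)
    freqs, psd = sps.welch(
        ts.values,
        fs=1.0 / ts.dt,
        window=cfg.window,
        nperseg=cfg.window_length,
        noverlap=noverlap,
        nfft=cfg.n_dft,
        detrend=False,
    )
    return Spectrum(freqs=freqs, psd=psd)


def frequency_normalize(
    ts: TimeSeries,
    cutoff: float = 0.2,
    cfg: SpectralConfig = SpectralConfig(),
    literal_division: bool = False,
) -> TimeSeries:
    """Remove the mean and rescale by the high-frequency noise floor.

    The trace is divided by the square root of its mean Welch PSD above
    ``cutoff`` Hz, so that the re-computed mean PSD above the cutoff equals
    one: power scales quadratically with amplitude, hence the square root.
    With ``literal_division=True`` the trace is divided by the mean PSD
    itself (no square root); this alternative convention does not produce a
    unit noise floor and exists only for comparison.
    """
    if cutoff >= ts.nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {ts.nyquist} Hz")
    centered = ts.values - ts.values.mean()
    spec = welch_psd(ts.copy_with(values=centered), cfg)
    high = spec.freqs > cutoff
    if not np.any(high):
        raise ValueError("no frequency bins above cutoff")
    mean_psd = float(spec.psd[high].mean())
    if mean_psd <= 0:
        raise ValueError("zero high-frequency power: degenerate input")
    divisor = mean_psd if literal_division else np.sqrt(mean_psd)
    return ts.copy_with(values=centered / divisor, normalized=True, norm_cutoff_hz=cutoff)


def bandpass(ts: TimeSeries, band: BandSpec, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2x).

    Uses odd-reflection padding of ``3 * max(len(a), len(b))`` samples at the
    edges; no group delay, so a within-band sine keeps its phase.
    """
    band.validate_for_dt(ts.dt)
    sos = sps.butter(
        order, [band.low, band.high], btype="bandpass", fs=1.0 / ts.dt, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, ts.values)
    return ts.copy_with(values=filtered, band=(band.low, band.high))


def bandpass_gain(band: BandSpec, freq: float, dt: float, order: int = 4) -> float:
    """Squared (forward-backward) magnitude response at ``freq`` Hz.

    Useful as an analytic oracle for stop-band attenuation.
    """
    sos = sps.butter(
        order, [band.low, band.high], btype="bandpass", fs=1.0 / dt, output="sos"
    )
    _, h = sps.sosfreqz(sos, worN=[freq], fs=1.0 / dt)
    return float(np.abs(h[0]) ** 2)


def resample_to_dt(ts: TimeSeries, target_dt: float, method: str = "poly") -> TimeSeries:
    """Resample to a new sampling interval, preserving duration within one sample.

    ``method='poly'`` uses polyphase low-pass resampling (anti-aliasing on
    down-sampling); ``method='linear'`` uses plain linear interpolation.
    """
    if not target_dt > 0:
        raise ValueError("target_dt must be positive")
    if target_dt == ts.dt:
        return ts.copy_with()
    if method == "linear":
        new_n = int(round(len(ts) * ts.dt / target_dt))
        new_t = np.arange(new_n) * target_dt
        vals = np.interp(new_t, ts.times, ts.values)
        out = vals
    elif method == "poly":
        ratio = Fraction(ts.dt / target_dt).limit_denominator(1000)
        up, down = ratio.numerator, ratio.denominator
        out = sps.resample_poly(ts.values, up, down)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    resampled = TimeSeries(out, dt=target_dt, label=ts.label, meta=dict(ts.meta))
    resampled.meta["resampled_from_dt"] = ts.dt
    return resampled


def make_target_pair(
    ts: TimeSeries,
    band: BandSpec,
    shift: float = 10.0,
    order: int = 4,
    cutoff: float = 0.2,
    cfg: SpectralConfig = SpectralConfig(),
) -> TargetPair:
    """Build the (input, 10-s-ahead target) pair for supervised training.

    input = frequency-normalised trace; target[t] = band-passed input at
    t + shift/dt. Both are truncated to the common valid length.
    """
    n_shift_f = shift / ts.dt
    if abs(n_shift_f - round(n_shift_f)) > 1e-9:
        raise ValueError(f"shift {shift}s not divisible by dt {ts.dt}s")
    n_shift = int(round(n_shift_f))
    if shift >= ts.duration:
        raise ValueError("shift must be smaller than the trace duration")
    normalized = frequency_normalize(ts, cutoff=cutoff, cfg=cfg)
    filtered = bandpass(normalized, band, order=order)
    n_valid = len(ts) - n_shift
    inp = normalized.copy_with(values=normalized.values[:n_valid])
    tgt = filtered.copy_with(values=filtered.values[n_shift:], shift_s=shift)
    return TargetPair(input=inp, target=tgt, shift=shift)


def psd_fwhm(spec: Spectrum) -> float:
    """Full width at half maximum of the PSD peak above 0 Hz.

    Linear interpolation between bins locates the two half-maximum crossings
    bracketing the (unique) peak; raises if either crossing is missing.
    """
    positive = spec.freqs > 0
    freqs = spec.freqs[positive]
    psd = spec.psd[positive]
    if freqs.size < 3:
        raise ValueError("spectrum too short for a peak width")
    k = int(np.argmax(psd))
    half = psd[k] / 2.0

    def _cross(idx_range, reverse: bool) -> float:
        seq = idx_range[::-1] if reverse else idx_range
        for i in seq:
            j = i + 1
            if (psd[i] - half) * (psd[j] - half) <= 0 and psd[i] != psd[j]:
                frac = (half - psd[i]) / (psd[j] - psd[i])
                return freqs[i] + frac * (freqs[j] - freqs[i])
        raise ValueError("no half-maximum crossing found bracketing the peak")

    left = _cross(range(0, k), reverse=True) if k > 0 else None
    right = _cross(range(k, freqs.size - 1), reverse=False)
    if left is None:
        raise ValueError("peak at the lowest positive bin: no left crossing")
    return float(right - left)
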