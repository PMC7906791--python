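"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators emulate the regimes the analysis operates in, so that every
downstream stage (preprocessing, surrogate controls, network training,
ARMAX baseline, session classification, vessel localisation) can be
exercised end-to-end without any acquisition data:

* **Vessel trials** — a set of noisy vessel traces all carrying one shared
  band-limited slow component (0.01-0.1 Hz human-like, 0.01-0.05 Hz
  rat-like) at vessel-specific weights, buried in 1/f^alpha colored noise
  plus white noise. The shared component includes, by default, a mild
  quadratic waveform-shaping term: resting hemodynamic oscillations are
  skewed and phase-coupled rather than Gaussian, and this is precisely the
  structure that phase-randomised surrogate controls destroy. A
  ``gaussian=True`` switch produces a strictly Gaussian component.
* **Network sessions** — multi-ROI sessions mixing a global component g(t)
  and a DMN-internal component d(t) at separately tunable couplings, for
  the brain-state classification analyses.
* **Probe signals** — Gaussian noise spectrally shaped by a Gaussian
  envelope (peak frequency f0, spectral width), for probing the spectral
  preference of trained predictors.
* **Vessel images** — a bright background with dark discs, mimicking
  venules on an arteriole-venule map, with ground-truth masks.

All generators are pure functions of their spec (seed included): the same
spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import BandSpec, SessionData, TimeSeries, TrialSet

__all__ = [
    "VesselTrialSpec",
    "NetworkSessionSpec",
    "generate_vessel_trial",
    "generate_network_session",
    "generate_probe_signal",
    "generate_vessel_image",
    "band_limited_noise",
    "colored_noise",
]


def band_limited_noise(
    n: int, dt: float, band: BandSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` by FFT masking."""
    band.validate_for_dt(dt)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= band.low) & (freqs <= band.high)
    if not np.any(mask):
        raise ValueError("band contains no FFT bins at this length/dt")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited draw (zero variance)")
    return x / sd


def colored_noise(
    n: int, dt: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via FFT amplitude shaping (no DC)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std()


# Fixed waveform shape: phase offsets of the 2nd and 3rd harmonics relative
# to the fundamental. The asymmetric (fast-rise, slow-recovery) waveform of
# vasomotor oscillations is a species-level characteristic, so the shape is
# shared across trials; only the fundamental's phase is random.
WAVEFORM_PHASES = (1.0, 2.0)


def _shared_slow_component(
    n: int,
    dt: float,
    band: BandSpec,
    rng: np.random.Generator,
    harmonics: tuple[float, float] = (0.7, 0.35),
    am_depth: float = 0.4,
    gaussian: bool = False,
) -> np.ndarray:
    """Band-dominated slow component, unit variance, zero mean.

    The default component is a wandering-frequency anharmonic oscillation:
    the instantaneous frequency drifts slowly (0.0005-0.004 Hz drift band)
    between 1.5x the band's low edge and 0.45x its high edge, and the
    waveform carries phase-locked 2nd and 3rd harmonics plus a slow
    amplitude modulation. This non-Gaussian, phase-coupled structure is
    what makes the real signal more predictable than its phase-randomised
    (IAAFT) surrogate — the property the prediction analysis probes. With
    ``gaussian=True`` a plain band-limited Gaussian process is returned
    instead (linear statistics only; its surrogates are statistically
    equivalent to it).
    """
    if gaussian:
        s = band_limited_noise(n, dt, band, rng)
    else:
        f_lo = 1.5 * band.low
        f_hi = 0.45 * band.high
        drift = band_limited_noise(n, dt, BandSpec(0.0005, 0.004), rng)
        u = (drift - drift.min()) / (drift.max() - drift.min())
        f_inst = f_lo + (f_hi - f_lo) * u
        phase = 2.0 * np.pi * np.cumsum(f_inst) * dt + rng.uniform(0, 2 * np.pi)
        h2, h3 = harmonics
        psi2, psi3 = WAVEFORM_PHASES
        s = (np.cos(phase)
             + h2 * np.cos(2 * phase + psi2)
             + h3 * np.cos(3 * phase + psi3))
        if am_depth > 0:
            e = band_limited_noise(n, dt, BandSpec(0.001, 0.008), rng)
            env = np.clip(1.0 + am_depth * e / np.abs(e).max() * 1.2, 0.1, None)
            s = env * s
    s = s - s.mean()
    return s / s.std()


@dataclass(frozen=True)
class VesselTrialSpec:
    """Conditions for one synthetic vessel trial.

    Defaults emulate the 15-min, 1-s-TR human-like regime at SNR ~ 1:
    vessel-specific weights of a shared slow component around one, and
    colored + white noise of comparable total variance.
    """

    n_vessels: int = 12
    n_timepoints: int = 900
    dt: float = 1.0
    band: BandSpec = field(default_factory=lambda: BandSpec(0.01, 0.1))
    shared_weight_range: tuple[float, float] = (0.5, 1.5)
    noise_exponent: float = 1.0
    colored_noise_sd: float = 0.7
    white_noise_sd: float = 0.7
    harmonics: tuple[float, float] = (0.7, 0.35)
    am_depth: float = 0.4
    gaussian: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if self.n_timepoints < 2 * 250:
            raise ValueError("n_timepoints must be >= 500 (2x default washout)")
        lo, hi = self.shared_weight_range
        if lo < 0 or hi < lo:
            raise ValueError("shared_weight_range must be a nonnegative interval")
        self.band.validate_for_dt(self.dt)


def generate_vessel_trial(spec: VesselTrialSpec) -> TrialSet:
    """Generate one trial of noisy vessel traces sharing a slow component.

    Each trace is ``w_i * s(t) + colored + white`` with w_i drawn uniformly
    from ``shared_weight_range``. The shared component s(t) is returned as
    ground truth under key ``"shared"`` together with the weights.
    """
    rng = np.random.default_rng(spec.seed)
    s = _shared_slow_component(
        spec.n_timepoints, spec.dt, spec.band, rng,
        harmonics=spec.harmonics, am_depth=spec.am_depth, gaussian=spec.gaussian,
    )
    lo, hi = spec.shared_weight_range
    weights = rng.uniform(lo, hi, size=spec.n_vessels)
    traces = []
    for i in range(spec.n_vessels):
        x = weights[i] * s
        if spec.colored_noise_sd > 0:
            x = x + spec.colored_noise_sd * colored_noise(
                spec.n_timepoints, spec.dt, spec.noise_exponent, rng
            )
        if spec.white_noise_sd > 0:
            x = x + spec.white_noise_sd * rng.standard_normal(spec.n_timepoints)
        traces.append(TimeSeries(x, dt=spec.dt, label=f"vessel{i:03d}"))
    return TrialSet(
        traces,
        name=f"synthetic_trial_seed{spec.seed}",
        ground_truth={"shared": s, "weights": weights},
    )


@dataclass(frozen=True)
class NetworkSessionSpec:
    """Conditions for one synthetic multi-ROI session.

    ROI traces mix a global component g(t) (all ROIs) and a DMN-internal
    component d(t) (DMN ROIs only) at the given couplings, plus white noise.
    """

    n_rois: int = 12
    dmn_roi_indices: tuple[int, ...] = (0, 1, 2, 3)
    global_coupling: float = 1.0
    dmn_coupling: float = 1.0
    n_timepoints: int = 900
    dt: float = 1.0
    band: BandSpec = field(default_factory=lambda: BandSpec(0.01, 0.1))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dmn_roi_indices) == 0:
            raise ValueError("DMN ROI set must not be empty")
        if any(i < 0 or i >= self.n_rois for i in self.dmn_roi_indices):
            raise ValueError("dmn_roi_indices out of range")
        if self.global_coupling < 0 or self.dmn_coupling < 0:
            raise ValueError("couplings must be nonnegative")
        self.band.validate_for_dt(self.dt)


def generate_network_session(spec: NetworkSessionSpec) -> SessionData:
    """Generate one session of ROI traces with global and DMN components.

    Ground-truth components g and d are stored as component traces
    ``"global"`` and ``"dmn_ica"`` on the returned :class:`SessionData`.
    """
    rng = np.random.default_rng(spec.seed)
    # the global component carries the predictable slow-oscillation
    # structure; the DMN-internal component is a generic band-limited process
    g = _shared_slow_component(spec.n_timepoints, spec.dt, spec.band, rng)
    d = _shared_slow_component(
        spec.n_timepoints, spec.dt, spec.band, rng, gaussian=True
    )
    dmn = set(spec.dmn_roi_indices)
    traces = np.empty((spec.n_timepoints, spec.n_rois))
    labels = []
    for i in range(spec.n_rois):
        x = spec.global_coupling * g
        if i in dmn:
            x = x + spec.dmn_coupling * d
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(spec.n_timepoints)
        traces[:, i] = x
        labels.append(f"DMN{i:02d}" if i in dmn else f"ROI{i:02d}")
    return SessionData(
        roi_traces=traces,
        roi_labels=labels,
        dmn_mask=[labels[i] for i in sorted(dmn)],
        component_traces={"global": g, "dmn_ica": d},
        dt=spec.dt,
        name=f"synthetic_session_seed{spec.seed}",
    )


def generate_probe_signal(
    f0: float, width: float, n_timepoints: int, dt: float, seed: int
) -> TimeSeries:
    """Gaussian noise spectrally shaped by a Gaussian envelope at ``f0``.

    The FFT of white noise is multiplied by exp(-(f - f0)^2 / (2 width^2));
    the result has unit variance and zero mean. Requires f0 + 3*width below
    the Nyquist frequency so the envelope is not truncated.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    nyquist = 0.5 / dt
    if f0 + 3 * width >= nyquist:
        raise ValueError(
            f"f0 + 3*width = {f0 + 3 * width} Hz must be below Nyquist {nyquist} Hz"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_timepoints)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_timepoints, d=dt)
    envelope = np.exp(-((freqs - f0) ** 2) / (2.0 * width**2))
    envelope[0] = 0.0
    x = np.fft.irfft(spec * envelope, n=n_timepoints)
    x = x - x.mean()
    return TimeSeries(
        x / x.std(), dt=dt, label=f"probe_f{f0:g}_w{width:g}", meta={"f0": f0, "width": width}
    )


def generate_vessel_image(
    shape: tuple[int, int],
    n_dots: int,
    dot_radius: float,
    contrast: float,
    seed: int,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Bright background with ``n_dots`` dark discs and a ground-truth mask.

    Dot centers are placed by rejection sampling with a minimum pairwise
    center distance of 3x the radius and a border margin of one radius;
    impossible packings raise after ``max_tries`` attempts. Background level
    is 1.0, disc level ``1 - contrast``.
    """
    if not (0 < contrast <= 1):
        raise ValueError("contrast must be in (0, 1]")
    h, w = shape
    margin = dot_radius + 1
    if n_dots > 0 and (h <= 2 * margin or w <= 2 * margin):
        raise ValueError("image too small for the requested dot radius")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_dots:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_dots} dots of radius {dot_radius} "
                f"in a {h}x{w} image (rejection sampling exhausted)"
            )
        tries += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all(np.hypot(cy - y, cx - x) >= 3 * dot_radius for y, x in centers):
            centers.append((cy, cx))
    image = np.ones(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx in centers:
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= dot_radius**2
        image[disc] = 1.0 - contrast
        mask |= disc
    return image, mask
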