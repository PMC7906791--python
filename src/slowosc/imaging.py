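"""Vessel localisation on 2-D anatomical images and time-course extraction.

Venules appear as small dark dots on arteriole-venule maps (and on mean
EPI images in humans). Localisation is a two-stage local-statistics
pipeline: a local minimum filter accentuates dark spots, a normalised
rectangular averaging filter smooths the result, and a dark-quantile
threshold produces the binary vessel mask. An ICA-derived component map
can be thresholded and intersected with the vessel mask to keep only
vessels carrying the slow oscillation; time courses are then extracted as
per-component pixel means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .timeseries import TimeSeries, TrialSet

__all__ = [
    "VesselMask",
    "localize_vessels",
    "combine_masks",
    "extract_timecourses",
    "spatial_ica_maps",
    "load_nifti",
    "save_mask_nifti",
]


@dataclass
class VesselMask:
    """Binary vessel-location image plus the parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def n_components(self) -> int:
        _, n = ndimage.label(self.mask)
        return n


def localize_vessels(
    image: np.ndarray,
    neighborhood: int = 3,
    rank_size: int = 10,
    threshold: float = 0.02,
) -> VesselMask:
    """Locate dark dots: min filter -> normalised box filter -> dark quantile.

    ``neighborhood`` is the minimum-filter window (3 = center +-1 pixel),
    ``rank_size`` the box filter size (sum over the window divided by its
    size, i.e. a moving average), ``threshold`` the darkness quantile kept.
    A constant image yields an empty mask with a warning.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if np.ptp(image) == 0:
        warnings.warn("constant image: returning an empty mask")
        return VesselMask(np.zeros(image.shape, bool),
                          {"neighborhood": neighborhood, "rank_size": rank_size,
                           "threshold": threshold, "constant_input": True})
    dark = ndimage.minimum_filter(image, size=neighborhood, mode="nearest")
    smoothed = ndimage.uniform_filter(dark, size=rank_size, mode="nearest")
    cut = np.quantile(smoothed, threshold)
    mask = smoothed <= cut
    return VesselMask(mask, {"neighborhood": neighborhood,
                             "rank_size": rank_size, "threshold": threshold})


def combine_masks(vessel_mask: VesselMask, component_map: np.ndarray,
                  z_threshold: float) -> VesselMask:
    """Intersect the vessel mask with |component map| >= z_threshold."""
    comp = np.asarray(component_map, float)
    if comp.shape != vessel_mask.shape:
        raise ValueError(
            f"component map shape {comp.shape} != mask shape {vessel_mask.shape}"
        )
    combined = vessel_mask.mask & (np.abs(comp) >= z_threshold)
    prov = dict(vessel_mask.provenance)
    prov["z_threshold"] = z_threshold
    return VesselMask(combined, prov)


def extract_timecourses(data: np.ndarray, mask: VesselMask, dt: float = 1.0
                        ) -> TrialSet:
    """One mean time course per connected mask component.

    ``data`` is (T, H, W) — or (H, W) for a single frame, treated as T=1.
    Components are labelled by their pixel centroid. An empty mask yields
    an empty TrialSet with a warning.
    """
    data = np.asarray(data, float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.shape[1:] != mask.shape:
        raise ValueError("data must be (T, H, W) matching the mask shape")
    labels, n = ndimage.label(mask.mask)
    if n == 0:
        warnings.warn("empty mask: no time courses extracted")
        return TrialSet([], name="extracted")
    traces = []
    for comp in range(1, n + 1):
        pix = labels == comp
        cy, cx = ndimage.center_of_mass(pix)
        series = data[:, pix].mean(axis=1)
        if series.size < 2:
            series = np.repeat(series, 2)  # degenerate single-frame input
        traces.append(TimeSeries(series, dt=dt, label=f"v_y{cy:.0f}_x{cx:.0f}",
                                 meta={"n_pixels": int(pix.sum())}))
    return TrialSet(traces, name="extracted")


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Load a NIfTI-1 file; returns (data, TR seconds from the header).

    2-D images come back as (H, W); 3-D/4-D volumes keep their axes, with
    time last per NIfTI convention (callers typically move it first).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) >= 4 else 1.0
    return data, tr


def save_mask_nifti(mask: VesselMask, path, affine: np.ndarray | None = None
                    ) -> None:
    """Write a vessel mask as a NIfTI-1 byte volume."""
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def spatial_ica_maps(data: np.ndarray, n_components: int = 10, dt: float = 1.0,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, int]:
    """Spatial ICA of (T, H, W) data: component maps and time courses.

    PCA reduction followed by FastICA on the spatial dimension; maps are
    z-scored. Also returns the index of the component whose time course
    carries the highest fraction of power below 0.1 Hz — the automatic
    pick for the slow-oscillation component (the choice can be overridden
    by the caller).
    """
    from sklearn.decomposition import FastICA

    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be (T, H, W)")
    T, H, W = data.shape
    X = data.reshape(T, H * W)
    X = X - X.mean(axis=0)
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=1000)
    sources = ica.fit_transform(X.T)  # spatial ICA: pixels are samples
    maps = sources.T.reshape(n_components, H, W)
    timecourses = ica.mixing_.T  # (n_components, T)
    maps = (maps - maps.mean(axis=(1, 2), keepdims=True)) / (
        maps.std(axis=(1, 2), keepdims=True) + 1e-12
    )
    # pick the component dominated by slow power
    freqs = np.fft.rfftfreq(T, d=dt)
    slow = freqs < 0.1
    best, best_frac = 0, -1.0
    for k in range(n_components):
        power = np.abs(np.fft.rfft(timecourses[k] - timecourses[k].mean())) ** 2
        frac = power[slow].sum() / power.sum() if power.sum() > 0 else 0.0
        if frac > best_frac:
            best, best_frac = k, frac
    return maps, timecourses, best
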