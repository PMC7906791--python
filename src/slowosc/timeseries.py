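"""Core containers for sampled signals and vessel/ROI collections.

Every signal in the pipeline is a :class:`TimeSeries`: a finite real vector
sampled at a fixed interval ``dt`` (seconds), carrying a label and a small
metadata dict used by the preprocessing stages to record what has been done
to the trace (normalisation, filtering band, time shift).

A :class:`TrialSet` bundles the vessel (or ROI) traces of one session/trial,
optionally together with generator ground truth when the data are synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["BandSpec", "TimeSeries", "TrialSet", "SessionData"]


@dataclass(frozen=True)
class BandSpec:
    """Frequency band in Hz, ``0 < low < high``.

    Defaults used throughout the project are 0.01-0.1 Hz (human-like) and
    0.01-0.05 Hz (rat-like, anesthetized).
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band requires 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_dt(self, dt: float) -> None:
        nyquist = 0.5 / dt
        if self.high >= nyquist:
            raise ValueError(
                f"band high edge {self.high} Hz >= Nyquist {nyquist} Hz for dt={dt}"
            )


HUMAN_BAND = BandSpec(0.01, 0.1)
RAT_BAND = BandSpec(0.01, 0.05)


@dataclass
class TimeSeries:
    """A regularly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Sample values; must be finite and of length >= 2.
    dt : float
        Sampling interval in seconds.
    label : str
        Human-readable identifier (vessel name, ROI name, ...).
    meta : dict
        Provenance flags, e.g. ``{"normalized": True, "band": (0.01, 0.1)}``.
    """

    values: np.ndarray
    dt: float
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if self.values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total span in seconds (n * dt)."""
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def copy_with(self, values: np.ndarray | None = None, **meta) -> "TimeSeries":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return TimeSeries(
            values=self.values.copy() if values is None else np.asarray(values, float),
            dt=self.dt,
            label=self.label,
            meta=new_meta,
        )


class TrialSet:
    """Vessel/ROI traces of one trial, optionally with generator ground truth."""

    def __init__(
        self,
        traces: Sequence[TimeSeries],
        name: str = "",
        ground_truth: Mapping[str, np.ndarray] | None = None,
    ):
        self.traces = list(traces)
        self.name = name
        self.ground_truth = dict(ground_truth) if ground_truth else {}
        dts = {ts.dt for ts in self.traces}
        if len(dts) > 1:
            raise ValueError(f"mixed sampling intervals in TrialSet: {sorted(dts)}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[TimeSeries]:
        return iter(self.traces)

    def __getitem__(self, i: int) -> TimeSeries:
        return self.traces[i]

    @property
    def dt(self) -> float:
        return self.traces[0].dt

    @property
    def labels(self) -> list[str]:
        return [ts.label for ts in self.traces]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: first column time in seconds, one column per trace."""
        data = {"time_s": self.traces[0].times}
        for ts in self.traces:
            data[ts.label or f"trace{len(data)}"] = ts.values
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        """Write traces as delimited text; ground truth in a sidecar JSON."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.ground_truth:
            sidecar = path.with_suffix(path.suffix + ".groundtruth.json")
            payload = {k: np.asarray(v).tolist() for k, v in self.ground_truth.items()}
            sidecar.write_text(json.dumps(payload))

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "TrialSet":
        path = Path(path)
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("expected a 'time_s' first column")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("need at least two rows")
        dt = float(np.median(np.diff(t)))
        traces = [
            TimeSeries(df[c].to_numpy(), dt=dt, label=str(c))
            for c in df.columns
            if c != "time_s"
        ]
        ground_truth = {}
        sidecar = path.with_suffix(path.suffix + ".groundtruth.json")
        if sidecar.exists():
            ground_truth = {
                k: np.asarray(v, float)
                for k, v in json.loads(sidecar.read_text()).items()
            }
        return cls(traces, name=name or path.stem, ground_truth=ground_truth)


@dataclass
class SessionData:
    """One multi-ROI session: a time x ROI matrix plus optional extras.

    ``dmn_mask`` names the ROIs belonging to the default-mode network;
    ``component_traces`` carries named component time courses (e.g. a
    DMN-ICA-like trace, or the generator's ground-truth components);
    ``voxel_traces`` optionally holds a finer-grained time x voxel matrix.
    """

    roi_traces: np.ndarray
    roi_labels: list[str]
    dmn_mask: list[str] = field(default_factory=list)
    voxel_traces: np.ndarray | None = None
    component_traces: dict[str, np.ndarray] = field(default_factory=dict)
    dt: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.roi_traces = np.asarray(self.roi_traces, dtype=float)
        if self.roi_traces.ndim != 2:
            raise ValueError("roi_traces must be 2-D (time x ROI)")
        if self.roi_traces.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels must match the number of ROI columns")
        unknown = set(self.dmn_mask) - set(self.roi_labels)
        if unknown:
            raise ValueError(f"dmn_mask names not in roi_labels: {sorted(unknown)}")
        n_t = self.roi_traces.shape[0]
        for key, trace in self.component_traces.items():
            if np.asarray(trace).shape[0] != n_t:
                raise ValueError(f"component trace {key!r} has wrong length")
        if self.voxel_traces is not None and self.voxel_traces.shape[0] != n_t:
            raise ValueError("voxel_traces time dimension mismatch")

    @property
    def n_timepoints(self) -> int:
        return self.roi_traces.shape[0]

    @property
    def n_rois(self) -> int:
        return self.roi_traces.shape[1]

    def roi(self, label: str) -> TimeSeries:
        """Extract one ROI trace by label."""
        try:
            idx = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"ROI {label!r} not in session {self.name!r}") from None
        return TimeSeries(self.roi_traces[:, idx], dt=self.dt, label=label)

    def global_signal(self) -> TimeSeries:
        """Unweighted mean across all ROIs present in the session."""
        return TimeSeries(
            self.roi_traces.mean(axis=1), dt=self.dt, label="global"
        )

    def dmn_traces(self) -> np.ndarray:
        """Time x ROI matrix restricted to DMN ROIs."""
        idx = [self.roi_labels.index(lbl) for lbl in self.dmn_mask]
        if not idx:
            raise ValueError("session has no DMN ROIs")
        return self.roi_traces[:, idx]
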