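"""Prediction-score-based brain-state classification of sessions.

A GRU trained on vessel-specific slow oscillations is applied to a named
ROI trace of every session; each session's prediction score (CC) becomes a
one-number brain-state index. The module then relates that index to the
session's functional-connectivity structure:

* percentile grouping (top/bottom 5% of scores) and seed-based correlation
  difference maps between the groups, masked by FDR-controlled two-sample
  tests on Fisher-z values;
* the intrinsic DMN correlation (mean correlation of a DMN component trace
  with individual DMN voxel/ROI signals) and its binned relationship to the
  prediction score — the headline observation is that internal DMN
  correlation *decreases* as the prediction score (global slow-fluctuation
  strength) increases;
* an alternative classification by global-signal variance, for contrast;
* Laplacian spectral reordering of correlation matrices (Fiedler vector),
  clustering ROIs with similar correlation profiles;
* spectral-preference probing of a trained model with synthetic
  narrow-band signals over a grid of peak frequencies and widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from . import evaluation
from .preprocess import SpectralConfig, make_target_pair
from .timeseries import BandSpec, SessionData, TimeSeries

__all__ = [
    "score_sessions",
    "percentile_groups",
    "seed_correlation_map",
    "difference_map",
    "intrinsic_dmn_correlation",
    "binned_relationship",
    "variance_groups",
    "spectral_reorder",
    "probe_preference_map",
    "DifferenceMap",
]


def score_sessions(
    results,
    sessions: list[SessionData],
    roi: str,
    band: BandSpec = BandSpec(0.01, 0.1),
    shift: float = 10.0,
    cfg: SpectralConfig = SpectralConfig(),
) -> pd.DataFrame:
    """Score every session by predicting the named ROI trace.

    ``results`` is a fitted :class:`slowosc.gru.GRUForecasterResults`. Each
    session's ROI trace is normalised, paired with its band-passed shifted
    target and predicted; the table records CC, lag, the global-signal
    variance and, when a ``"dmn_ica"`` component trace is present, the
    intrinsic DMN correlation. Sessions missing the ROI are recorded with
    NaN scores and an error message; the rest proceed.
    """
    rows = []
    for sess in sessions:
        row = {"session": sess.name, "roi": roi}
        try:
            ts = sess.roi(roi)
            pair = make_target_pair(ts, band, shift=shift, cfg=cfg)
            rec = results.predict(pair)
            row["prediction_cc"] = rec.cc
            row["lag_s"] = rec.lag
        except (KeyError, ValueError) as exc:
            row["prediction_cc"] = np.nan
            row["lag_s"] = np.nan
            row["error"] = str(exc)
        row["global_variance"] = float(np.var(sess.global_signal().values))
        if "dmn_ica" in sess.component_traces and sess.dmn_mask:
            row["intrinsic_dmn_corr"] = intrinsic_dmn_correlation(
                sess.component_traces["dmn_ica"], sess.dmn_traces()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def percentile_groups(scores: np.ndarray, pct: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ceil(pct*n) largest and smallest scores.

    Ties are broken by stable original order: with all-equal scores the
    bottom group is the first k indices and the top group the last k.
    """
    scores = np.asarray(scores, float)
    if not (0.0 < pct < 0.5):
        raise ValueError("pct must be in (0, 0.5)")
    n = scores.size
    k = int(np.ceil(pct * n))
    if k < 1 or n * pct < 1:
        raise ValueError(f"pct {pct} selects no sessions out of {n}")
    order = np.argsort(scores, kind="stable")
    bottom = order[:k]
    top = order[-k:]
    return top, bottom


def seed_correlation_map(seed_trace: np.ndarray, traces_matrix: np.ndarray
                         ) -> np.ndarray:
    """Pearson correlation of the seed with each column of a time x node matrix.

    Zero-variance columns yield NaN with a warning.
    """
    seed = np.asarray(seed_trace, float)
    mat = np.asarray(traces_matrix, float)
    if mat.ndim != 2 or mat.shape[0] != seed.size:
        raise ValueError("traces_matrix must be time x nodes, aligned with seed")
    s = seed - seed.mean()
    ss = np.linalg.norm(s)
    if ss == 0:
        raise ValueError("zero-variance seed")
    m = mat - mat.mean(axis=0)
    norms = np.linalg.norm(m, axis=0)
    out = np.full(mat.shape[1], np.nan)
    good = norms > 0
    if not np.all(good):
        warnings.warn(f"{int((~good).sum())} zero-variance column(s): NaN")
    out[good] = (s @ m[:, good]) / (ss * norms[good])
    return out


@dataclass
class DifferenceMap:
    """Mean seed-correlation difference between two session groups."""

    difference: np.ndarray
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray

    @property
    def masked(self) -> np.ndarray:
        """Difference with insignificant nodes set to NaN."""
        out = self.difference.copy()
        out[~self.significant] = np.nan
        return out


def difference_map(maps_top: np.ndarray, maps_bottom: np.ndarray,
                   q: float = 0.05) -> DifferenceMap:
    """mean(top) - mean(bottom) per node, FDR-masked significance.

    ``maps_*`` are (n_sessions, n_nodes) arrays of correlation values.
    """
    top = np.atleast_2d(np.asarray(maps_top, float))
    bot = np.atleast_2d(np.asarray(maps_bottom, float))
    if top.shape[0] < 2 or bot.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    diff = top.mean(axis=0) - bot.mean(axis=0)
    t, p = evaluation.two_sample_fisher_test(top, bot)
    _, reject = evaluation.fdr_adjust(p, q=q)
    return DifferenceMap(difference=diff, t=t, p=p, significant=reject)


def intrinsic_dmn_correlation(dmn_component_trace: np.ndarray,
                              dmn_voxel_traces: np.ndarray) -> float:
    """Mean over DMN voxels of their correlation with the component trace.

    Note the order: the mean of correlations, not the correlation with the
    mean voxel trace (the two differ whenever voxels disagree).
    """
    comp = np.asarray(dmn_component_trace, float)
    mat = np.atleast_2d(np.asarray(dmn_voxel_traces, float))
    if mat.shape[1] == 0:
        raise ValueError("empty DMN voxel set")
    if mat.shape[0] != comp.size:
        raise ValueError("component and voxel traces must be aligned in time")
    corrs = seed_correlation_map(comp, mat)
    return float(np.nanmean(corrs))


def binned_relationship(scores: np.ndarray, values: np.ndarray,
                        bin_pct: float = 0.02
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sort sessions by score and average score/value in consecutive bins.

    Bin size is floor(n * bin_pct) sessions; the remainder joins the last
    bin. Returns (bin mean scores, bin mean values).
    """
    scores = np.asarray(scores, float)
    values = np.asarray(values, float)
    if scores.shape != values.shape:
        raise ValueError("scores and values must be aligned")
    n = scores.size
    size = int(np.floor(n * bin_pct))
    if size < 1:
        raise ValueError(f"{n} sessions cannot fill bins of fraction {bin_pct}")
    n_bins = n // size
    order = np.argsort(scores, kind="stable")
    bin_scores = np.empty(n_bins)
    bin_values = np.empty(n_bins)
    for b in range(n_bins):
        lo = b * size
        hi = (b + 1) * size if b < n_bins - 1 else n  # remainder to last bin
        idx = order[lo:hi]
        bin_scores[b] = scores[idx].mean()
        bin_values[b] = values[idx].mean()
    return bin_scores, bin_values


def variance_groups(table: pd.DataFrame, pct: float = 0.05,
                    score_col: str = "prediction_cc",
                    var_col: str = "global_variance") -> dict:
    """Classify sessions by global-signal variance; compare to score groups.

    Returns a report with the variance-based and score-based top/bottom
    index sets, their overlaps, summary spreads, and log-variance binned
    curves against the intrinsic DMN correlation when available. Sessions
    with zero variance are excluded from the log curves with a warning.
    """
    var = table[var_col].to_numpy()
    scores = table[score_col].to_numpy()
    v_top, v_bottom = percentile_groups(var, pct)
    s_top, s_bottom = percentile_groups(scores, pct)
    report = {
        "variance_top": v_top, "variance_bottom": v_bottom,
        "score_top": s_top, "score_bottom": s_bottom,
        "overlap_top": np.intersect1d(v_top, s_top),
        "overlap_bottom": np.intersect1d(v_bottom, s_bottom),
        "score_top_variance_range": (
            float(var[s_top].min()), float(var[s_top].max())
        ),
        "variance_range": (float(var.min()), float(var.max())),
    }
    if "intrinsic_dmn_corr" in table.columns:
        good = var > 0
        if not np.all(good):
            warnings.warn(f"{int((~good).sum())} zero-variance session(s) "
                          "excluded from log-variance curves")
        log_var = np.log(var[good])
        dmn = table["intrinsic_dmn_corr"].to_numpy()[good]
        report["logvar_curve"] = binned_relationship(log_var, dmn)
    return report


def spectral_reorder(corr_matrix: np.ndarray) -> np.ndarray:
    """Permutation ordering ROIs by the graph Laplacian's Fiedler vector.

    The affinity is A = (corr + 1)/2 with a zeroed diagonal; the Fiedler
    vector (eigenvector of the second-smallest Laplacian eigenvalue) is
    sign-fixed so its first entry is nonnegative, and rows are ordered by
    their Fiedler loading. A disconnected affinity graph is ordered
    per-component with a warning.
    """
    C = np.asarray(corr_matrix, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("need a square matrix")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("need a symmetric matrix")
    n = C.shape[0]
    A = (C + 1.0) / 2.0
    np.fill_diagonal(A, 0.0)
    n_comp, labels = connected_components(A > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"affinity graph has {n_comp} components; ordering per component"
        )
        perm_parts = []
        for comp in range(n_comp):
            idx = np.flatnonzero(labels == comp)
            if idx.size == 1:
                perm_parts.append(idx)
            else:
                sub = spectral_reorder(C[np.ix_(idx, idx)])
                perm_parts.append(idx[sub])
        return np.concatenate(perm_parts)
    L = np.diag(A.sum(axis=1)) - A
    eigvals, eigvecs = np.linalg.eigh(L)
    fiedler = eigvecs[:, 1]
    if fiedler[0] < 0:
        fiedler = -fiedler
    return np.argsort(fiedler, kind="stable")


def probe_preference_map(
    results,
    f0_grid: np.ndarray,
    width_grid: np.ndarray,
    n_seeds: int = 3,
    n_timepoints: int = 900,
    dt: float = 1.0,
    band: BandSpec = BandSpec(0.01, 0.1),
    shift: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Mean prediction CC over seeded probe signals for each (f0, width).

    Probes are narrow-band Gaussian-envelope signals; each is preprocessed
    exactly like a vessel trace (normalise, band-pass + shift target) and
    predicted by the fitted model. Returns a |f0_grid| x |width_grid|
    matrix of seed-averaged CCs.
    """
    from .synth import generate_probe_signal  # local import: synth uses containers only

    f0_grid = np.asarray(f0_grid, float)
    width_grid = np.asarray(width_grid, float)
    if f0_grid.size == 0 or width_grid.size == 0:
        raise ValueError("empty probe grid")
    out = np.empty((f0_grid.size, width_grid.size))
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for i, f0 in enumerate(f0_grid):
        for j, width in enumerate(width_grid):
            ccs = []
            for s in base:
                probe = generate_probe_signal(f0, width, n_timepoints, dt, int(s))
                pair = make_target_pair(probe, band, shift=shift)
                ccs.append(results.predict(pair).cc)
            out[i, j] = float(np.mean(ccs))
    return out
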