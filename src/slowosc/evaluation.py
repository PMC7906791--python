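"""Scoring and statistics for prediction records and group comparisons.

Conventions:

* The prediction score is the Pearson correlation (CC) between the
  predicted and the target band-limited signal over post-washout samples.
* Cross-correlation lags are computed between z-scored series; a positive
  lag means the prediction is *delayed* relative to the target, a negative
  lag that it runs early.
* Sliding-window score signals use a centered 30 s window; the first and
  last 15 values are based on shorter (truncated) windows.
* All correlations are Fisher z-transformed (atanh) before t-tests, and
  families of p-values are controlled for false discovery rate with the
  Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_cc",
    "xcorr_lag",
    "sliding_window_cc",
    "paired_fisher_test",
    "two_sample_fisher_test",
    "fdr_adjust",
]


def pearson_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    pa = a - a.mean()
    pb = b - b.mean()
    sa, sb = np.linalg.norm(pa), np.linalg.norm(pb)
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(pa @ pb / (sa * sb))


def xcorr_lag(
    pred: np.ndarray,
    target: np.ndarray,
    dt: float = 1.0,
    max_lag: int | None = None,
) -> float:
    """Lag (seconds) of the cross-correlation maximum between z-scored series.

    ``pred(t) = target(t - k)`` (prediction delayed by k samples) yields
    ``+k*dt``. With ``max_lag=None`` all lags with full-overlap information
    (|lag| < n) are searched.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape or pred.size < 3:
        raise ValueError("need equal-length vectors, n >= 3")
    if pred.std() == 0 or target.std() == 0:
        raise ValueError("flat input: cross-correlation undefined")
    zp = (pred - pred.mean()) / pred.std()
    zt = (target - target.mean()) / target.std()
    c = np.correlate(zp, zt, mode="full")
    n = pred.size
    lags = np.arange(-(n - 1), n)
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        c, lags = c[keep], lags[keep]
    return float(lags[int(np.argmax(c))] * dt)


def sliding_window_cc(
    pred: np.ndarray,
    target: np.ndarray,
    window: float = 30.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Per-timepoint CC in a centered window of ``window`` seconds.

    The half-width is ``round(window / (2 dt))`` samples (15 at dt = 1 s),
    so the interior window covers center +- half-width; windows at the
    edges are truncated to the available data. Output length equals input
    length; points whose truncated window holds fewer than 3 samples, or
    has zero variance, are NaN.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape or pred.ndim != 1:
        raise ValueError("need equal-length 1-D vectors")
    half = int(round(window / (2.0 * dt)))
    n = pred.size
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if hi - lo < 3:
            continue
        p = pred[lo:hi]
        t = target[lo:hi]
        if p.std() == 0 or t.std() == 0:
            continue
        out[i] = pearson_cc(p, t)
    return out


def _check_ccs(ccs: np.ndarray) -> np.ndarray:
    ccs = np.asarray(ccs, float)
    if np.any(np.abs(ccs) >= 1.0):
        raise ValueError("|cc| = 1 present: Fisher z-transform is infinite")
    return np.arctanh(ccs)


def paired_fisher_test(real_ccs: np.ndarray, surrogate_ccs: np.ndarray
                       ) -> tuple[float, float]:
    """Paired t-test on Fisher z-transformed correlation pairs.

    Returns (t, p); t > 0 means real scores exceed surrogate scores.
    """
    za = _check_ccs(real_ccs)
    zb = _check_ccs(surrogate_ccs)
    if za.shape != zb.shape or za.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(za == zb):  # zero differences: no evidence either way
        return 0.0, 1.0
    res = stats.ttest_rel(za, zb)
    return float(res.statistic), float(res.pvalue)


def two_sample_fisher_test(
    group_a_maps: np.ndarray,
    group_b_maps: np.ndarray,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node two-sample t-test on Fisher z-transformed correlation maps.

    ``group_*_maps`` are (n_maps, n_nodes) arrays of correlations. Nodes
    with zero variance in both groups get t = 0, p = 1 with a warning.
    Returns per-node (t, p) vectors.
    """
    za = _check_ccs(np.atleast_2d(group_a_maps))
    zb = _check_ccs(np.atleast_2d(group_b_maps))
    if za.shape[0] < 2 or zb.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    if za.shape[1] != zb.shape[1]:
        raise ValueError("groups must share the node dimension")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(za, zb, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} node(s) with degenerate variance; p set to 1"
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    return t, p


def fdr_adjust(pvals: np.ndarray, q: float = 0.05
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns (adjusted_p, reject_mask) at level ``q``; empty input yields
    empty output.
    """
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject
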