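"""ARMAX baseline: estimation, multi-step forecasting, order grid search.

The model, in the convention with the autoregressive polynomial on the
left-hand side, is

    y(t) + a_1 y(t-1) + ... + a_na y(t-n_a)
        = b_1 u(t-n_k) + ... + b_nb u(t-n_k-n_b+1)
        + c_1 e(t-1) + ... + c_nc e(t-n_c) + e(t)

where u is the exogenous input (the normalised raw vessel trace), y the
output (the band-passed slow oscillation, not shifted) and e white noise.
The delay ``n_k = 10`` realises the 10-s-ahead prediction scheme: a
10-step-ahead forecast then involves only already-observed inputs.

Estimation is the classical two-stage Hannan-Rissanen procedure (long-AR
residual proxy, then least squares including lagged residuals) refined by
Gauss-Newton minimisation of the recursively computed one-step prediction
errors. Unstable or non-invertible estimates are flagged on the result,
never silently accepted. Forecasts use zero future innovations (the
minimum-MSE predictor).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import evaluation

__all__ = [
    "ARMAXOrder",
    "ARMAXModel",
    "ARMAX",
    "ARMAXResults",
    "fit_armax",
    "forecast_armax",
    "forecast_series",
    "grid_search_orders",
]


@dataclass(frozen=True)
class ARMAXOrder:
    """(n_a, n_b, n_c, n_k): past outputs, inputs, errors, and input delay."""

    n_a: int
    n_b: int
    n_c: int = 0
    n_k: int = 10

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 0 or self.n_c < 0 or self.n_k < 0:
            raise ValueError("orders must satisfy n_a >= 1, n_b, n_c, n_k >= 0")

    @property
    def max_lag(self) -> int:
        lags = [self.n_a, self.n_c]
        if self.n_b > 0:
            lags.append(self.n_k + self.n_b - 1)
        return max(lags)


@dataclass
class ARMAXModel:
    """Estimated coefficients in the left-hand-side sign convention.

    ``a`` multiplies past outputs on the LEFT of the equation (so the
    one-step predictor subtracts them); an AR(1) with a_1 = -phi is
    y(t) = phi*y(t-1) + e(t).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    order: ARMAXOrder
    noise_variance: float
    stable: bool = True
    invertible: bool = True
    sign_convention: str = "a on the left-hand side"

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(), "b": self.b.tolist(), "c": self.c.tolist(),
            "order": {"n_a": self.order.n_a, "n_b": self.order.n_b,
                      "n_c": self.order.n_c, "n_k": self.order.n_k},
            "noise_variance": self.noise_variance,
            "stable": self.stable, "invertible": self.invertible,
            "sign_convention": self.sign_convention,
        }


def _poly_is_stable(coeffs: np.ndarray) -> bool:
    """Roots of 1 + c_1 q^-1 + ... outside the unit circle <=> z-roots inside."""
    if coeffs.size == 0:
        return True
    roots = np.roots(np.concatenate([[1.0], coeffs]))
    return bool(np.all(np.abs(roots) < 1.0 + 1e-9))


def _residuals(theta: np.ndarray, y: np.ndarray, u: np.ndarray,
               order: ARMAXOrder) -> np.ndarray:
    """Recursive one-step prediction errors e(t) for t >= max_lag."""
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    a = theta[:na]
    b = theta[na:na + nb]
    c = theta[na + nb:]
    n = y.size
    t0 = order.max_lag
    e = np.zeros(n)
    for t in range(t0, n):
        val = y[t]
        for i in range(na):
            val += a[i] * y[t - 1 - i]
        for j in range(nb):
            val -= b[j] * u[t - nk - j]
        for k in range(nc):
            val -= c[k] * e[t - 1 - k]
        e[t] = val
    return e[t0:]


def _hannan_rissanen(y: np.ndarray, u: np.ndarray, order: ARMAXOrder
                     ) -> np.ndarray:
    """Two-stage initial estimate: long-ARX residuals, then full LS."""
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    n = y.size

    if nc > 0:
        # stage 1: long ARX to proxy the innovations
        p = min(max(20, 2 * (na + nb + nc)), n // 4)
        t0 = max(p, nk + nb - 1 if nb > 0 else 0)
        rows = []
        for t in range(t0, n):
            row = [-y[t - 1 - i] for i in range(p)]
            row += [u[t - nk - j] for j in range(nb)]
            rows.append(row)
        A1 = np.asarray(rows)
        coef1, *_ = np.linalg.lstsq(A1, y[t0:], rcond=None)
        e_hat = np.zeros(n)
        e_hat[t0:] = y[t0:] - A1 @ coef1
    else:
        e_hat = np.zeros(n)

    # stage 2: LS with lagged outputs, delayed inputs and residual proxies
    t0 = order.max_lag
    rows = []
    for t in range(t0, n):
        row = [-y[t - 1 - i] for i in range(na)]
        row += [u[t - nk - j] for j in range(nb)]
        row += [e_hat[t - 1 - k] for k in range(nc)]
        rows.append(row)
    A2 = np.asarray(rows)
    theta, *_ = np.linalg.lstsq(A2, y[t0:], rcond=None)
    return theta


def fit_armax(y: np.ndarray, u: np.ndarray, order: ARMAXOrder,
              refine: bool = True) -> ARMAXModel:
    """Estimate ARMAX coefficients by prediction-error minimisation.

    Hannan-Rissanen initialisation; when ``refine`` and n_c > 0, Gauss-
    Newton (Levenberg-Marquardt) refinement of the recursive prediction
    errors. With n_c = 0 the least-squares solution is already the
    prediction-error minimiser.
    """
    y = np.asarray(y, float)
    u = np.asarray(u, float)
    if y.shape != u.shape or y.ndim != 1:
        raise ValueError("y and u must be aligned 1-D series")
    n_params = order.n_a + order.n_b + order.n_c
    if y.size < 4 * max(n_params, order.max_lag + 1):
        raise ValueError(
            f"series of length {y.size} too short for order {order}"
        )
    theta = _hannan_rissanen(y, u, order)
    if refine and order.n_c > 0:
        sol = least_squares(
            _residuals, theta, args=(y, u, order), method="lm",
            max_nfev=200 * (n_params + 1),
        )
        theta = sol.x
    e = _residuals(theta, y, u, order)
    na, nb = order.n_a, order.n_b
    a, b, c = theta[:na], theta[na:na + nb], theta[na + nb:]
    return ARMAXModel(
        a=a, b=b, c=c, order=order,
        noise_variance=float(np.var(e)),
        stable=_poly_is_stable(a),
        invertible=_poly_is_stable(c),
    )


def training_residuals(model: ARMAXModel, y: np.ndarray, u: np.ndarray
                       ) -> np.ndarray:
    """One-step prediction errors e(t) on data, t >= max_lag."""
    theta = np.concatenate([model.a, model.b, model.c])
    return _residuals(theta, np.asarray(y, float), np.asarray(u, float),
                      model.order)


def forecast_armax(model: ARMAXModel, y_hist: np.ndarray, u: np.ndarray,
                   horizon: int = 10) -> np.ndarray:
    """h-step-ahead forecasts with future innovations set to zero.

    Given history ``y_hist[0..N-1]`` and inputs ``u`` (known up to N-1;
    with n_k >= horizon no future input is needed), returns forecasts for
    times N .. N+horizon-1. For AR(1) with y(t) = phi*y(t-1) + e this is
    phi^h * y[N-1].
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    y_hist = np.asarray(y_hist, float)
    u = np.asarray(u, float)
    order = model.order
    if y_hist.size < order.max_lag:
        raise ValueError("history shorter than the model's maximal lag")
    n = y_hist.size
    # innovations over the history; future innovations are zero
    theta = np.concatenate([model.a, model.b, model.c])
    e_tail = _residuals(theta, y_hist, u, order)
    e = np.zeros(n + horizon)
    e[order.max_lag:n] = e_tail
    y_ext = np.concatenate([y_hist, np.zeros(horizon)])
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    for t in range(n, n + horizon):
        val = 0.0
        for i in range(na):
            val -= model.a[i] * y_ext[t - 1 - i]
        for j in range(nb):
            src = t - nk - j
            if src >= n:
                raise ValueError(
                    "forecast requires future inputs: horizon exceeds n_k"
                )
            if src >= 0:
                val += model.b[j] * u[src]
        for k in range(nc):
            val += model.c[k] * e[t - 1 - k]
        y_ext[t] = val
    return y_ext[n:]


def forecast_series(model: ARMAXModel, y: np.ndarray, u: np.ndarray,
                    horizon: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Rolling h-step-ahead forecast over a whole series.

    Returns (t_index, forecasts): forecasts[i] is the prediction of
    y[t_index[i]] made from data up to t_index[i] - horizon. Vectorised
    recursion over origins, O(horizon * (n_a+n_b+n_c) * n).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    y = np.asarray(y, float)
    u = np.asarray(u, float)
    order = model.order
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    n = y.size
    theta = np.concatenate([model.a, model.b, model.c])
    e = np.zeros(n)
    e[order.max_lag:] = _residuals(theta, y, u, order)

    first_origin = order.max_lag  # earliest time with a defined predictor
    origins = np.arange(first_origin, n - horizon)  # forecast y[origin+horizon]
    if origins.size == 0:
        raise ValueError("series too short for the requested horizon")
    # y_steps[s, i]: forecast of y[origins[i] + s] given data up to origins[i]
    y_steps = np.zeros((horizon + 1, origins.size))
    y_steps[0] = y[origins]
    with np.errstate(over="raise", invalid="raise"):
        return _forecast_series_recursion(
            model, y, u, e, origins, y_steps, horizon)


def _forecast_series_recursion(model, y, u, e, origins, y_steps, horizon):
    order = model.order
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    for s in range(1, horizon + 1):
        t = origins + s
        val = np.zeros(origins.size)
        for i in range(na):
            lag_t = t - 1 - i
            back = s - 1 - i
            if back >= 1:
                val -= model.a[i] * y_steps[back]
            else:
                val -= model.a[i] * y[lag_t]
        for j in range(nb):
            src = t - nk - j
            valid = src <= origins  # only past inputs may enter
            if not np.all(valid):
                raise ValueError("forecast requires future inputs")
            val += model.b[j] * np.where(src >= 0, u[np.clip(src, 0, None)], 0.0)
        for k in range(nc):
            back = s - 1 - k
            if back < 1:  # innovation already observed at forecast time
                lag_t = t - 1 - k
                val += model.c[k] * np.where(lag_t <= origins, e[lag_t], 0.0)
            # future innovations are zero
        y_steps[s] = val
    return origins + horizon, y_steps[horizon]


def simulate(model: ARMAXModel, u: np.ndarray) -> np.ndarray:
    """Noise-free simulation driven by the input alone: y_hat = (B/A) u.

    With ``n_k = 10`` the simulated output at time t involves u only up to
    t - 10, realising the 10-s-ahead prediction scheme with exactly the
    information the recurrent predictor receives (no access to the true
    output history). This is the evaluation used for the GRU-vs-ARMAX
    comparison.
    """
    u = np.asarray(u, float)
    order = model.order
    na, nb, nk = order.n_a, order.n_b, order.n_k
    n = u.size
    y_hat = np.zeros(n)
    with np.errstate(over="raise", invalid="raise"):
        for t in range(n):
            val = 0.0
            for j in range(nb):
                src = t - nk - j
                if src >= 0:
                    val += model.b[j] * u[src]
            for i in range(na):
                if t - 1 - i >= 0:
                    val -= model.a[i] * y_hat[t - 1 - i]
            y_hat[t] = val
    return y_hat


def _multi_fit(series: list[tuple[np.ndarray, np.ndarray]], order: ARMAXOrder,
               refine: bool = False) -> ARMAXModel:
    """One model for several (y, u) records: jointly stacked estimation.

    Stage-1 innovation proxies are computed per record; the stage-2 least
    squares then stacks all records' regression rows, giving a single
    coherent coefficient set (multi-experiment estimation).
    """
    na, nb, nc, nk = order.n_a, order.n_b, order.n_c, order.n_k
    blocks_A, blocks_y = [], []
    for y, u in series:
        y = np.asarray(y, float)
        u = np.asarray(u, float)
        if nc > 0:
            p = min(max(20, 2 * (na + nb + nc)), y.size // 4)
            t0 = max(p, nk + nb - 1 if nb > 0 else 0)
            rows = []
            for t in range(t0, y.size):
                row = [-y[t - 1 - i] for i in range(p)]
                row += [u[t - nk - j] for j in range(nb)]
                rows.append(row)
            A1 = np.asarray(rows)
            coef1, *_ = np.linalg.lstsq(A1, y[t0:], rcond=None)
            e_hat = np.zeros(y.size)
            e_hat[t0:] = y[t0:] - A1 @ coef1
        else:
            e_hat = np.zeros(y.size)
        t0 = order.max_lag
        rows = []
        for t in range(t0, y.size):
            row = [-y[t - 1 - i] for i in range(na)]
            row += [u[t - nk - j] for j in range(nb)]
            row += [e_hat[t - 1 - k] for k in range(nc)]
            rows.append(row)
        blocks_A.append(np.asarray(rows))
        blocks_y.append(y[t0:])
    A = np.vstack(blocks_A)
    rhs = np.concatenate(blocks_y)
    theta, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    a, b, c = theta[:na], theta[na:na + nb], theta[na + nb:]
    var = float(np.mean([
        np.var(_residuals(theta, np.asarray(y, float), np.asarray(u, float),
                          order))
        for y, u in series
    ]))
    return ARMAXModel(a=a, b=b, c=c, order=order, noise_variance=var,
                      stable=_poly_is_stable(a), invertible=_poly_is_stable(c))


DESK_GRID = {
    "n_a": range(1, 11),
    "n_b": range(1, 11),
    "n_c": range(0, 6),
}
# The exhaustive grid (1-50 step 1, plus 1-150 step 5 per order) is
# cluster-scale; enable explicitly via grid_spec.
FULL_GRID = {
    "n_a": sorted(set(range(1, 51)) | set(range(1, 151, 5))),
    "n_b": sorted(set(range(1, 51)) | set(range(1, 151, 5))),
    "n_c": sorted(set(range(1, 51)) | set(range(1, 151, 5))),
}


def grid_search_orders(
    series: list[tuple[np.ndarray, np.ndarray]],
    grid_spec: dict | None = None,
    n_k: int = 10,
    horizon: int = 10,
    washout: int = 0,
    score: str = "forecast",
) -> tuple[ARMAXOrder, pd.DataFrame]:
    """Exhaustive (n_a, n_b, n_c) search by cross-validated prediction CC.

    Leave-one-record-out: each record is scored by a model fitted on the
    remaining records (or, with a single record, on itself). ``score``
    selects the evaluation: ``"forecast"`` scores rolling h-step forecasts
    from the true output history, ``"simulate"`` scores the input-driven
    noise-free simulation (the information-matched comparison with the
    recurrent predictor). Returns the argmax order and the full score
    table; cells whose fits fail score NaN, and an error is raised only if
    every cell fails.
    """
    grid_spec = DESK_GRID if grid_spec is None else grid_spec
    if score not in ("forecast", "simulate"):
        raise ValueError(f"unknown score {score!r}")
    cells = list(product(grid_spec["n_a"], grid_spec["n_b"], grid_spec["n_c"]))
    if not cells:
        raise ValueError("empty grid")
    rows = []
    failures = []
    for n_a, n_b, n_c in cells:
        order = ARMAXOrder(n_a=n_a, n_b=n_b, n_c=n_c, n_k=n_k)
        ccs = []
        try:
            with np.errstate(over="raise"):
                for i, (y, u) in enumerate(series):
                    train = [s for j, s in enumerate(series) if j != i] or series
                    model = _multi_fit(train, order, refine=False)
                    if score == "simulate":
                        y_hat = simulate(model, u)
                        ccs.append(evaluation.pearson_cc(y_hat[washout:],
                                                         y[washout:]))
                    else:
                        t_idx, preds = forecast_series(model, y, u,
                                                       horizon=horizon)
                        keep = t_idx >= washout
                        ccs.append(evaluation.pearson_cc(preds[keep],
                                                         y[t_idx[keep]]))
            score_val = float(np.mean(ccs))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append((order, str(exc)))
            score_val = np.nan
        rows.append({"n_a": n_a, "n_b": n_b, "n_c": n_c, "cv_cc": score_val})
    table = pd.DataFrame(rows)
    if table["cv_cc"].isna().all():
        detail = "; ".join(f"{o}: {msg}" for o, msg in failures[:5])
        raise RuntimeError(f"all grid cells failed to fit: {detail}")
    best_row = table.loc[table["cv_cc"].idxmax()]
    best = ARMAXOrder(n_a=int(best_row["n_a"]), n_b=int(best_row["n_b"]),
                      n_c=int(best_row["n_c"]), n_k=n_k)
    return best, table


# ---------------------------------------------------------------------------
# statsmodels-style surface


class ARMAX:
    """ARMAX model of a (y, u) record pair; ``fit()`` returns results."""

    def __init__(self, y: np.ndarray, u: np.ndarray, order: ARMAXOrder):
        self.y = np.asarray(y, float)
        self.u = np.asarray(u, float)
        self.order = order

    def fit(self, refine: bool = True) -> "ARMAXResults":
        model = fit_armax(self.y, self.u, self.order, refine=refine)
        return ARMAXResults(self, model)


class ARMAXResults:
    """Fitted ARMAX model with forecasting and a summary table."""

    def __init__(self, parent: ARMAX, model: ARMAXModel):
        self.parent = parent
        self.model = model

    @property
    def a(self) -> np.ndarray:
        return self.model.a

    @property
    def b(self) -> np.ndarray:
        return self.model.b

    @property
    def c(self) -> np.ndarray:
        return self.model.c

    def resid(self) -> np.ndarray:
        return training_residuals(self.model, self.parent.y, self.parent.u)

    def forecast(self, horizon: int = 10) -> np.ndarray:
        return forecast_armax(self.model, self.parent.y, self.parent.u, horizon)

    def forecast_series(self, horizon: int = 10) -> tuple[np.ndarray, np.ndarray]:
        return forecast_series(self.model, self.parent.y, self.parent.u, horizon)

    def summary(self) -> str:
        m = self.model
        o = m.order
        lines = [
            "ARMAX prediction-error fit",
            "=" * 47,
            f"order (n_a, n_b, n_c, n_k) = ({o.n_a}, {o.n_b}, {o.n_c}, {o.n_k})",
            f"sign convention: {m.sign_convention}",
            f"noise variance {m.noise_variance:.6g}",
            f"stable={m.stable}  invertible={m.invertible}",
            "-" * 47,
        ]
        for name, vec in (("a", m.a), ("b", m.b), ("c", m.c)):
            for i, v in enumerate(vec, start=1):
                lines.append(f"  {name}_{i:<3} {v:>+12.6f}")
        lines.append("=" * 47)
        return "\n".join(lines)
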