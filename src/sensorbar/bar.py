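"""Bernoulli autoregressive core: component recursions, likelihood, gradient.

The model for a binary sensor series y_t on the 15-minute grid is

    Y_t | F_{t-1} ~ Bernoulli(p_t),      logit(p_t) = Δ_t,
    Δ_t = a + b_t + Σ_j c_{j,t} + d_t,

where each component spikes when its driving sensor fired in the previous
bin and then decays geometrically (a discrete-time, Hawkes-inspired
self-excitation):

    b_t     = φ_b b_{t-1}   + π_b y_{t-1}              (autoregressive)
    c_{j,t} = ψ_j c_{j,t-1} + τ_j z_{j,t-1}            (covariate sensor j)
    d_t     = φ_d d_{t-96}  + π_d max(y_{t-97..t-95})  (daily seasonal)

with b_1 = c_{j,1} = 0 and d_t = 0 for the whole first day (t ≤ 96; the
seasonal driver looks one day back across a 45-minute window, letting
routine timing drift by ±15 minutes).  Each recursion telescopes to a
geometric sum over the driver's history, which the tests check directly.

All recursions are evaluated with `scipy.signal.lfilter` (they are linear
IIR filters), so a likelihood or gradient evaluation is O(T) in C.
Indexing is 0-based internally; the public ``seasonal_driver`` follows the
1-based convention used for time-of-day bins 1..96.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .events import BINS_PER_DAY, BinarySensorSeries, HouseholdSeries
from .params import ModelParams

LAG = BINS_PER_DAY  # seasonal lag: one day = 96 bins


def _lag1(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    out[1:] = x[:-1]
    return out


def _lag96(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    out[LAG:] = x[:-LAG]
    return out


def _decay_recursion(spike: float, decay: float, driver: np.ndarray) -> np.ndarray:
    """x_t = decay * x_{t-1} + spike * driver_{t-1}, x_0 = 0."""
    return lfilter([spike], [1.0, -decay], _lag1(driver))


_DEN96 = np.zeros(LAG + 1)
_DEN96[0] = 1.0


def _seasonal_recursion(spike: float, decay: float, driver: np.ndarray) -> np.ndarray:
    """x_t = decay * x_{t-96} + spike * driver_t (driver already 0 for t < 96)."""
    den = _DEN96.copy()
    den[LAG] = -decay
    return lfilter([spike], den, driver)


def seasonal_max_series(y: np.ndarray) -> np.ndarray:
    """Per-bin seasonal driver: max of y over the 45-minute window one day back.

    Entry t (0-based) is max(y[t-97], y[t-96], y[t-95]) for t >= 96, with
    indices before the series start dropped from the max; 0 for t < 96.
    """
    y = np.asarray(y, dtype=float)
    T = y.size
    m = np.zeros(T)
    for k in (LAG - 1, LAG, LAG + 1):
        if T > k:
            np.maximum(m[k:], y[: T - k], out=m[k:])
    m[:LAG] = 0.0
    return m


def seasonal_driver(y: BinarySensorSeries, t: int) -> int:
    """Seasonal driver at 1-based time t >= 97: max of y one day back ±1 bin."""
    if t <= LAG:
        raise ValueError(f"seasonal driver undefined for t = {t} <= {LAG}")
    lo = max(t - LAG - 1, 1)
    hi = min(t - LAG + 1, len(y))
    return int(y.values[lo - 1 : hi].max())


@dataclass
class PredictorTrace:
    """Per-time-point components of Δ_t and the implied probabilities."""

    b: np.ndarray        # (T,)
    c: np.ndarray        # (J, T)
    d: np.ndarray        # (T,)
    delta: np.ndarray    # (T,)
    p: np.ndarray        # (T,)


def compute_trace(params: ModelParams, data: HouseholdSeries) -> PredictorTrace:
    """Evaluate all model components over the household series."""
    if params.J != data.J:
        raise ValueError(f"params expect J = {params.J} sensors, data has J = {data.J}")
    y = data.y.astype(float)
    T = data.T

    if params.ar is not None:
        b = _decay_recursion(*params.ar, y)
    else:
        b = np.zeros(T)

    c = np.zeros((data.J, T))
    Z = data.Z
    for j, pair in enumerate(params.sensors):
        if pair is not None:
            c[j] = _decay_recursion(*pair, Z[:, j].astype(float))

    if params.seasonal is not None:
        d = _seasonal_recursion(*params.seasonal, seasonal_max_series(y))
    else:
        d = np.zeros(T)

    delta = params.a + b + c.sum(axis=0) + d
    return PredictorTrace(b=b, c=c, d=d, delta=delta, p=expit(delta))


def log_likelihood(
    params: ModelParams, data: HouseholdSeries, trace: PredictorTrace | None = None
) -> float:
    """Bernoulli log-likelihood  Σ_t y_t Δ_t − Σ_t log(1 + exp Δ_t)."""
    if trace is None:
        trace = compute_trace(params, data)
    delta = trace.delta
    if not np.isfinite(delta).all():
        t_bad = int(np.flatnonzero(~np.isfinite(delta))[0])
        raise FloatingPointError(f"non-finite linear predictor at t = {t_bad + 1}")
    y = data.y.astype(float)
    # log(1+exp(x)) via logaddexp: exact softplus, no overflow for large |Δ|
    return float(y @ delta - np.logaddexp(0.0, delta).sum())


def gradient(
    params: ModelParams, data: HouseholdSeries, trace: PredictorTrace | None = None
) -> np.ndarray:
    """Analytic ∂l/∂α in the flat packing order of :class:`ModelParams`.

    Chain rule: ∂l/∂Δ_t = y_t − p_t; each component's sensitivity to its own
    spike and decay obeys the same linear recursion as the component itself,
    e.g. ∂b_t/∂π_b = φ_b ∂b_{t-1}/∂π_b + y_{t-1} and
    ∂b_t/∂φ_b = φ_b ∂b_{t-1}/∂φ_b + b_{t-1}.
    """
    if trace is None:
        trace = compute_trace(params, data)
    if not np.isfinite(trace.delta).all():
        t_bad = int(np.flatnonzero(~np.isfinite(trace.delta))[0])
        raise FloatingPointError(f"non-finite linear predictor at t = {t_bad + 1}")
    y = data.y.astype(float)
    e = y - trace.p

    g = [e.sum()]
    if params.ar is not None:
        _, phi_b = params.ar
        g.append(e @ _decay_recursion(1.0, phi_b, y))          # ∂l/∂π_b
        g.append(e @ lfilter([1.0], [1.0, -phi_b], _lag1(trace.b)))  # ∂l/∂φ_b
    Z = data.Z
    for j, pair in enumerate(params.sensors):
        if pair is not None:
            _, psi_j = pair
            zj = Z[:, j].astype(float)
            g.append(e @ _decay_recursion(1.0, psi_j, zj))
            g.append(e @ lfilter([1.0], [1.0, -psi_j], _lag1(trace.c[j])))
    if params.seasonal is not None:
        _, phi_d = params.seasonal
        m = seasonal_max_series(y)
        g.append(e @ _seasonal_recursion(1.0, phi_d, m))       # ∂l/∂π_d
        g.append(e @ _seasonal_recursion(1.0, phi_d, _lag96(trace.d)))  # ∂l/∂φ_d
    return np.asarray(g)
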