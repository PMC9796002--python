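"""Lag-1 logistic-regression baseline.

The comparison model drops the exponential-decay memory and regresses y_t
on the immediately preceding bin of every sensor plus the seasonal window:

    Δ_t = a + π_b y_{t-1} + Σ_j τ_j z_{j,t-1} + π_d max(y_{t-97..t-95})

for t ≥ 97 (1-based), so there is one design row per usable time point.
It is fit by iteratively reweighted least squares and plugs into the same
one-step-ahead forecasting and quantile-band validation machinery as the
autoregressive model, making outside-counts directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bar import LAG, seasonal_max_series
from .events import HouseholdSeries
from .forecast import ForecastSeries, concat_household
from .params import ModelParams  # noqa: F401  (re-exported alongside in the CLI)

_BETA_CAP = 30.0


@dataclass
class LogisticParams:
    """Coefficients of the lag-1 logistic baseline (no decay parameters)."""

    a: float
    pi_b: float
    tau: np.ndarray     # (J,)
    pi_d: float

    def __post_init__(self) -> None:
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))

    @property
    def k(self) -> int:
        return 3 + self.tau.size

    def pack(self) -> np.ndarray:
        return np.concatenate([[self.a, self.pi_b], self.tau, [self.pi_d]])

    @classmethod
    def from_vector(cls, beta: np.ndarray) -> "LogisticParams":
        beta = np.asarray(beta, dtype=float)
        return cls(a=beta[0], pi_b=beta[1], tau=beta[2:-1], pi_d=beta[-1])

    def to_dict(self, sensor_ids: list[str] | None = None) -> dict:
        ids = sensor_ids or [str(j) for j in range(self.tau.size)]
        d = {"model": "logistic", "a": self.a, "pi_b": self.pi_b,
             "pi_d": self.pi_d, "sensor_ids": list(ids)}
        for sid, t in zip(ids, self.tau):
            d[f"tau_{sid}"] = float(t)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticParams":
        tau = np.array([d[f"tau_{sid}"] for sid in d["sensor_ids"]], dtype=float)
        return cls(a=d["a"], pi_b=d["pi_b"], tau=tau, pi_d=d["pi_d"])


def build_design(data: HouseholdSeries) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response for t ≥ 97: [1, y_{t-1}, z_{j,t-1}, seasonal max].

    Returns (X, y) with one row per usable t, so X has T − 96 rows.
    """
    T = data.T
    if T < LAG + 2:
        raise ValueError(f"need at least {LAG + 2} bins, got {T}")
    y = data.y.astype(float)
    m = seasonal_max_series(y)
    t0 = np.arange(LAG, T)  # 0-based usable times
    X = np.column_stack([
        np.ones(t0.size),
        y[t0 - 1],
        data.Z[t0 - 1].astype(float),
        m[t0],
    ])
    return X, y[t0]


def fit_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                 max_iter: int = 100) -> LogisticParams:
    """Logistic-regression MLE by iteratively reweighted least squares."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("response is constant; logistic MLE does not exist")
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    if np.max(np.abs(beta)) > _BETA_CAP:
        warnings.warn(
            "logistic fit drifting to the boundary (possible perfect separation); "
            f"coefficients capped at |beta| <= {_BETA_CAP}",
            stacklevel=2,
        )
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
    return LogisticParams.from_vector(beta)


def fit_baseline(data: HouseholdSeries) -> LogisticParams:
    """Fit the lag-1 logistic baseline on a household series."""
    return fit_logistic(*build_design(data))


def forecast_logistic(params: LogisticParams, history: HouseholdSeries) -> float:
    """P(Y_{T+1} = 1 | history through T) under the logistic baseline."""
    y = history.y.astype(float)
    T = y.size
    if T < LAG:
        seas = 0.0
    else:
        lo = max(T - LAG - 1, 0)
        seas = float(y[lo : T - LAG + 2].max())
    row = np.concatenate([[1.0, y[-1]], history.Z[-1].astype(float), [seas]])
    return float(expit(row @ params.pack()))


def forecast_logistic_series(
    params: LogisticParams, train: HouseholdSeries, test: HouseholdSeries
) -> ForecastSeries:
    """One-step-ahead baseline probabilities over the test grid."""
    joined = concat_household(train, test)
    y = joined.y.astype(float)
    m = seasonal_max_series(y)
    t0 = np.arange(train.T, joined.T)
    X = np.column_stack([
        np.ones(t0.size),
        y[t0 - 1],
        joined.Z[t0 - 1].astype(float),
        m[t0],
    ])
    start = test.target.grid_start
    start_bin = (start.hour * 60 + start.minute) // 15
    return ForecastSeries(p_hat=expit(X @ params.pack()), start_bin=int(start_bin))
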