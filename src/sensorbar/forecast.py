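"""One-step-ahead forecasting and Poisson-binomial quantile-interval validation.

Model validation works on a held-out month: with parameters fitted on the
training month, the one-step-ahead probability p̂_{t+1} = logistic(Δ̂_{t+1})
is computed for every test bin from the full realised history (training
data plus test data observed so far).  The first forecast day is discarded
as burn-in — the seasonal component needs a full day of held-out history.

The remaining probabilities are stacked by time-of-day bin w ∈ {1..96}.
The per-bin count of events over D−1 days is then a sum of independent but
non-identical Bernoulli trials — a Poisson binomial — whose exact 2.5% and
97.5% quantiles give an integer prediction band.  A bin whose observed
count escapes its closed interval [lower_w, upper_w] counts as "outside";
for a well-specified model roughly 5% of the 96 bins may fall outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np

from .bar import LAG, compute_trace
from .events import BIN_MINUTES, BinarySensorSeries, HouseholdSeries
from .params import ModelParams

BURN_IN = LAG  # one day of forecasts discarded


def concat_household(train: HouseholdSeries, test: HouseholdSeries) -> HouseholdSeries:
    """Concatenate aligned train and test household series in time."""
    if train.covariate_ids != test.covariate_ids:
        raise ValueError("train and test must share the same covariate sensors")
    if train.target.sensor_id != test.target.sensor_id:
        raise ValueError("train and test must share the same target sensor")
    expected_start = train.target.bin_times()[-1].to_pydatetime() + timedelta(
        minutes=BIN_MINUTES
    )
    if test.target.grid_start != expected_start:
        raise ValueError(
            f"test series starts at {test.target.grid_start}, expected {expected_start}"
        )
    joined_target = BinarySensorSeries(
        train.target.sensor_id,
        np.concatenate([train.y, test.y]),
        train.target.grid_start,
    )
    joined_covs = [
        BinarySensorSeries(a.sensor_id, np.concatenate([a.values, b.values]), a.grid_start)
        for a, b in zip(train.covariates, test.covariates)
    ]
    return HouseholdSeries(joined_target, joined_covs)


@dataclass
class ForecastSeries:
    """One-step-ahead probabilities aligned to the held-out grid."""

    p_hat: np.ndarray
    burn_in: int = BURN_IN
    start_bin: int = 0   # time-of-day bin (0-based) of the first forecast

    def retained(self) -> np.ndarray:
        """Probabilities after the burn-in day."""
        return self.p_hat[self.burn_in:]


def one_step_forecast(params: ModelParams, history: HouseholdSeries) -> float:
    """P(Y_{T+1} = 1 | history through T) under the fitted parameters.

    Computed by extending the series one bin (the appended target value is
    irrelevant to its own predictor) and reading p at the new end, so it is
    identical to ``compute_trace`` run over the extended series.
    """
    ext_target = BinarySensorSeries(
        history.target.sensor_id,
        np.concatenate([history.y, [0]]),
        history.target.grid_start,
    )
    ext_covs = [
        BinarySensorSeries(s.sensor_id, np.concatenate([s.values, [0]]), s.grid_start)
        for s in history.covariates
    ]
    trace = compute_trace(params, HouseholdSeries(ext_target, ext_covs))
    return float(trace.p[-1])


def forecast_series(
    params: ModelParams, train: HouseholdSeries, test: HouseholdSeries
) -> ForecastSeries:
    """One-step-ahead probabilities for every test bin, given the full history.

    Because each p̂_{t} depends only on data strictly before t, running the
    component recursions once over the concatenated train+test series yields
    exactly the sequence of online one-step-ahead forecasts.
    """
    joined = concat_household(train, test)
    trace = compute_trace(params, joined)
    start = test.target.grid_start
    start_bin = (start.hour * 60 + start.minute) // BIN_MINUTES
    return ForecastSeries(p_hat=trace.p[train.T:], start_bin=int(start_bin))


def stack_by_bin(forecast: ForecastSeries) -> list[np.ndarray]:
    """Group post-burn-in probabilities by time-of-day bin w ∈ {0..95}.

    A 28-day forecast month yields 27 probabilities per bin.
    """
    if forecast.p_hat.size < 2 * LAG:
        raise ValueError("forecast horizon must cover at least 2 days")
    retained = forecast.retained()
    bins = (forecast.start_bin + forecast.burn_in + np.arange(retained.size)) % LAG
    return [retained[bins == w] for w in range(LAG)]


def poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact pmf over {0..n} of a sum of independent Bernoulli(p_i) trials.

    Iterative convolution, O(n²); exact for the n ≈ 27 used here.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.ones(1)
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


@dataclass
class QuantileBand:
    """Per-time-of-day-bin integer quantiles of the stacked forecast counts."""

    lower: np.ndarray            # (96,) ints
    upper: np.ndarray            # (96,) ints
    probs: list[np.ndarray]      # stacked probabilities per bin

    def __post_init__(self) -> None:
        ok = (0 <= self.lower) & (self.lower <= self.upper)
        ok &= self.upper <= np.array([len(p) for p in self.probs])
        if not ok.all():
            raise ValueError("quantile band violates 0 <= lower <= upper <= n")


def _pmf_quantile(cdf: np.ndarray, q: float) -> int:
    """min{k : CDF(k) >= q}, robust to accumulated floating error."""
    return int(np.searchsorted(cdf, q - 1e-12, side="left"))


def quantile_band(
    probs_by_bin: list[np.ndarray], q_lo: float = 0.025, q_hi: float = 0.975
) -> QuantileBand:
    """Exact [q_lo, q_hi] Poisson-binomial count quantiles for each bin."""
    lower = np.zeros(len(probs_by_bin), dtype=int)
    upper = np.zeros(len(probs_by_bin), dtype=int)
    for w, probs in enumerate(probs_by_bin):
        if len(probs) == 0:
            raise ValueError(f"bin {w + 1} has no stacked probabilities")
        cdf = np.cumsum(poisson_binomial(probs))
        lower[w] = _pmf_quantile(cdf, q_lo)
        upper[w] = _pmf_quantile(cdf, q_hi)
    return QuantileBand(lower=lower, upper=upper,
                        probs=[np.asarray(p, dtype=float) for p in probs_by_bin])


@dataclass
class ValidationReport:
    """Observed per-bin counts versus the prediction band."""

    empirical_counts: np.ndarray   # (96,) ints
    n_outside: int
    outside_bins: list[int]        # 1-based time-of-day bins outside the band


def validate(
    y_test: BinarySensorSeries, band: QuantileBand, burn_in: int = BURN_IN
) -> ValidationReport:
    """Count, per time-of-day bin, events in the held-out month (burn-in day
    excluded) and flag bins whose count escapes the closed band interval."""
    start = y_test.grid_start
    start_bin = (start.hour * 60 + start.minute) // BIN_MINUTES
    y = y_test.values[burn_in:]
    bins = (start_bin + burn_in + np.arange(y.size)) % LAG
    counts = np.bincount(bins, weights=y, minlength=LAG).astype(int)
    expected = np.array([len(p) for p in band.probs])
    if not np.array_equal(np.bincount(bins, minlength=LAG), expected):
        raise ValueError("test series grid does not match the quantile band")
    outside = np.flatnonzero((counts < band.lower) | (counts > band.upper))
    return ValidationReport(
        empirical_counts=counts,
        n_outside=int(outside.size),
        outside_bins=[int(w) + 1 for w in outside],
    )


def plot_band(band: QuantileBand, report: ValidationReport, path=None, ax=None):
    """Observed per-bin counts (line) with the 95% quantile band (shaded)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    w = np.arange(1, LAG + 1)
    ax.fill_between(w, band.lower, band.upper, alpha=0.3, label="95% quantile interval")
    ax.plot(w, report.empirical_counts, lw=1.2, label="observed events")
    ax.set_xlabel("time-of-day bin (15 min)")
    ax.set_ylabel("events over held-out days")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
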