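"""One-step-ahead forecasting and Poisson-binomial quantile-band validation."""

from datetime import datetime, timedelta
from itertools import product

import numpy as np
import pytest
from scipy import stats

from sensorbar import (
    BinarySensorSeries,
    ForecastSeries,
    ModelParams,
    compute_trace,
    forecast_series,
    one_step_forecast,
    poisson_binomial,
    quantile_band,
    stack_by_bin,
    validate,
)
from sensorbar.simulate import split_household

from conftest import GRID_START, make_household, random_instance


class TestPoissonBinomial:
    def test_two_fair_coins(self):
        assert np.allclose(poisson_binomial([0.5, 0.5]), [0.25, 0.5, 0.25])

    def test_degenerate_certain_trials(self):
        pmf = poisson_binomial([1.0, 1.0])
        assert np.allclose(pmf, [0.0, 0.0, 1.0])

    def test_matches_exhaustive_enumeration(self, rng):
        probs = rng.random(10)
        pmf = poisson_binomial(probs)
        oracle = np.zeros(11)
        for outcome in product((0, 1), repeat=10):
            w = np.prod([p if o else 1 - p for p, o in zip(probs, outcome)])
            oracle[sum(outcome)] += w
        assert np.abs(pmf - oracle).max() < 1e-12

    def test_equal_probs_reduce_to_binomial(self, rng):
        p = float(rng.random())
        pmf = poisson_binomial(np.full(15, p))
        assert np.allclose(pmf, stats.binom.pmf(np.arange(16), 15, p), atol=1e-12)

    def test_mean_variance_and_normalisation(self, rng):
        probs = rng.random(20)
        pmf = poisson_binomial(probs)
        k = np.arange(21)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf * k).sum() == pytest.approx(probs.sum(), abs=1e-10)
        var = (pmf * k**2).sum() - (pmf * k).sum() ** 2
        assert var == pytest.approx((probs * (1 - probs)).sum(), abs=1e-10)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial([0.5, 1.2])


class TestQuantileBand:
    def test_half_probs_match_binomial_quantiles(self):
        band = quantile_band([np.full(27, 0.5)] * 96)
        assert np.all(band.lower == stats.binom.ppf(0.025, 27, 0.5))
        assert np.all(band.upper == stats.binom.ppf(0.975, 27, 0.5))
        assert band.lower[0] == 8 and band.upper[0] == 19

    def test_all_zero_probs_collapse_band(self):
        band = quantile_band([np.zeros(27)] * 96)
        assert np.all(band.lower == 0) and np.all(band.upper == 0)

    def test_permutation_invariance(self, rng):
        probs = rng.random(27)
        b1 = quantile_band([probs] * 96)
        b2 = quantile_band([rng.permutation(probs)] * 96)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)


class TestStackByBin:
    @pytest.mark.parametrize("days,expected", [(28, 27), (3, 2)])
    def test_days_give_one_less_per_bin(self, days, expected):
        fc = ForecastSeries(p_hat=np.random.default_rng(0).random(days * 96))
        stacks = stack_by_bin(fc)
        assert len(stacks) == 96
        assert all(len(s) == expected for s in stacks)

    def test_partition_is_exact(self, rng):
        fc = ForecastSeries(p_hat=rng.random(5 * 96))
        stacks = stack_by_bin(fc)
        assert sum(len(s) for s in stacks) == fc.retained().size
        assert np.sort(np.concatenate(stacks)).tolist() == np.sort(fc.retained()).tolist()

    def test_short_horizon_rejected(self):
        with pytest.raises(ValueError, match="2 days"):
            stack_by_bin(ForecastSeries(p_hat=np.full(96, 0.5)))


class TestOneStepForecast:
    def test_intercept_only_closed_form(self, rng):
        params = ModelParams(a=-3.3)
        hh = make_household(rng.integers(0, 2, 200))
        assert one_step_forecast(params, hh) == pytest.approx(
            1 / (1 + np.exp(3.3)), abs=1e-6
        )

    def test_spike_raises_forecast_after_event(self):
        params = ModelParams(a=-3.0, ar=(0.8, 0.5))
        y1 = np.zeros(100, dtype=int)
        y0 = y1.copy()
        y1[-1] = 1
        assert one_step_forecast(params, make_household(y1)) > one_step_forecast(
            params, make_household(y0)
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_consistent_with_trace_over_concatenation(self, seed):
        rng = np.random.default_rng(seed)
        params, hh = random_instance(rng, T=4 * 96, J=1)
        train, test = split_household(hh, 2)
        fc = forecast_series(params, train, test)
        full = compute_trace(params, hh)
        assert np.allclose(fc.p_hat, full.p[train.T:], atol=1e-12)
        # and the online one-step forecast agrees at the split point
        assert one_step_forecast(params, train) == pytest.approx(
            float(full.p[train.T]), abs=1e-12
        )


class TestValidate:
    def _band(self, lower, upper):
        from sensorbar import QuantileBand

        return QuantileBand(
            lower=np.full(96, lower, dtype=int),
            upper=np.full(96, upper, dtype=int),
            probs=[np.full(2, 0.5)] * 96,
        )

    def test_counts_inside_give_zero_outside(self):
        y = BinarySensorSeries("y", np.zeros(3 * 96, dtype=int), GRID_START)
        report = validate(y, self._band(0, 2))
        assert report.n_outside == 0
        assert np.all(report.empirical_counts == 0)

    def test_count_on_boundary_is_inside(self):
        # counts equal upper bound exactly -> closed interval keeps them inside
        y = BinarySensorSeries("y", np.ones(3 * 96, dtype=int), GRID_START)
        assert validate(y, self._band(0, 2)).n_outside == 0
        assert validate(y, self._band(0, 1)).n_outside == 96

    def test_grid_mismatch_rejected(self):
        y = BinarySensorSeries("y", np.zeros(4 * 96, dtype=int), GRID_START)
        with pytest.raises(ValueError, match="band"):
            validate(y, self._band(0, 2))

    def test_forecast_starting_off_midnight_aligns_bins(self):
        # forecasts starting at 06:00 must still map to the right day bins
        start = GRID_START + timedelta(hours=6)
        y = np.zeros(3 * 96, dtype=int)
        fc = ForecastSeries(p_hat=np.full(3 * 96, 0.01), start_bin=24)
        stacks = stack_by_bin(fc)
        band = quantile_band(stacks)
        report = validate(BinarySensorSeries("y", y, start), band)
        assert report.n_outside == 0
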