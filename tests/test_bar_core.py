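"""Component recursions, linear predictor, likelihood, and analytic gradient."""

import numpy as np
import pytest
from scipy.special import expit

from sensorbar import (
    BinarySensorSeries,
    ModelParams,
    compute_trace,
    gradient,
    log_likelihood,
    seasonal_driver,
)

from conftest import GRID_START, make_household, random_instance


def closed_form_components(params, data):
    """Geometric-sum forms of b_t, c_{j,t}, d_t (independent of the recursions)."""
    y = data.y.astype(float)
    Z = data.Z.astype(float)
    T = data.T
    b = np.zeros(T)
    if params.ar is not None:
        pi_b, phi_b = params.ar
        for t in range(T):
            b[t] = pi_b * sum(phi_b ** (i - 1) * y[t - i] for i in range(1, t + 1))
    c = np.zeros((data.J, T))
    for j, pair in enumerate(params.sensors):
        if pair is not None:
            tau, psi = pair
            for t in range(T):
                c[j, t] = tau * sum(psi ** (i - 1) * Z[t - i, j] for i in range(1, t + 1))
    d = np.zeros(T)
    if params.seasonal is not None:
        pi_d, phi_d = params.seasonal
        for t in range(96, T):
            i = 1
            acc = 0.0
            while t - 96 * i >= 0:
                lo = max(t - 96 * i - 1, 0)
                hi = min(t - 96 * i + 2, T)
                acc += phi_d ** (i - 1) * y[lo:hi].max()
                i += 1
            d[t] = pi_d * acc
    return b, c, d


class TestSeasonalDriver:
    def setup_method(self):
        values = np.zeros(200, dtype=int)
        values[1] = 1  # 1-based bin 2
        self.y = BinarySensorSeries("y", values, GRID_START)

    def test_active_middle_lag(self):
        y = np.zeros(300, dtype=int)
        y[103] = 1  # 1-based 104 = t - 96 for t = 200
        s = BinarySensorSeries("y", y, GRID_START)
        assert seasonal_driver(s, 200) == 1

    def test_all_three_lags_zero(self):
        assert seasonal_driver(self.y, 200) == 0

    def test_boundary_clamp_at_t_97(self):
        # t = 97: window indices 0,1,2 (1-based); index 0 out of range, dropped.
        # y_1 = 0, y_2 = 1 -> max over remaining is 1.
        assert seasonal_driver(self.y, 97) == 1

    def test_contract_violation_before_day_two(self):
        with pytest.raises(ValueError):
            seasonal_driver(self.y, 96)


class TestTrace:
    def test_memoryless_spike(self):
        params = ModelParams(a=0.0, ar=(1.0, 0.0))
        hh = make_household(np.ones(50, dtype=int))
        tr = compute_trace(params, hh)
        assert tr.b[0] == 0.0
        assert np.all(tr.b[1:] == 1.0)

    def test_zero_predictor_gives_half(self):
        params = ModelParams(a=0.0, ar=(0.0, 0.0), sensors=[], seasonal=(0.0, 0.0))
        hh = make_household(np.zeros(200, dtype=int))
        assert np.allclose(compute_trace(params, hh).p, 0.5)

    def test_intercept_only_probability(self):
        # fitted bedroom-sensor intercept: p = 1/(1+e^3.009) ~ 0.0470
        params = ModelParams(a=-3.009)
        hh = make_household(np.zeros(96, dtype=int))
        assert compute_trace(params, hh).p == pytest.approx(0.04703, abs=1e-4)

    def test_recursion_matches_geometric_sum(self, rng):
        params, hh = random_instance(rng, T=300, J=1)
        tr = compute_trace(params, hh)
        b, c, d = closed_form_components(params, hh)
        assert np.allclose(tr.b, b, atol=1e-10)
        assert np.allclose(tr.c, c, atol=1e-10)
        assert np.allclose(tr.d, d, atol=1e-10)

    def test_no_overflow_for_huge_predictor(self):
        params = ModelParams(a=700.0)
        hh = make_household(np.ones(10, dtype=int))
        tr = compute_trace(params, hh)
        assert np.all(tr.p > 0) and np.all(tr.p <= 1) and np.isfinite(tr.p).all()

    def test_dimension_mismatch_rejected(self, rng):
        params = ModelParams(a=0.0, sensors=[(0.1, 0.5)])
        hh = make_household(rng.integers(0, 2, 50))
        with pytest.raises(ValueError, match="J"):
            compute_trace(params, hh)


class TestLogLikelihood:
    def test_fair_coin(self):
        params = ModelParams(a=0.0)
        hh = make_household(np.array([1, 0]))
        assert log_likelihood(params, hh) == pytest.approx(2 * np.log(0.5))

    def test_vanishes_in_rare_event_limit(self):
        params = ModelParams(a=-30.0)
        hh = make_household(np.zeros(500, dtype=int))
        assert log_likelihood(params, hh) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_with_generic_bernoulli_loglik(self, seed):
        rng = np.random.default_rng(seed)
        params, hh = random_instance(rng, T=400, J=2)
        tr = compute_trace(params, hh)
        y = hh.y
        oracle = float(np.sum(y * np.log(tr.p) + (1 - y) * np.log(1 - tr.p)))
        assert log_likelihood(params, hh) == pytest.approx(oracle, abs=1e-8)

    def test_invariant_under_covariate_permutation(self, rng):
        params, hh = random_instance(rng, T=300, J=3)
        perm = [2, 0, 1]
        params_p = ModelParams(
            params.a, params.ar, [params.sensors[j] for j in perm], params.seasonal
        )
        hh_p = make_household(hh.y, hh.Z[:, perm])
        assert log_likelihood(params, hh) == pytest.approx(
            log_likelihood(params_p, hh_p), rel=1e-12
        )


def finite_difference_gradient(params, data, h=1e-6):
    vec = params.pack()
    fd = np.zeros_like(vec)
    for i in range(vec.size):
        vp, vm = vec.copy(), vec.copy()
        vp[i] += h
        vm[i] -= h
        fd[i] = (
            log_likelihood(params.unpack(vp), data)
            - log_likelihood(params.unpack(vm), data)
        ) / (2 * h)
    return fd


class TestGradient:
    def test_intercept_score_at_zero(self, rng):
        y = rng.integers(0, 2, 300)
        params = ModelParams(a=0.0)
        hh = make_household(y)
        g = gradient(params, hh)
        assert g.shape == (1,)
        assert g[0] == pytest.approx(y.sum() - 0.5 * y.size)

    def test_score_vanishes_at_intercept_mle(self, rng):
        y = rng.integers(0, 2, 500)
        from scipy.special import logit

        params = ModelParams(a=float(logit(y.mean())))
        assert gradient(params, make_household(y))[0] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "J,ar,seasonal",
        [(0, False, False), (0, True, False), (0, True, True),
         (1, True, True), (2, False, True), (3, True, True)],
    )
    def test_matches_finite_differences_across_blocks(self, J, ar, seasonal):
        rng = np.random.default_rng(7 * J + 2 * ar + seasonal)
        params, hh = random_instance(rng, T=350, J=J, include_seasonal=seasonal)
        if not ar:
            params = ModelParams(params.a, None, params.sensors, params.seasonal)
        g = gradient(params, hh)
        fd = finite_difference_gradient(params, hh)
        assert g.shape == fd.shape == (params.k,)
        denom = max(1.0, float(np.abs(fd).max()))
        assert np.abs(g - fd).max() / denom < 1e-5
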