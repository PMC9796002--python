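"""scikit-learn style estimators wrapping the functional core.

These follow the sklearn conventions — parameters set in ``__init__``,
``fit(X, y)``, fitted attributes with a trailing underscore,
``get_params``/``set_params`` via :class:`~sklearn.base.BaseEstimator` — so
they compose with ``clone`` and model-selection utilities.  One deviation
is intrinsic to self-exciting time-series models: prediction is
one-step-ahead and conditions on the *realised* target history, so
``predict_proba`` takes ``y`` alongside ``X``.

``X`` is the (T, J) 0/1 covariate-sensor matrix (or None when J = 0) and
``y`` the (T,) 0/1 target series, both on the 15-minute grid starting at
midnight.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .baseline import build_design, fit_logistic
from .bar import compute_trace, log_likelihood, seasonal_max_series
from .events import BinarySensorSeries, HouseholdSeries
from .optimize import DEFAULT_MAX_ITER, DEFAULT_STEP_SIZES, DEFAULT_TOL, fit
from .params import ModelParams
from .selection import forward_select
from .simulate import DEFAULT_GRID_START


def _as_household(X, y) -> HouseholdSeries:
    y = np.asarray(y)
    if X is None:
        X = np.zeros((y.size, 0), dtype=np.int8)
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"X must be (T, J) aligned with y; got {X.shape} vs {y.size}")
    target = BinarySensorSeries("y", y, DEFAULT_GRID_START)
    covs = [
        BinarySensorSeries(f"z{j}", X[:, j], DEFAULT_GRID_START)
        for j in range(X.shape[1])
    ]
    return HouseholdSeries(target, covs)


class BernoulliAR(BaseEstimator):
    """Bernoulli autoregressive sensor model with exponential-decay components.

    Parameters
    ----------
    ar, seasonal : bool
        Include the self-excitation block / the daily seasonal block.
    sensors : "all" or sequence of int
        Covariate sensor columns to include as (spike, decay) blocks.
    step_sizes, tol, max_iter
        Adaptive-BFGS settings (six candidate step sizes per iteration).

    Attributes
    ----------
    params_ : ModelParams
        Fitted parameters (intercept plus per-block spike/decay pairs).
    loglik_ : float
        Maximised log-likelihood.
    n_iter_ : int
        BFGS iterations used.
    converged_ : bool
    """

    def __init__(
        self,
        ar: bool = True,
        seasonal: bool = True,
        sensors="all",
        step_sizes: tuple = DEFAULT_STEP_SIZES,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ):
        self.ar = ar
        self.seasonal = seasonal
        self.sensors = sensors
        self.step_sizes = step_sizes
        self.tol = tol
        self.max_iter = max_iter

    def _blocks(self, J: int) -> set[str]:
        blocks: set[str] = set()
        if self.ar:
            blocks.add("ar")
        if self.seasonal:
            blocks.add("seasonal")
        cols = range(J) if self.sensors == "all" else self.sensors
        blocks.update(f"z{j}" for j in cols)
        return blocks

    def fit(self, X, y):
        data = _as_household(X, y)
        res = fit(
            data,
            blocks=self._blocks(data.J),
            step_sizes=tuple(self.step_sizes),
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.params_ = res.params_hat
        self.loglik_ = res.loglik
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.trajectory_ = list(res.trajectory)
        return self

    def predict_proba(self, X, y):
        """One-step-ahead P(y_t | history before t) for every t, shape (T, 2)."""
        check_is_fitted(self, "params_")
        p = compute_trace(self.params_, _as_household(X, y)).p
        return np.column_stack([1.0 - p, p])

    def predict(self, X, y):
        return (self.predict_proba(X, y)[:, 1] >= 0.5).astype(int)

    def score(self, X, y):
        """Mean per-bin log-likelihood of y under the one-step-ahead forecasts."""
        check_is_fitted(self, "params_")
        data = _as_household(X, y)
        return log_likelihood(self.params_, data) / data.T


class ForwardBAR(BaseEstimator):
    """Forward BIC selection over component blocks, then a final BernoulliAR fit.

    Attributes
    ----------
    chosen_blocks_ : list of str
        Blocks in inclusion order ("ar", "seasonal", "z<j>").
    bic_path_ : list of float
        Intercept-only BIC followed by the BIC after each accepted block.
    params_, loglik_ : fitted selected model.
    """

    def __init__(
        self,
        step_sizes: tuple = DEFAULT_STEP_SIZES,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ):
        self.step_sizes = step_sizes
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        data = _as_household(X, y)
        sel = forward_select(
            data, step_sizes=tuple(self.step_sizes), tol=self.tol,
            max_iter=self.max_iter,
        )
        self.chosen_blocks_ = sel.chosen_blocks
        self.bic_path_ = sel.bic_path
        self.params_ = sel.final_fit.params_hat
        self.loglik_ = sel.final_fit.loglik
        return self

    def predict_proba(self, X, y):
        check_is_fitted(self, "params_")
        p = compute_trace(self.params_, _as_household(X, y)).p
        return np.column_stack([1.0 - p, p])


class LagLogistic(BaseEstimator):
    """Lag-1 logistic baseline: y_t on y_{t-1}, z_{j,t-1} and the seasonal window.

    Attributes
    ----------
    params_ : LogisticParams
    coef_ : ndarray, coefficients in design order (intercept first).
    """

    def fit(self, X, y):
        data = _as_household(X, y)
        self.params_ = fit_logistic(*build_design(data))
        self.coef_ = self.params_.pack()
        return self

    def predict_proba(self, X, y):
        check_is_fitted(self, "params_")
        data = _as_household(X, y)
        yf = data.y.astype(float)
        m = seasonal_max_series(yf)
        ylag = np.concatenate([[0.0], yf[:-1]])
        Zlag = np.vstack([np.zeros((1, data.J)), data.Z[:-1].astype(float)])
        eta = np.column_stack([np.ones(data.T), ylag, Zlag, m]) @ self.coef_
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, y):
        return (self.predict_proba(X, y)[:, 1] >= 0.5).astype(int)
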