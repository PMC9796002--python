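"""Maximum-likelihood fitting by BFGS with a six-candidate adaptive step size.

The log-likelihood surface of the self-exciting model is prone to exploding
gradients (the decay parameters sit inside geometric sums), so instead of a
line search the quasi-Newton direction is normalised and probed at six fixed
step sizes {5e-5, 0.01, 0.5, 1, 2.5, 4} each iteration; the step giving the
largest log-likelihood is taken (ties go to the smallest step).  Iteration
stops when the log-likelihood improves by less than ``tol``, when no
candidate step improves it, or after ``max_iter`` iterations.

Decay parameters are constrained to (-1, 1) — outside, the component sums
diverge — via a smooth tanh bijection, so the optimiser itself is
unconstrained.  Spikes and the intercept are unconstrained throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from .bar import compute_trace, gradient, log_likelihood
from .events import HouseholdSeries
from .params import ModelParams

DEFAULT_STEP_SIZES = (5e-5, 0.01, 0.5, 1.0, 2.5, 4.0)
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 500
_GRAD_BLOWUP = 1e8
_INIT_DECAY = 0.5


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params_hat: ModelParams
    loglik: float
    n_iter: int
    converged: bool
    trajectory: list[float] = field(default_factory=list)


def template_params(
    J: int,
    blocks: set[str] | frozenset[str],
    sensor_ids: list[str] | None = None,
    a: float = 0.0,
) -> ModelParams:
    """Build a ModelParams inclusion template from block labels.

    ``blocks`` may contain ``"ar"``, ``"seasonal"``, and covariate sensor
    labels (or stringified indices when no labels are given).  Spikes start
    at 0 and decays at 0.5 — neutral dynamics around the intercept.
    """
    ids = sensor_ids or [str(j) for j in range(J)]
    if len(ids) != J:
        raise ValueError("sensor_ids length must equal J")
    unknown = set(blocks) - {"ar", "seasonal"} - set(ids)
    if unknown:
        raise ValueError(f"unknown blocks: {sorted(unknown)}")
    pair = (0.0, _INIT_DECAY)
    return ModelParams(
        a=a,
        ar=pair if "ar" in blocks else None,
        sensors=[pair if sid in blocks else None for sid in ids],
        seasonal=pair if "seasonal" in blocks else None,
    )


def _decay_mask(template: ModelParams) -> np.ndarray:
    """Boolean mask over the packed vector marking decay coordinates."""
    mask = [False]
    for pair in [template.ar, *template.sensors, template.seasonal]:
        if pair is not None:
            mask += [False, True]
    return np.asarray(mask)


def _to_unconstrained(vec: np.ndarray, mask: np.ndarray) -> np.ndarray:
    theta = vec.astype(float).copy()
    theta[mask] = np.arctanh(vec[mask])
    return theta


def _from_unconstrained(theta: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vec = theta.astype(float).copy()
    vec[mask] = np.tanh(theta[mask])
    return vec


def _default_init(data: HouseholdSeries, template: ModelParams) -> ModelParams:
    ybar = float(data.y.mean())
    a0 = float(np.clip(logit(ybar), -8.0, 8.0)) if 0.0 < ybar < 1.0 else (
        -8.0 if ybar == 0.0 else 8.0
    )
    vec = np.where(_decay_mask(template), _INIT_DECAY, 0.0)
    vec[0] = a0
    return template.unpack(vec)


def adaptive_bfgs(
    f_and_g,
    theta0: np.ndarray,
    f_only=None,
    step_sizes: tuple[float, ...] = DEFAULT_STEP_SIZES,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """Maximise f by BFGS, probing the unit quasi-Newton direction at each of
    the candidate step sizes and taking the best (smallest step wins ties).

    ``f_and_g(theta) -> (f, grad)``; ``f_only`` defaults to the first element
    of ``f_and_g``.  Returns (theta, f, n_iter, converged, trajectory).
    """
    if f_only is None:
        f_only = lambda th: f_and_g(th)[0]  # noqa: E731
    theta = np.asarray(theta0, dtype=float).copy()
    val, g = f_and_g(theta)
    if not np.isfinite(val):
        raise ValueError("objective is not finite at the initial point")
    steps = np.sort(np.asarray(step_sizes, dtype=float))
    trajectory = [val]
    H = np.eye(theta.size)
    converged = False
    n_iter = 0

    for _ in range(max_iter):
        if np.linalg.norm(g) > _GRAD_BLOWUP:
            raise RuntimeError(
                f"gradient norm {np.linalg.norm(g):.3g} exceeds {_GRAD_BLOWUP:.0e}: "
                "exploding gradient; try different starting values"
            )
        dirn = H @ g
        nrm = np.linalg.norm(dirn)
        if not np.isfinite(nrm) or nrm == 0.0:
            converged = True
            break
        u = dirn / nrm
        cand = np.array([f_only(theta + s * u) for s in steps])
        best = int(np.argmax(cand))  # first max -> smallest tied step
        n_iter += 1
        if not np.isfinite(cand[best]) or cand[best] <= val:
            converged = True  # no candidate step improves the objective
            break
        theta_new = theta + steps[best] * u
        val_new, g_new = f_and_g(theta_new)
        trajectory.append(val_new)

        # BFGS inverse-Hessian update in the minimisation convention (-f);
        # curvature violations reset the approximation to the identity.
        s_vec = theta_new - theta
        y_vec = g - g_new
        sy = float(s_vec @ y_vec)
        if sy > 1e-12:
            rho = 1.0 / sy
            I = np.eye(theta.size)
            V = I - rho * np.outer(s_vec, y_vec)
            H = V @ H @ V.T + rho * np.outer(s_vec, s_vec)
        else:
            H = np.eye(theta.size)

        done = abs(val_new - val) < tol
        theta, val, g = theta_new, val_new, g_new
        if done:
            converged = True
            break
    else:
        warnings.warn(
            f"maximum number of iterations ({max_iter}) reached without convergence",
            stacklevel=3,
        )
    return theta, val, n_iter, converged, trajectory


def fit(
    data: HouseholdSeries,
    blocks: set[str] | frozenset[str] | None = None,
    init: ModelParams | None = None,
    step_sizes: tuple[float, ...] = DEFAULT_STEP_SIZES,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Maximise the log-likelihood over the included blocks.

    Parameters
    ----------
    data
        Aligned household series (target y plus covariates z).
    blocks
        Component blocks to include besides the always-present intercept:
        ``"ar"``, ``"seasonal"``, and/or covariate sensor labels.  Ignored
        when ``init`` is given (its inclusion mask is used instead).
        Defaults to all blocks.
    init
        Optional starting parameters; defaults to the intercept-only MLE
        a = logit(mean y) with zero spikes and 0.5 decays.
    """
    if init is None:
        if blocks is None:
            blocks = {"ar", "seasonal", *data.covariate_ids}
        template = template_params(data.J, set(blocks), data.covariate_ids or None)
        init = _default_init(data, template)
    mask = _decay_mask(init)

    theta = _to_unconstrained(init.pack(), mask)

    def unpack(th: np.ndarray) -> ModelParams:
        return init.unpack(_from_unconstrained(th, mask))

    def f_and_g(th: np.ndarray):
        p = unpack(th)
        trace = compute_trace(p, data)
        ll = log_likelihood(p, data, trace)
        g = gradient(p, data, trace)
        # chain rule through decay = tanh(theta): d decay/d theta = 1 - decay^2
        vec = _from_unconstrained(th, mask)
        g[mask] *= 1.0 - vec[mask] ** 2
        return ll, g

    def f_only(th: np.ndarray) -> float:
        p = unpack(th)
        try:
            return log_likelihood(p, data)
        except FloatingPointError:
            return -np.inf

    theta, ll, n_iter, converged, trajectory = adaptive_bfgs(
        f_and_g, theta, f_only=f_only,
        step_sizes=step_sizes, tol=tol, max_iter=max_iter,
    )

    return FitResult(
        params_hat=unpack(theta),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        trajectory=trajectory,
    )
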