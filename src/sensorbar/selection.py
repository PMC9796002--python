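"""Greedy forward model selection over component blocks using BIC.

Candidates are two-parameter (spike, decay) blocks: the autoregressive
term, the daily seasonal term, and each covariate sensor.  Starting from
the intercept-only model, each round fits every one-block extension and
adds the block with the lowest BIC, stopping as soon as no extension
improves on the current BIC.  BIC is preferred over AIC for parsimony:
the model is refit for every sensor in every household, so conservative
selection keeps the overall computation down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import HouseholdSeries
from .optimize import DEFAULT_MAX_ITER, DEFAULT_STEP_SIZES, DEFAULT_TOL, FitResult, fit


def bic(loglik: float, k: int, T: int) -> float:
    """Bayesian information criterion  k·ln(T) − 2·loglik  (lower is better)."""
    if k < 1 or T < 2:
        raise ValueError("need k >= 1 and T >= 2")
    return k * float(np.log(T)) - 2.0 * loglik


@dataclass
class SelectionResult:
    """Outcome of forward selection: chosen blocks in inclusion order."""

    chosen_blocks: list[str]
    bic_path: list[float]       # intercept-only BIC, then BIC after each added block
    final_fit: FitResult
    candidate_bics: list[dict[str, float]] = field(default_factory=list)


def forward_select(
    data: HouseholdSeries,
    step_sizes: tuple[float, ...] = DEFAULT_STEP_SIZES,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SelectionResult:
    """Greedy forward BIC selection over {AR, seasonal, each covariate sensor}."""
    T = data.T
    candidates = ["ar", "seasonal", *data.covariate_ids]

    current: FitResult = fit(
        data, blocks=set(), step_sizes=step_sizes, tol=tol, max_iter=max_iter
    )
    chosen: list[str] = []
    current_bic = bic(current.loglik, current.params_hat.k, T)
    bic_path = [current_bic]
    rounds: list[dict[str, float]] = []

    while True:
        remaining = [c for c in candidates if c not in chosen]
        if not remaining:
            break
        round_bics: dict[str, float] = {}
        round_fits: dict[str, FitResult] = {}
        for cand in remaining:
            try:
                res = fit(
                    data,
                    blocks={*chosen, cand},
                    step_sizes=step_sizes,
                    tol=tol,
                    max_iter=max_iter,
                )
            except (ValueError, RuntimeError, FloatingPointError) as exc:
                warnings.warn(f"candidate block {cand!r} failed to fit: {exc}",
                              stacklevel=2)
                continue
            round_bics[cand] = bic(res.loglik, res.params_hat.k, T)
            round_fits[cand] = res
        rounds.append(round_bics)
        if not round_bics:
            break
        best = min(round_bics, key=lambda c: round_bics[c])
        if round_bics[best] >= current_bic:
            break
        chosen.append(best)
        current = round_fits[best]
        current_bic = round_bics[best]
        bic_path.append(current_bic)

    return SelectionResult(
        chosen_blocks=chosen,
        bic_path=bic_path,
        final_fit=current,
        candidate_bics=rounds,
    )
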