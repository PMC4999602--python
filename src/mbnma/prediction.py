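"""Absolute response predictions over a dose grid.

Relative-effect posteriors say nothing about absolute response; combining
them with the separately fitted placebo model produces the absolute response
probability at any (agent, dose) point: draw-wise inverse-logit of
(placebo anchor + relative effect). Two anchoring modes:

* ``typical_trial`` — the anchor is the mean m of the placebo random-effects
  distribution (a typical trial's placebo log-odds);
* ``new_trial``     — the anchor additionally draws a study effect from
  N(m, s^2), widening the intervals into prediction intervals for a future
  trial.

The two fits share no parameters, so their draws are combined independently;
draw counts are matched by seeded resampling of the shorter set. Doses beyond
the maximum trialed standardized dose of an agent are allowed but flagged as
extrapolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import FitResult


def predict(
    fit: FitResult,
    placebo_fit: FitResult,
    grid,
    mode: str = "typical_trial",
    seed: int = 0,
    interval: float = 0.95,
) -> pd.DataFrame:
    """Response-probability median and interval per (agent, dose) grid point.

    ``grid`` maps agent -> iterable of standardized doses (or is an iterable
    of (agent, dose) pairs). Returns one row per grid point with columns
    agent, dose_std, median, lower, upper, mode, extrapolated.
    """
    if mode not in ("typical_trial", "new_trial"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    pairs = _as_pairs(grid)
    rng = np.random.default_rng(seed)

    anchor = placebo_fit.get("m").copy()
    if mode == "new_trial":
        anchor = anchor + placebo_fit.get("s") * rng.standard_normal(anchor.shape)

    theta = fit.pooled
    k = min(theta.shape[0], anchor.shape[0])
    if theta.shape[0] > k:
        theta = theta[rng.choice(theta.shape[0], size=k, replace=False)]
    if anchor.shape[0] > k:
        anchor = anchor[rng.choice(anchor.shape[0], size=k, replace=False)]

    max_dose = fit.model.max_trialed_dose
    a = (1.0 - interval) / 2.0
    rows = []
    for agent, dose in pairs:
        eff = np.zeros(k) if _is_placebo_point(agent, dose) else np.asarray(
            fit.model.dose_effect_draws(theta, agent, float(dose))
        )
        p = expit(anchor + eff)
        lo, med, hi = np.quantile(p, [a, 0.5, 1.0 - a])
        rows.append(
            {
                "agent": agent,
                "dose_std": float(dose),
                "median": med,
                "lower": lo,
                "upper": hi,
                "mode": mode,
                "extrapolated": float(dose) > max_dose.get(agent, np.inf),
            }
        )
    return pd.DataFrame(rows)


def _is_placebo_point(agent, dose):
    from .trial_data import is_placebo

    return is_placebo(agent)


def _as_pairs(grid):
    if isinstance(grid, dict):
        return [(agent, d) for agent, doses in grid.items() for d in np.atleast_1d(doses)]
    return [(agent, dose) for agent, dose in grid]


def dose_grid(agents, doses) -> dict:
    """Convenience: the same dose list for every agent."""
    return {a: list(doses) for a in agents}
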