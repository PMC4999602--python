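"""Dose-response functions f(x, t) on the linear-predictor (log-odds) scale.

A dose-response model maps a standardized dose x and an agent's parameter
block to a log-odds effect relative to placebo. Placebo is the fixed zero of
the scale: f is never evaluated for placebo, the model layer substitutes 0.
Relative effects between any two arms are differences of f, so consistency of
all contrasts holds identically (the effect of c vs a equals the effect of
b vs a plus c vs b, for any treatments a, b, c).

Shipped forms:

* ``emax``             — Emax * x / (ED50 + x), ED50 parameterized on the log
                         scale because a dose is necessarily positive; Emax is
                         sign-unconstrained (effects may be beneficial or
                         harmful).
* ``linear``           — d_t * x (no intercept).
* ``linear_intercept`` — b_t + d_t * x; the intercept exists only for active
                         agents, so f jumps from 0 (placebo) to b_t as the
                         dose falls to zero.

Any user object satisfying :class:`DoseResponseModel` can be registered by
name and used by the model layer unchanged.
"""

from __future__ import annotations

import numpy as np

from .trial_data import is_placebo


class DoseResponseModel:
    """Contract for a pluggable dose-response form.

    Attributes
    ----------
    name : str
        Registry key.
    param_names : tuple of str
        Per-agent parameter block, in sampling-scale units (e.g. ``log_ed50``).
    class_effect_params : tuple of str
        Parameters that may be made exchangeable across agents.
    """

    name: str = "abstract"
    param_names: tuple[str, ...] = ()
    class_effect_params: tuple[str, ...] = ()

    def evaluate(self, x, params):
        """f(x, t) for standardized dose(s) ``x`` and parameter array ``params``.

        ``params`` has the block's values along the last axis; broadcasting
        against ``x`` is expected. Must return 0 at x = 0 only if the form has
        no intercept; must be finite for all x >= 0 and finite parameters.
        """
        raise NotImplementedError


def emax_f(x, emax, log_ed50):
    """Emax curve on the log-odds scale: emax * x / (exp(log_ed50) + x).

    At x = ED50 = exp(log_ed50) exactly half the maximal effect is reached;
    as x grows the effect saturates at ``emax``.
    """
    x = np.asarray(x, dtype=float)
    return emax * x / (np.exp(log_ed50) + x)


def linear_f(x, slope, intercept=None):
    """Linear log-odds dose-response, optionally with an intercept."""
    x = np.asarray(x, dtype=float)
    out = slope * x
    if intercept is not None:
        out = out + intercept
    return out


class EmaxModel(DoseResponseModel):
    name = "emax"
    param_names = ("emax", "log_ed50")
    class_effect_params = ("emax", "log_ed50")

    def evaluate(self, x, params):
        params = np.asarray(params, dtype=float)
        return emax_f(x, params[..., 0], params[..., 1])


class LinearModel(DoseResponseModel):
    def __init__(self, with_intercept: bool):
        self.with_intercept = bool(with_intercept)
        self.name = "linear_intercept" if with_intercept else "linear"
        self.param_names = ("intercept", "slope") if with_intercept else ("slope",)

    def evaluate(self, x, params):
        params = np.asarray(params, dtype=float)
        if self.with_intercept:
            return linear_f(x, params[..., 1], params[..., 0])
        return linear_f(x, params[..., 0])


_REGISTRY: dict[str, DoseResponseModel] = {}


def register(model: DoseResponseModel) -> DoseResponseModel:
    """Register a dose-response model under ``model.name`` (overwrites)."""
    if not model.param_names:
        raise ValueError("dose-response model must declare param_names")
    _REGISTRY[model.name] = model
    return model


def get_dose_response(name) -> DoseResponseModel:
    if isinstance(name, DoseResponseModel):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown dose-response model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register(EmaxModel())
register(LinearModel(with_intercept=False))
register(LinearModel(with_intercept=True))


def relative_effect(model, arm_k, arm_1, params: dict) -> float:
    """Log-odds ratio of arm_k vs arm_1: f(x_k, t_k) - f(x_1, t_1).

    ``arm_k``/``arm_1`` are (agent, dose_std) pairs; ``params`` maps agent ->
    parameter block (sequence ordered as ``model.param_names``). Placebo
    contributes 0 and needs no entry.
    """
    model = get_dose_response(model)

    def f(agent, x):
        if is_placebo(agent):
            return 0.0
        if agent not in params:
            raise KeyError(f"unknown agent {agent!r}")
        return float(model.evaluate(float(x), np.asarray(params[agent], dtype=float)))

    return f(*arm_k) - f(*arm_1)
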