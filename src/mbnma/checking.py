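"""Model criticism: residual deviance, plug-in DIC, inconsistency screen, VPC.

Residual deviance compares each arm's fitted binomial probability with the
saturated model; an adequate model contributes about 1 per data point, so the
posterior mean total residual deviance (Dbar) should be close to the number
of arms. The effective number of parameters is computed by the plug-in
method, pD = Dbar - D(plug-in), with the plug-in fitted value taken as the
posterior mean of each arm's probability — the default pD of general MCMC
software can be unreliable for nonlinear models. DIC = Dbar + pD; DIC
differences of three or more between models on the same data are considered
meaningful.

Evidence inconsistency is screened by refitting the data with the unrelated
mean effects (UME) model and comparing per-point deviance contributions and
the between-study SD posteriors: a clearly smaller UME heterogeneity suggests
the consistency assumptions are absorbing real disagreement between direct
and indirect evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult

# fitted probabilities are clipped by floating-point safety only; anything
# statistically meaningful must come from the model, not the clip
_P_EPS = 1e-300


@dataclass
class DevianceReport:
    """Residual-deviance block of one fit.

    Dbar: posterior mean total residual deviance; D_plugin: deviance at the
    plug-in fitted values; pD = Dbar - D_plugin; DIC = Dbar + pD. ``per_point``
    carries one row per arm with its mean deviance contribution.
    """

    Dbar: float
    D_plugin: float
    pD: float
    DIC: float
    per_point: pd.DataFrame
    n_datapoints: int

    def __post_init__(self):
        if self.pD < 0:
            warnings.warn(
                f"negative effective number of parameters (pD = {self.pD:.3f}); "
                "the plug-in point may be in a region of poor fit",
                stacklevel=2,
            )

    @property
    def dbar_per_point(self) -> float:
        return self.Dbar / self.n_datapoints


def binomial_residual_deviance(r, n, p_hat):
    """Per-arm residual deviance vs the saturated binomial model.

    2 [ r log(r / (n p)) + (n - r) log((n - r) / (n - n p)) ], with the
    0 log 0 := 0 convention at boundary counts. Fails on fitted probabilities
    of exactly 0 or 1, which signal a degenerate fit.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("fitted probabilities must lie strictly inside (0, 1)")
    if np.any((r < 0) | (r > n)):
        raise ValueError("need 0 <= r <= n")
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / (n * p)), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - n * p)), 0.0)
    return np.maximum(2.0 * (t1 + t2), 0.0)


def normal_residual_deviance(y, se, mu_hat):
    """Per-point residual deviance for a known-variance normal likelihood."""
    y = np.asarray(y, dtype=float)
    return ((y - np.asarray(mu_hat, dtype=float)) / np.asarray(se, dtype=float)) ** 2


def dic_plugin(fitted_draws, deviance_fn, plugin_fitted=None, meta=None) -> DevianceReport:
    """Plug-in DIC from per-draw fitted values and a deviance function.

    ``fitted_draws`` is (n_draws, n_points); ``deviance_fn(fitted)`` maps
    fitted values (any leading shape) to per-point deviance contributions.
    ``plugin_fitted`` defaults to the mean of ``fitted_draws`` over draws.
    A single draw has no posterior spread, so pD = 0 and DIC = Dbar exactly.
    """
    fitted_draws = np.atleast_2d(np.asarray(fitted_draws, dtype=float))
    per_draw = deviance_fn(fitted_draws)
    per_point = per_draw.mean(axis=0)
    dbar = float(per_point.sum())
    if plugin_fitted is None:
        plugin_fitted = fitted_draws.mean(axis=0)
    d_plug = float(np.sum(deviance_fn(plugin_fitted)))
    pd_eff = dbar - d_plug
    table = pd.DataFrame(meta) if meta is not None else pd.DataFrame()
    table["deviance"] = per_point
    return DevianceReport(
        Dbar=dbar,
        D_plugin=d_plug,
        pD=pd_eff,
        DIC=dbar + pd_eff,
        per_point=table,
        n_datapoints=per_point.size,
    )


def deviance_report(fit: FitResult, plugin_scale: str = "probability") -> DevianceReport:
    """Plug-in DIC for a fitted binomial-logit model.

    The plug-in point is the posterior mean of each arm's fitted probability
    (``plugin_scale="probability"``, the default — it pairs directly with the
    binomial deviance); ``"linear"`` instead averages on the linear-predictor
    scale before back-transforming. The report is also attached to
    ``fit.deviance``.
    """
    model = fit.model
    probs = np.clip(model.fitted_probs(fit.pooled), _P_EPS, 1.0 - 1e-16)
    r, n = _observed(model)

    def dev(p):
        return binomial_residual_deviance(r, n, np.clip(p, _P_EPS, 1.0 - 1e-16))

    if plugin_scale == "probability":
        plug = probs.mean(axis=0)
    elif plugin_scale == "linear":
        from scipy.special import expit, logit

        plug = expit(logit(probs).mean(axis=0))
    else:
        raise ValueError(f"unknown plugin_scale {plugin_scale!r}")
    report = dic_plugin(probs, dev, plugin_fitted=plug, meta=model.arm_meta.copy())
    fit.deviance = report
    return report


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

DIC_MEANINGFUL = 3.0


def _sigma_name(model):
    if getattr(model, "sigma_index", None) is not None:
        return "sigma"
    if "s" in getattr(model, "param_names", ()):
        return "s"
    return None


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Fit-statistics table across models of the same dataset, sorted by DIC.

    Columns: model, DIC, pD, residual deviance (Dbar), between-study SD
    median and 95% CrI. ``delta_DIC`` is the distance to the best model and
    ``not_meaningfully_different`` flags models within 3 DIC units of it.
    """
    if not fits:
        raise ValueError("no fits to compare")
    sig0 = fits[0].model.data_signature
    for f in fits[1:]:
        if f.model.data_signature != sig0:
            raise ValueError(
                f"mixed datasets: {f.label!r} was fitted to different data"
            )
    rows = []
    for f in fits:
        rep = f.deviance or deviance_report(f)
        name = _sigma_name(f.model)
        if name and name in f.param_names:
            sd = f.get(name)
            lo, med, hi = np.quantile(sd, [0.025, 0.5, 0.975])
        else:
            lo = med = hi = np.nan
        rows.append(
            {
                "model": f.label,
                "DIC": rep.DIC,
                "pD": rep.pD,
                "residual_deviance": rep.Dbar,
                "between_study_sd": med,
                "between_study_sd_lower": lo,
                "between_study_sd_upper": hi,
            }
        )
    out = pd.DataFrame(rows).sort_values("DIC", ignore_index=True)
    out["delta_DIC"] = out["DIC"] - out["DIC"].iloc[0]
    out["not_meaningfully_different"] = out["delta_DIC"] < DIC_MEANINGFUL
    return out


# ---------------------------------------------------------------------------
# inconsistency screen
# ---------------------------------------------------------------------------

# margin for the heterogeneity comparison: a raw median comparison is a coin
# flip when the data are consistent, so the flag requires the UME posterior
# median to undercut the consistency-model one by 25%
SIGMA_RATIO_FLAG = 0.75


@dataclass
class InconsistencyScreen:
    per_point: pd.DataFrame
    sigma_consistency: tuple[float, float, float]  # median, lower, upper
    sigma_ume: tuple[float, float, float]
    flag: bool

    def __repr__(self):
        s_c, s_u = self.sigma_consistency[0], self.sigma_ume[0]
        verdict = "POSSIBLE INCONSISTENCY" if self.flag else "no inconsistency signal"
        return (
            f"<InconsistencyScreen sigma(consistency)={s_c:.3f} "
            f"sigma(UME)={s_u:.3f}: {verdict}>"
        )


def inconsistency_screen(
    consistency_fit: FitResult, ume_fit: FitResult, ratio_flag: float = SIGMA_RATIO_FLAG
) -> InconsistencyScreen:
    """Compare a consistency model against the UME model on the same data.

    Pairs the per-point deviance contributions (points with clearly larger
    contributions under the consistency model are candidates for local
    inconsistency) and puts the two between-study SD posteriors side by side.
    The qualitative flag raises when the UME SD median falls below
    ``ratio_flag`` times the consistency-model SD median.
    """
    if consistency_fit.model.data_signature != ume_fit.model.data_signature:
        raise ValueError("the two fits are not on the same data points")
    rep_c = consistency_fit.deviance or deviance_report(consistency_fit)
    rep_u = ume_fit.deviance or deviance_report(ume_fit)
    tbl = rep_c.per_point[["study", "agent", "dose_std"]].copy()
    tbl["dev_consistency"] = rep_c.per_point["deviance"].to_numpy()
    tbl["dev_ume"] = rep_u.per_point["deviance"].to_numpy()
    tbl["difference"] = tbl["dev_consistency"] - tbl["dev_ume"]

    def _sig(f):
        name = _sigma_name(f.model)
        lo, med, hi = np.quantile(f.get(name), [0.025, 0.5, 0.975])
        return (float(med), float(lo), float(hi))

    sig_c, sig_u = _sig(consistency_fit), _sig(ume_fit)
    return InconsistencyScreen(
        per_point=tbl,
        sigma_consistency=sig_c,
        sigma_ume=sig_u,
        flag=bool(sig_u[0] < ratio_flag * sig_c[0]),
    )


# ---------------------------------------------------------------------------
# visual predictive check data
# ---------------------------------------------------------------------------


def vpc_data(
    fit: FitResult, n_sims: int = 500, seed: int = 0, interval: float = 0.95
) -> pd.DataFrame:
    """Observed vs posterior-predictive response proportions per arm.

    For each arm, the predictive distribution of r/n is simulated from the
    posterior: study nuisances use their own draws, non-reference arms redraw
    their relative effect from N(model mean, sigma^2) under random effects
    (the marginal of the correlated multi-arm scheme), and counts are drawn
    binomially. The table is plot-ready: one row per data point with the
    observed proportion, predictive median and interval, keyed by study,
    agent and standardized dose. Deviance-vs-dose layouts use the
    per-point table of :func:`deviance_report` the same way.
    """
    model = fit.model
    rng = np.random.default_rng(seed)
    pooled = fit.pooled
    take = rng.choice(pooled.shape[0], size=min(n_sims, pooled.shape[0]), replace=False)
    theta = pooled[take]
    dec = model.decompose(theta) if hasattr(model, "decompose") else None
    s = model.arms if hasattr(model, "arms") else None
    if dec is not None and s is not None:
        mu = dec["mu"][:, s.arm_study]
        means = dec["delta_mean"]
        if dec["sigma"] is not None and s.n_slots:
            draws = rng.normal(means, dec["sigma"][:, None])
        else:
            draws = means
        if s.n_slots:
            gathered = draws[:, np.maximum(s.arm_slot, 0)]
            lin = mu + np.where(s.arm_slot >= 0, gathered, 0.0)
        else:
            lin = mu
        from scipy.special import expit

        p = expit(lin)
        r_obs, n_obs = s.r, s.n
        meta = s.arm_meta
    else:  # placebo-style model: fitted probabilities are the predictive mean
        p = model.fitted_probs(theta)
        r_obs, n_obs = _observed(model)
        meta = model.arm_meta
    sim = rng.binomial(n_obs.astype(int), p) / n_obs
    a = (1.0 - interval) / 2.0
    lo, med, hi = np.quantile(sim, [a, 0.5, 1.0 - a], axis=0)
    out = meta.copy()
    out["observed"] = r_obs / n_obs
    out["pred_median"] = med
    out["pred_lower"] = lo
    out["pred_upper"] = hi
    out["inside"] = (out["observed"] >= lo) & (out["observed"] <= hi)
    return out


def _observed(model):
    if hasattr(model, "arms"):
        return model.arms.r, model.arms.n
    return model.r, model.n
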