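"""Joint Bayesian models: NMA, dose-response MBNMA, UME, and placebo baselines.

Every model here shares one skeleton. Arm-level counts r_ik out of n_ik get a
binomial likelihood with

    logit(p_ik) = mu_i            for the reference arm (k = 1)
    logit(p_ik) = mu_i + delta_ik for k >= 2,

where mu_i is a per-study nuisance (the reference-arm log-odds, always an
independent vague normal so concurrent control is respected) and delta_ik is
the relative effect of arm k vs arm 1. The families differ only in how the
model-mean of delta_ik is built:

* NMA (lumped or split): d[t_k] - d[t_1] from s-1 basic parameters, so every
  contrast is a function of the basic parameters and consistency holds by
  construction.
* MBNMA: f(x_k, t_k) - f(x_1, t_1) for a parametric dose-response f — the
  consistency equations applied at the level of the dose-response curve.
  Agent parameters (e.g. Emax, log ED50) may be exchangeable across agents
  around class means to borrow strength.
* UME (unrelated mean effects): one free mean per treatment pair actually
  compared head-to-head in some study; no consistency constraints, used to
  probe disagreement of direct and indirect evidence.

Fixed-effect models set delta_ik equal to its model mean. Random-effects
models give each study's delta vector an exchangeable multivariate normal with
Var = sigma^2 and Cov = sigma^2/2 (so that every pairwise contrast within a
multi-arm study has the same heterogeneity variance), realized by sequential
univariate conditionals; sigma is common to all comparisons.

The standalone placebo model puts a random effect on the placebo-arm log-odds
(mu_i ~ N(m, s^2)) in the placebo-controlled trials only; it shares no
parameters with any relative-effect model, so running it cannot bias the
relative effects.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import trial_data as td
from .dose_response import get_dose_response

_LOG_2PI = float(np.log(2.0 * np.pi))

FAMILIES = ("nma_lumped", "nma_split", "mbnma", "ume", "placebo_re")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters (variances on the sampling scale).

    Defaults: N(0, 1000) on basic effects, dose-response parameters, class
    means and study nuisances; uniform(0, 4) on the between-study SD and on
    class SDs, except uniform(0, 20) for the Emax class SD. The between-study
    SD prior can be switched to a half-normal with precision 100 (SD 0.1) as
    a sensitivity option.
    """

    effect_sd: float = float(np.sqrt(1000.0))
    mu_sd: float = float(np.sqrt(1000.0))
    class_mean_sd: float = float(np.sqrt(1000.0))
    sigma_prior: tuple = ("uniform", 0.0, 4.0)
    class_sd_prior: tuple = ("uniform", 0.0, 4.0)
    emax_class_sd_prior: tuple = ("uniform", 0.0, 20.0)

    def to_dict(self):
        return {
            "effect_sd": self.effect_sd,
            "mu_sd": self.mu_sd,
            "class_mean_sd": self.class_mean_sd,
            "sigma_prior": list(self.sigma_prior),
            "class_sd_prior": list(self.class_sd_prior),
            "emax_class_sd_prior": list(self.emax_class_sd_prior),
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d or {})
        for k in ("sigma_prior", "class_sd_prior", "emax_class_sd_prior"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _normalize_class_effects(class_effects, dose_model):
    alias = {"emax_exchangeable": "emax", "ed50_exchangeable": "log_ed50", "ed50": "log_ed50"}
    out = frozenset(alias.get(c, c) for c in (class_effects or ()))
    if out and dose_model is not None:
        dm = get_dose_response(dose_model)
        bad = out - set(dm.class_effect_params)
        if bad:
            raise ValueError(
                f"class effects {sorted(bad)} not supported by dose model {dm.name!r}"
            )
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Which synthesis model to fit.

    family: nma_lumped | nma_split | mbnma | ume | placebo_re
    effect: fixed | random
    dose_model: registered dose-response name (mbnma only)
    class_effects: subset of the dose model's exchangeable parameters,
        e.g. {"emax_exchangeable", "ed50_exchangeable"} (mbnma/emax only)
    """

    family: str
    effect: str = "random"
    dose_model: str | None = None
    class_effects: frozenset = frozenset()
    priors: PriorSpec = field(default_factory=PriorSpec)
    link: str = "logit"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.effect not in ("fixed", "random"):
            raise ValueError(f"effect must be fixed|random, got {self.effect!r}")
        if self.link != "logit":
            raise ValueError("only the binomial-logit link is implemented")
        if self.family == "mbnma" and self.dose_model is None:
            object.__setattr__(self, "dose_model", "emax")
        if self.family != "mbnma" and self.dose_model is not None:
            raise ValueError(f"family {self.family!r} takes no dose model")
        object.__setattr__(
            self, "class_effects", _normalize_class_effects(self.class_effects, self.dose_model)
        )

    @property
    def label(self) -> str:
        if self.family == "mbnma":
            extras = ""
            if self.class_effects:
                extras = " (" + " & ".join(sorted(self.class_effects)) + " exch.)"
            return f"mbnma[{self.dose_model}]{extras} ({self.effect})"
        return f"{self.family} ({self.effect})"

    def to_dict(self):
        return {
            "family": self.family,
            "effect": self.effect,
            "dose_model": self.dose_model,
            "class_effects": sorted(self.class_effects),
            "priors": self.priors.to_dict(),
            "link": self.link,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["priors"] = PriorSpec.from_dict(d.get("priors"))
        d["class_effects"] = frozenset(d.get("class_effects") or ())
        return cls(**d)


# ---------------------------------------------------------------------------
# multi-arm random-effects decomposition
# ---------------------------------------------------------------------------


def sequential_logpdf(delta, means, sigma):
    """Log density of one study's relative effects under the multi-arm scheme.

    The a-1 relative effects of an a-arm study are exchangeable multivariate
    normal with Var = sigma^2 and Cov = sigma^2/2. This evaluates the joint
    density through sequential univariate conditionals: the effect in arm
    position j (j = 2..a) has conditional mean
    ``mean_j + (1/(j-1)) * sum_{h<j} (delta_h - mean_h)`` and conditional
    variance ``sigma^2 * j / (2 (j-1))``.

    ``delta``/``means`` may carry leading batch axes; the last axis is the
    within-study position. Returns the summed log density over positions.
    """
    delta = np.asarray(delta, dtype=float)
    means = np.broadcast_to(np.asarray(means, dtype=float), delta.shape)
    sigma = np.asarray(sigma, dtype=float)
    q = delta.shape[-1]
    resid = delta - means
    out = 0.0
    prefix = np.zeros(delta.shape[:-1])
    for p in range(q):  # p = 0-based position, arm index j = p + 2
        cond_mean = means[..., p] + prefix / (p + 1)
        cond_var = sigma**2 * (p + 2) / (2.0 * (p + 1))
        out = out - 0.5 * (
            _LOG_2PI + np.log(cond_var) + (delta[..., p] - cond_mean) ** 2 / cond_var
        )
        prefix = prefix + resid[..., p]
    return out


def sequential_draw(means, sigma, rng):
    """Draw one study's correlated relative effects via the same conditionals."""
    means = np.asarray(means, dtype=float)
    q = means.shape[-1]
    delta = np.empty_like(means)
    prefix = 0.0
    for p in range(q):
        cond_mean = means[p] + prefix / (p + 1)
        cond_sd = sigma * np.sqrt((p + 2) / (2.0 * (p + 1)))
        delta[p] = rng.normal(cond_mean, cond_sd)
        prefix += delta[p] - means[p]
    return delta


def multiarm_covariance(q, sigma):
    """The q x q covariance the sequential scheme realizes (for oracles/tests)."""
    return sigma**2 * (0.5 * np.eye(q) + 0.5 * np.ones((q, q)))


# ---------------------------------------------------------------------------
# prior helpers
# ---------------------------------------------------------------------------


def _normal_lp(x, sd, mean=0.0):
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sd) + ((x - mean) / sd) ** 2)


def _sd_prior_lp(x, prior):
    """Log prior for an SD parameter; -inf outside support."""
    kind = prior[0]
    if kind == "uniform":
        lo, hi = prior[1], prior[2]
        return np.where((x > lo) & (x < hi), -np.log(hi - lo), -np.inf)
    if kind == "half_normal":
        sd = prior[1]
        return np.where(x > 0, _normal_lp(x, sd) + np.log(2.0), -np.inf)
    raise ValueError(f"unknown SD prior {prior!r}")


def _sd_prior_init(prior, rng, shape):
    hi = prior[2] if prior[0] == "uniform" else 4.0 * prior[1]
    return rng.uniform(0.1, min(0.6, 0.9 * hi), size=shape)


# ---------------------------------------------------------------------------
# shared arm structure
# ---------------------------------------------------------------------------


class _ArmStructure:
    """Index arrays tying arms, studies and delta slots together.

    A "slot" is one latent relative effect: one per distinct non-reference
    coded treatment within each study (arms coded identically to the study
    reference — which only happens under lumping — are pinned to delta = 0,
    and arms duplicating another non-reference coded treatment share its
    slot).
    """

    def __init__(self, net: td.TrialNetwork):
        self.net = net
        self.study_ids = [st.study_id for st in net.studies]
        self.n_studies = len(net.studies)
        r, n, arm_study, arm_slot = [], [], [], []
        slot_study, slot_code, slot_ref_code, slot_pos = [], [], [], []
        slot_emp_logor = []
        meta_rows = []
        study_starts = []
        for i, st in enumerate(net.studies):
            study_starts.append(len(r))
            ref = st.arms[0]
            ref_code = net.coded(ref)
            local: dict = {}
            emp_ref = np.log((ref.responders + 0.5) / (ref.sample_size - ref.responders + 0.5))
            for a in st.arms:
                code = net.coded(a)
                if a is st.arms[0] or code == ref_code:
                    slot = -1
                elif code in local:
                    slot = local[code]
                else:
                    slot = len(slot_study)
                    local[code] = slot
                    slot_study.append(i)
                    slot_code.append(code)
                    slot_ref_code.append(ref_code)
                    slot_pos.append(len(local) - 1)
                    emp_a = np.log(
                        (a.responders + 0.5) / (a.sample_size - a.responders + 0.5)
                    )
                    slot_emp_logor.append(emp_a - emp_ref)
                r.append(a.responders)
                n.append(a.sample_size)
                arm_study.append(i)
                arm_slot.append(slot)
                meta_rows.append(
                    {
                        "study": a.study_id,
                        "agent": a.agent,
                        "dose_std": a.dose_std,
                        "responders": a.responders,
                        "sample_size": a.sample_size,
                    }
                )
        self.r = np.asarray(r, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.arm_study = np.asarray(arm_study, dtype=np.intp)
        self.arm_slot = np.asarray(arm_slot, dtype=np.intp)
        self.study_starts = np.asarray(study_starts, dtype=np.intp)
        self.slot_study = np.asarray(slot_study, dtype=np.intp)
        self.slot_pos = np.asarray(slot_pos, dtype=np.intp)
        self.slot_code = slot_code
        self.slot_ref_code = slot_ref_code
        self.slot_emp_logor = np.asarray(slot_emp_logor, dtype=float)
        self.n_arms = len(r)
        self.n_slots = len(slot_code)
        self.arm_meta = pd.DataFrame(meta_rows)
        # reduceat groups for the RE density: slots are contiguous by study
        self.slot_group_starts = np.flatnonzero(
            np.r_[True, np.diff(self.slot_study) != 0]
        ).astype(np.intp)
        self.slot_group_study = (
            self.slot_study[self.slot_group_starts]
            if self.n_slots
            else np.empty(0, dtype=np.intp)
        )
        # index arrays for the sequential-conditional density (precomputed,
        # the density is evaluated once per posterior-part call)
        first_slot = np.empty(self.n_slots, dtype=np.intp)
        for g, start in enumerate(self.slot_group_starts):
            end = (
                self.slot_group_starts[g + 1]
                if g + 1 < len(self.slot_group_starts)
                else self.n_slots
            )
            first_slot[start:end] = start
        self.slot_prev_idx = np.arange(self.n_slots) - 1
        self.slot_base_idx = first_slot - 1
        self.slot_var_factor = (self.slot_pos + 2) / (2.0 * (self.slot_pos + 1))
        # per-study empirical reference log-odds for initialization
        ref_idx = self.study_starts
        self.emp_mu = np.log(
            (self.r[ref_idx] + 0.5) / (self.n[ref_idx] - self.r[ref_idx] + 0.5)
        )


# ---------------------------------------------------------------------------
# base network model
# ---------------------------------------------------------------------------


class _BaseNetworkModel:
    """Common machinery: parameter layout, likelihood, posterior parts.

    Parameter vector layout: [mu_0..mu_{S-1}] + [delta slots (random effects
    only)] + [treatment/hyper scalars] + [sigma (random effects only)].
    """

    def __init__(self, net: td.TrialNetwork, spec: ModelSpec):
        self.net = net
        self.spec = spec
        self.priors = spec.priors
        self.arms = _ArmStructure(net)
        self.random_effects = spec.effect == "random"
        s = self.arms
        self.n_studies = s.n_studies
        self.n_datapoints = s.n_arms
        self.treat_names = self._treat_param_names()
        names = [f"mu[{sid}]" for sid in s.study_ids]
        self.mu_indices = np.arange(s.n_studies, dtype=np.intp)
        if self.random_effects and s.n_slots:
            names += [
                f"delta[{sid}:{td._node_label(code)}]"
                for sid, code in zip(
                    (s.study_ids[i] for i in s.slot_study), s.slot_code
                )
            ]
            self.delta_indices = np.arange(
                s.n_studies, s.n_studies + s.n_slots, dtype=np.intp
            )
        else:
            self.delta_indices = np.empty(0, dtype=np.intp)
        self._scalar_start = len(names)
        names += list(self.treat_names)
        if self.random_effects:
            names += ["sigma"]
            self.sigma_index = len(names) - 1
        else:
            self.sigma_index = None
        self.param_names = names
        self.n_params = len(names)
        self.scalar_indices = np.arange(self._scalar_start, self.n_params, dtype=np.intp)
        self._tp_slice = slice(self._scalar_start, self._scalar_start + len(self.treat_names))
        self.label = spec.label
        self.data_signature = hashlib.sha1(
            np.ascontiguousarray(np.c_[s.r, s.n]).tobytes()
        ).hexdigest()

    # -- hooks ------------------------------------------------------------

    def _treat_param_names(self) -> list[str]:
        raise NotImplementedError

    def _delta_means(self, theta) -> np.ndarray:
        """Model means of the delta slots; theta is (m, n_params)."""
        raise NotImplementedError

    def _treat_logprior(self, theta) -> np.ndarray:
        raise NotImplementedError

    def _initial_treat(self, rng, m) -> np.ndarray:
        return 0.5 * rng.standard_normal((m, len(self.treat_names)))

    # -- posterior --------------------------------------------------------

    def _delta_contrib(self, theta):
        if self.random_effects and self.arms.n_slots:
            return theta[..., self.delta_indices]
        return self._delta_means(theta)

    def _linear_predictor(self, theta):
        s = self.arms
        mu = theta[..., self.mu_indices]
        lin = mu[..., s.arm_study]
        if s.n_slots:
            contrib = self._delta_contrib(theta)
            gathered = contrib[..., np.maximum(s.arm_slot, 0)]
            lin = lin + np.where(s.arm_slot >= 0, gathered, 0.0)
        return lin

    # The sampler caches the three posterior pieces separately so each block
    # update recomputes only what it can change:
    #   base_part  — binomial likelihood + mu priors, per study (mu, delta)
    #   re_part    — multi-arm RE density, per study (delta, treat, sigma)
    #   glob_part  — treatment / hyper / sigma priors (scalars)
    # Under random effects, scalar updates never touch the likelihood and mu
    # updates never touch the RE density.
    mu_affects_re = False

    @property
    def scalars_affect_base(self):
        # fixed effects route the contrast means straight into the likelihood
        return not (self.random_effects and self.arms.n_slots)

    def base_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        s = self.arms
        lin = self._linear_predictor(theta)
        ll = s.r * lin - s.n * np.logaddexp(0.0, lin)
        study = np.add.reduceat(ll, s.study_starts, axis=-1)
        mu = theta[..., self.mu_indices]
        return study + _normal_lp(mu, self.priors.mu_sd)

    def re_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        s = self.arms
        if not (self.random_effects and s.n_slots):
            return np.zeros(theta.shape[:-1] + (s.n_studies,))
        sigma = theta[..., self.sigma_index]
        delta = theta[..., self.delta_indices]
        means = self._delta_means(theta)
        return self._grouped_re_logpdf(delta, means, np.where(sigma > 0, sigma, 1.0))

    def glob_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        glob = self._treat_logprior(theta)
        if self.random_effects:
            sigma = theta[..., self.sigma_index]
            glob = glob + _sd_prior_lp(sigma, self.priors.sigma_prior)
        return glob

    def logpost_parts(self, theta):
        """(per-study log-posterior terms (m, S), remaining global terms (m,))."""
        theta = np.asarray(theta, dtype=float)
        return self.base_part(theta) + self.re_part(theta), self.glob_part(theta)

    def _grouped_re_logpdf(self, delta, means, sigma):
        """Sequential-conditional RE density, batched over chains, per study."""
        s = self.arms
        pos = s.slot_pos
        resid = delta - means
        cs = np.cumsum(resid, axis=-1)
        prefix = np.where(
            pos > 0,
            cs[..., s.slot_prev_idx]
            - np.where(s.slot_base_idx >= 0, cs[..., s.slot_base_idx], 0.0),
            0.0,
        )
        cond_mean = means + prefix / (pos + 1)
        sig2 = np.asarray(sigma)[..., None] ** 2
        cond_var = sig2 * s.slot_var_factor
        lp = -0.5 * (
            _LOG_2PI + np.log(cond_var) + (delta - cond_mean) ** 2 / cond_var
        )
        sums = np.add.reduceat(lp, s.slot_group_starts, axis=-1)
        out = np.zeros(delta.shape[:-1] + (s.n_studies,))
        out[..., s.slot_group_study] = sums
        return out

    def log_posterior(self, theta):
        """Joint log posterior, vectorized over a (m, n_params) batch."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        study, glob = self.logpost_parts(theta)
        out = study.sum(axis=-1) + glob
        return np.where(np.isfinite(out), out, -np.inf)

    # -- fitted values ----------------------------------------------------

    def fitted_probs(self, theta):
        """Per-arm fitted probabilities for a batch of parameter vectors."""
        return expit(self._linear_predictor(np.asarray(theta, dtype=float)))

    def decompose(self, theta):
        """mu, delta model means, realized deltas and sigma from draws."""
        theta = np.asarray(theta, dtype=float)
        out = {
            "mu": theta[..., self.mu_indices],
            "delta_mean": self._delta_means(theta),
            "delta": theta[..., self.delta_indices] if self.random_effects else None,
            "sigma": theta[..., self.sigma_index] if self.random_effects else None,
        }
        return out

    # -- initialization ---------------------------------------------------

    def initial_values(self, rng, m):
        """Overdispersed, data-informed starting points with finite posterior."""
        s = self.arms
        theta = np.empty((m, self.n_params))
        theta[:, self.mu_indices] = s.emp_mu + 0.5 * rng.standard_normal((m, s.n_studies))
        if self.random_effects and s.n_slots:
            theta[:, self.delta_indices] = s.slot_emp_logor + 0.5 * rng.standard_normal(
                (m, s.n_slots)
            )
        theta[:, self._tp_slice] = self._initial_treat(rng, m)
        if self.random_effects:
            theta[:, self.sigma_index] = _sd_prior_init(self.priors.sigma_prior, rng, m)
        return theta

    # -- prediction hook ---------------------------------------------------

    def dose_effect_draws(self, theta, agent, dose):
        """Draws of the log-odds effect of (agent, dose) vs placebo."""
        raise NotImplementedError

    @property
    def arm_meta(self) -> pd.DataFrame:
        return self.arms.arm_meta

    @property
    def max_trialed_dose(self):
        out: dict[str, float] = {}
        for st in self.net.studies:
            for a in st.arms:
                if not td.is_placebo(a.agent):
                    out[a.agent] = max(out.get(a.agent, 0.0), a.dose_std)
        return out


# ---------------------------------------------------------------------------
# NMA (lumped / split)
# ---------------------------------------------------------------------------


class NMAModel(_BaseNetworkModel):
    """Standard NMA with s-1 basic parameters at the coded-treatment level."""

    def __init__(self, net, spec):
        self.nodes = net.nodes  # reference first
        self._node_index = {c: i for i, c in enumerate(self.nodes)}
        super().__init__(net, spec)
        s = self.arms
        self._slot_node = np.asarray(
            [self._node_index[c] for c in s.slot_code], dtype=np.intp
        )
        self._slot_ref_node = np.asarray(
            [self._node_index[c] for c in s.slot_ref_code], dtype=np.intp
        )

    def _treat_param_names(self):
        return [f"d[{td._node_label(c)}]" for c in self.nodes[1:]]

    def basic_parameters(self):
        return list(self.treat_names)

    def _d_full(self, theta):
        tp = theta[..., self._tp_slice]
        zero = np.zeros(tp.shape[:-1] + (1,))
        return np.concatenate([zero, tp], axis=-1)

    def _delta_means(self, theta):
        d = self._d_full(theta)
        return d[..., self._slot_node] - d[..., self._slot_ref_node]

    def _treat_logprior(self, theta):
        tp = theta[..., self._tp_slice]
        return _normal_lp(tp, self.priors.effect_sd).sum(axis=-1)

    def contrast(self, theta, node_c, node_k):
        """d_{c,k} = d_{1,k} - d_{1,c} from the basic parameters."""
        d = self._d_full(np.asarray(theta, dtype=float))
        return d[..., self._node_index[node_k]] - d[..., self._node_index[node_c]]

    def dose_effect_draws(self, theta, agent, dose):
        d = self._d_full(np.asarray(theta, dtype=float))
        if self.net.level == "agent":
            if agent not in self._node_index:
                raise KeyError(f"agent {agent!r} not in fitted network")
            return d[..., self._node_index[agent]]
        for node, i in self._node_index.items():
            if isinstance(node, tuple) and node[0] == agent and np.isclose(node[1], dose):
                return d[..., i]
        raise KeyError(
            f"treatment ({agent!r}, {dose}) was not a node of the split network; "
            "a split NMA can only predict at trialed doses"
        )


# ---------------------------------------------------------------------------
# MBNMA
# ---------------------------------------------------------------------------


class MBNMAModel(_BaseNetworkModel):
    """Dose-response MBNMA: delta means are differences of f(x, t)."""

    def __init__(self, net, spec):
        self.dose_model = get_dose_response(spec.dose_model)
        self.active_agents = [a for a in net.agents if not td.is_placebo(a)]
        self._agent_index = {a: i for i, a in enumerate(self.active_agents)}
        if spec.class_effects and len(self.active_agents) < 2:
            raise ValueError(
                "class effects need at least 2 active agents to be identifiable"
            )
        super().__init__(net, spec)
        s = self.arms

        def _ai(code):
            return -1 if td.is_placebo(code[0]) else self._agent_index[code[0]]

        self._slot_agent = np.asarray([_ai(c) for c in s.slot_code], dtype=np.intp)
        self._slot_x = np.asarray([c[1] for c in s.slot_code], dtype=float)
        self._ref_agent = np.asarray([_ai(c) for c in s.slot_ref_code], dtype=np.intp)
        self._ref_x = np.asarray([c[1] for c in s.slot_ref_code], dtype=float)
        # absolute theta columns of each slot's agent parameter block, so the
        # dose-response means need a single gather per evaluation
        P = len(self.dose_model.param_names)
        A = len(self.active_agents)
        self._slot_param_cols = (
            self._scalar_start
            + np.arange(P)[None, :] * A
            + np.maximum(self._slot_agent, 0)[:, None]
        )
        self._ref_param_cols = (
            self._scalar_start
            + np.arange(P)[None, :] * A
            + np.maximum(self._ref_agent, 0)[:, None]
        )
        self._any_active_ref = bool(np.any(self._ref_agent >= 0))
        # Emax-specific sampler hint: the likelihood is nearly flat along the
        # (Emax, log ED50) ridge that preserves the effect in the trialed dose
        # range, so expose per-agent ridge moves. Two pivots (the agent's
        # lowest and highest trialed dose) let alternating moves both shift
        # and tilt the curve while staying on the ridge.
        self.ridge_moves = []
        if tuple(self.dose_model.param_names) == ("emax", "log_ed50"):
            A = len(self.active_agents)
            doses_by_agent: dict[str, list[float]] = {}
            for st in net.studies:
                for a in st.arms:
                    if not td.is_placebo(a.agent):
                        doses_by_agent.setdefault(a.agent, []).append(a.dose_std)
            for i, agent in enumerate(self.active_agents):
                pivots = {float(min(doses_by_agent[agent])), float(max(doses_by_agent[agent]))}
                for pivot in sorted(pivots):
                    self.ridge_moves.append(
                        (self._scalar_start + i, self._scalar_start + A + i, pivot)
                    )

    def _treat_param_names(self):
        dm = get_dose_response(self.spec.dose_model)
        names = [f"{p}[{a}]" for p in dm.param_names for a in self.active_agents]
        for p in dm.param_names:
            if p in self.spec.class_effects:
                names += [f"mu_{p}", f"sigma_{p}"]
        return names

    @property
    def _n_agent_params(self):
        return len(self.dose_model.param_names) * len(self.active_agents)

    def agent_param_array(self, theta):
        """(..., n_agents, n_dose_params) agent-level parameter blocks."""
        theta = np.asarray(theta, dtype=float)
        tp = theta[..., self._tp_slice][..., : self._n_agent_params]
        A = len(self.active_agents)
        P = len(self.dose_model.param_names)
        return np.moveaxis(tp.reshape(tp.shape[:-1] + (P, A)), -1, -2)

    def _f(self, theta, agent_idx, x, param_cols):
        """f(x, agent) batched; agent_idx -1 means placebo (f = 0)."""
        gathered = theta[..., param_cols]  # (..., L, P)
        vals = self.dose_model.evaluate(x, gathered)
        return np.where(agent_idx >= 0, vals, 0.0)

    def _delta_means(self, theta):
        out = self._f(theta, self._slot_agent, self._slot_x, self._slot_param_cols)
        if self._any_active_ref:
            out = out - self._f(theta, self._ref_agent, self._ref_x, self._ref_param_cols)
        return out

    def _hyper_offsets(self):
        off = self._scalar_start + self._n_agent_params
        out = {}
        for p in self.dose_model.param_names:
            if p in self.spec.class_effects:
                out[p] = (off, off + 1)
                off += 2
        return out

    def _treat_logprior(self, theta):
        pr = self.priors
        A = len(self.active_agents)
        hy = self._hyper_offsets()
        out = 0.0
        for j, p in enumerate(self.dose_model.param_names):
            block = theta[..., self._tp_slice][..., j * A : (j + 1) * A]
            if p in self.spec.class_effects:
                mu_i, sd_i = hy[p]
                mu, sd = theta[..., mu_i], theta[..., sd_i]
                sd_prior = pr.emax_class_sd_prior if p == "emax" else pr.class_sd_prior
                sd_safe = np.where(sd > 0, sd, 1.0)
                out = (
                    out
                    + _normal_lp(block, sd_safe[..., None], mu[..., None]).sum(axis=-1)
                    + _normal_lp(mu, pr.class_mean_sd)
                    + _sd_prior_lp(sd, sd_prior)
                )
            else:
                out = out + _normal_lp(block, pr.effect_sd).sum(axis=-1)
        return out + np.zeros(theta.shape[:-1])

    def _empirical_emax_start(self):
        """Crude per-agent (emax, log_ed50) from empirical log-odds ratios.

        Grid over log ED50 with a least-squares Emax at each grid point;
        keeps chain starts in the data-supported region instead of the
        near-flat ridge, which matters at short run lengths.
        """
        s = self.arms
        A = len(self.active_agents)
        est = np.zeros((A, 2))
        for i in range(A):
            mask = (self._slot_agent == i) & (self._ref_agent < 0)
            if not np.any(mask):
                continue
            x = self._slot_x[mask]
            y = s.slot_emp_logor[mask]
            best = (np.inf, 0.0, 0.0)
            for led in np.linspace(-2.0, 2.0, 9):
                g = x / (np.exp(led) + x)
                denom = float(g @ g)
                emax = float(g @ y) / denom if denom > 0 else 0.0
                sse = float(((y - emax * g) ** 2).sum())
                if sse < best[0]:
                    best = (sse, emax, led)
            est[i] = (best[1], best[2])
        return est

    def _initial_treat(self, rng, m):
        out = 0.5 * rng.standard_normal((m, len(self.treat_names)))
        if self.ridge_moves:
            A = len(self.active_agents)
            est = self._empirical_emax_start()
            out[:, :A] += est[:, 0]
            out[:, A : 2 * A] += est[:, 1]
        hy = self._hyper_offsets()
        pr = self.priors
        for p, (mu_i, sd_i) in hy.items():
            sd_prior = pr.emax_class_sd_prior if p == "emax" else pr.class_sd_prior
            out[:, sd_i - self._scalar_start] = _sd_prior_init(sd_prior, rng, m)
        return out

    def dose_effect_draws(self, theta, agent, dose):
        if agent not in self._agent_index:
            raise KeyError(f"agent {agent!r} not in fitted network")
        theta = np.asarray(theta, dtype=float)
        pa = self.agent_param_array(theta)[..., self._agent_index[agent], :]
        return np.asarray(self.dose_model.evaluate(float(dose), pa))


# ---------------------------------------------------------------------------
# UME
# ---------------------------------------------------------------------------


class UMEModel(_BaseNetworkModel):
    """Unrelated mean effects: a free mean per pair compared within some study."""

    def __init__(self, net, spec):
        node_index = {c: i for i, c in enumerate(net.nodes)}
        pairs = []
        seen = {}
        struct = _ArmStructure(net)
        for code, ref in zip(struct.slot_code, struct.slot_ref_code):
            i, j = node_index[ref], node_index[code]
            key = (min(i, j), max(i, j))
            if key not in seen:
                seen[key] = len(pairs)
                pairs.append(key)
        self._node_index = node_index
        self._nodes = net.nodes
        self.pairs = pairs
        self._pair_index = seen
        super().__init__(net, spec)
        s = self.arms
        slot_pair, slot_sign = [], []
        for code, ref in zip(s.slot_code, s.slot_ref_code):
            i, j = node_index[ref], node_index[code]
            key = (min(i, j), max(i, j))
            slot_pair.append(seen[key])
            slot_sign.append(1.0 if j > i else -1.0)
        self._slot_pair = np.asarray(slot_pair, dtype=np.intp)
        self._slot_sign = np.asarray(slot_sign, dtype=float)

    def _treat_param_names(self):
        return [
            f"d[{td._node_label(self._nodes[i])}|{td._node_label(self._nodes[j])}]"
            for i, j in self.pairs
        ]

    def _delta_means(self, theta):
        tp = theta[..., self._tp_slice]
        return self._slot_sign * tp[..., self._slot_pair]

    def _treat_logprior(self, theta):
        tp = theta[..., self._tp_slice]
        return _normal_lp(tp, self.priors.effect_sd).sum(axis=-1)

    def dose_effect_draws(self, theta, agent, dose):
        raise NotImplementedError(
            "the UME model has no consistent relative effects to predict from"
        )


# ---------------------------------------------------------------------------
# placebo random-effects model
# ---------------------------------------------------------------------------


class PlaceboREModel:
    """Random-effects model for placebo-arm log-odds, fitted separately.

    mu_i ~ N(m, s^2) for each placebo-controlled study; the posterior of m is
    the "typical trial" anchor used for absolute predictions. Shares no
    parameters with any relative-effect model.
    """

    random_effects = False  # no between-study sigma on relative effects
    sigma_index = None

    def __init__(self, net: td.TrialNetwork, priors: PriorSpec | None = None):
        self.net = net
        self.priors = priors or PriorSpec()
        r, n, arm_study, study_ids = [], [], [], []
        meta = []
        for st in net.studies:
            p_arms = [a for a in st.arms if td.is_placebo(a.agent)]
            if not p_arms:
                continue
            sid = len(study_ids)
            study_ids.append(st.study_id)
            for a in p_arms:
                r.append(a.responders)
                n.append(a.sample_size)
                arm_study.append(sid)
                meta.append(
                    {
                        "study": a.study_id,
                        "agent": a.agent,
                        "dose_std": 0.0,
                        "responders": a.responders,
                        "sample_size": a.sample_size,
                    }
                )
        if len(study_ids) < 2:
            raise ValueError(
                "placebo random-effects model needs placebo arms in >= 2 studies "
                "(the between-study SD is unidentifiable otherwise)"
            )
        self.r = np.asarray(r, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.arm_study = np.asarray(arm_study, dtype=np.intp)
        self.study_ids = study_ids
        self.n_studies = len(study_ids)
        self.n_datapoints = len(r)
        self.arm_meta = pd.DataFrame(meta)
        order = np.argsort(self.arm_study, kind="stable")
        assert np.all(order == np.arange(len(order)))  # built in study order
        self.study_starts = np.flatnonzero(np.r_[True, np.diff(self.arm_study) != 0])
        self.param_names = [f"mu[{sid}]" for sid in study_ids] + ["m", "s"]
        self.n_params = len(self.param_names)
        self.mu_indices = np.arange(self.n_studies, dtype=np.intp)
        self.delta_indices = np.empty(0, dtype=np.intp)
        self.scalar_indices = np.arange(self.n_studies, self.n_params, dtype=np.intp)
        self.label = "placebo_re"
        self.spec = ModelSpec(family="placebo_re", effect="random", priors=self.priors)
        self.data_signature = hashlib.sha1(
            np.ascontiguousarray(np.c_[self.r, self.n]).tobytes()
        ).hexdigest()
        self.emp_mu = np.log(
            (self.r[self.study_starts] + 0.5)
            / (self.n[self.study_starts] - self.r[self.study_starts] + 0.5)
        )

    mu_affects_re = True  # the mu_i "RE" term is their N(m, s^2) prior
    scalars_affect_base = False

    def base_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        mu = theta[..., self.mu_indices]
        lin = mu[..., self.arm_study]
        ll = self.r * lin - self.n * np.logaddexp(0.0, lin)
        return np.add.reduceat(ll, self.study_starts, axis=-1)

    def re_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        mu = theta[..., self.mu_indices]
        m = theta[..., self.n_studies]
        s = theta[..., self.n_studies + 1]
        s_safe = np.where(s > 0, s, 1.0)
        return _normal_lp(mu, s_safe[..., None], m[..., None])

    def glob_part(self, theta):
        theta = np.asarray(theta, dtype=float)
        m = theta[..., self.n_studies]
        s = theta[..., self.n_studies + 1]
        return _normal_lp(m, self.priors.mu_sd) + _sd_prior_lp(s, ("uniform", 0.0, 4.0))

    def logpost_parts(self, theta):
        theta = np.asarray(theta, dtype=float)
        return self.base_part(theta) + self.re_part(theta), self.glob_part(theta)

    def log_posterior(self, theta):
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        study, glob = self.logpost_parts(theta)
        out = study.sum(axis=-1) + glob
        return np.where(np.isfinite(out), out, -np.inf)

    def fitted_probs(self, theta):
        theta = np.asarray(theta, dtype=float)
        return expit(theta[..., self.mu_indices][..., self.arm_study])

    def initial_values(self, rng, m):
        theta = np.empty((m, self.n_params))
        theta[:, self.mu_indices] = self.emp_mu + 0.5 * rng.standard_normal(
            (m, self.n_studies)
        )
        theta[:, self.n_studies] = self.emp_mu.mean() + 0.5 * rng.standard_normal(m)
        theta[:, self.n_studies + 1] = rng.uniform(0.1, 0.6, size=m)
        return theta


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _check_connected(net, level, family):
    ok, comps = td.connectivity(net, level)
    if not ok:
        raise ValueError(
            f"{family}: the {level}-level network is disconnected; components: {comps}"
        )


def build_nma(net: td.TrialNetwork, spec: ModelSpec) -> NMAModel:
    """Lumped (agent-level) or split (treatment-level) NMA."""
    if spec.family not in ("nma_lumped", "nma_split"):
        raise ValueError(f"build_nma got family {spec.family!r}")
    level = "agent" if spec.family == "nma_lumped" else "treatment"
    net = replace(net, level=level)
    _check_connected(net, level, spec.family)
    return NMAModel(net, spec)


def build_mbnma(net: td.TrialNetwork, spec: ModelSpec) -> MBNMAModel:
    """Dose-response MBNMA at the (agent, standardized dose) treatment level."""
    if spec.family != "mbnma":
        raise ValueError(f"build_mbnma got family {spec.family!r}")
    net = replace(net, level="treatment")
    # agent-parameter sharing links all doses of an agent, so connectivity is
    # required at the agent level only
    _check_connected(net, "agent", spec.family)
    return MBNMAModel(net, spec)


def build_ume(net: td.TrialNetwork, spec: ModelSpec) -> UMEModel:
    """Unrelated-mean-effects inconsistency model at the split-treatment level."""
    if spec.family != "ume":
        raise ValueError(f"build_ume got family {spec.family!r}")
    return UMEModel(replace(net, level="treatment"), spec)


def build_placebo_re(net: td.TrialNetwork, priors: PriorSpec | None = None) -> PlaceboREModel:
    return PlaceboREModel(net, priors)


def build_model(net: td.TrialNetwork, spec: ModelSpec):
    """Dispatch on ``spec.family``."""
    if spec.family in ("nma_lumped", "nma_split"):
        return build_nma(net, spec)
    if spec.family == "mbnma":
        return build_mbnma(net, spec)
    if spec.family == "ume":
        return build_ume(net, spec)
    if spec.family == "placebo_re":
        return build_placebo_re(net, spec.priors)
    raise ValueError(f"unknown family {spec.family!r}")
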