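"""MCMC estimation, convergence diagnostics and posterior summaries.

The estimation contract is distributional: any correct sampler is acceptable,
and the backend is a replaceable strategy. Two are shipped:

* ``"gibbs"`` (default) — a blocked adaptive Metropolis-within-Gibbs sampler
  written for the model structure in :mod:`mbnma.models`. Study nuisances and
  study relative effects are proposed for all studies at once and accepted
  per study (their full conditionals factorize over studies), treatment-level
  and variance parameters are updated one at a time against the full
  posterior. Proposal scales adapt by Robbins-Monro during burn-in only, so
  the post-burn-in chain is Markovian.
* ``"ensemble"`` — the affine-invariant ensemble sampler from :mod:`emcee`,
  used as an independent cross-check of distributional correctness.

Runs are deterministic given the seed, the configuration and the backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RunConfig:
    """Chain lengths and seeding.

    Defaults follow common practice for these models: 3 independent chains,
    40,000 kept iterations after 40,000 burn-in, thinning 10. ``reduced()``
    gives a short preset (3 x 2000/2000, thin 1) for tests and simulation
    studies.
    """

    n_chains: int = 3
    burn_in: int = 40000
    keep: int = 40000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.burn_in < 0 or self.keep < 1 or self.thin < 1:
            raise ValueError("invalid run configuration")
        if self.keep // self.thin < 100:
            warnings.warn(
                "fewer than 100 retained draws per chain; summaries will be noisy",
                stacklevel=2,
            )

    @property
    def n_kept(self) -> int:
        """Retained draws per chain: keep // thin exactly."""
        return self.keep // self.thin

    @classmethod
    def reduced(cls, seed: int = 0, n_chains: int = 3) -> "RunConfig":
        return cls(n_chains=n_chains, burn_in=2000, keep=2000, thin=1, seed=seed)

    def to_dict(self):
        return {
            "n_chains": self.n_chains,
            "burn_in": self.burn_in,
            "keep": self.keep,
            "thin": self.thin,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class FitResult:
    """Posterior draws plus bookkeeping.

    ``draws`` has shape (n_chains, n_kept, n_params) on the sampling scale
    (ED50 is sampled as log ED50; summaries back-transform). ``deviance`` is
    filled by :mod:`mbnma.checking`.
    """

    draws: np.ndarray
    param_names: list[str]
    model: object
    config: RunConfig
    sampler: str
    rhat: dict[str, float] = field(default_factory=dict)
    deviance: object | None = None
    label: str = ""

    def __post_init__(self):
        if not self.label:
            self.label = getattr(self.model, "label", type(self.model).__name__)

    # -- access -----------------------------------------------------------

    @property
    def pooled(self) -> np.ndarray:
        c, k, d = self.draws.shape
        return self.draws.reshape(c * k, d)

    def _index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """Pooled post-thinning draws of one parameter."""
        return self.pooled[:, self._index(name)]

    def chains(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) draws of one parameter."""
        return self.draws[:, :, self._index(name)]

    def names(self, prefix: str) -> list[str]:
        return [p for p in self.param_names if p.startswith(prefix)]

    @property
    def converged(self) -> bool:
        return bool(self.rhat) and max(self.rhat.values()) < RHAT_WARN_THRESHOLD

    def summary(self, transforms: dict | None = None) -> pd.DataFrame:
        return summarize(self, transforms)

    def mcse(self, name: str) -> float:
        """Monte Carlo standard error of the posterior mean of one parameter."""
        ch = self.chains(name)
        return float(ch.std(ddof=1) / np.sqrt(max(effective_sample_size(ch), 1.0)))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

RHAT_WARN_THRESHOLD = 1.05


def fit(model, config: RunConfig, sampler: str = "gibbs") -> FitResult:
    """Sample the joint posterior of a built model.

    Deterministic given (seed, config, sampler backend). Raises if the log
    posterior is non-finite at the initial values. Attaches split-chain R-hat
    per parameter and warns when any exceeds 1.05.
    """
    if sampler == "gibbs":
        draws = _metropolis_gibbs(model, config)
    elif sampler == "ensemble":
        draws = _ensemble(model, config)
    else:
        raise ValueError(f"unknown sampler backend {sampler!r}")
    result = FitResult(
        draws=draws,
        param_names=list(model.param_names),
        model=model,
        config=config,
        sampler=sampler,
    )
    result.rhat = {
        p: float(v)
        for p, v in zip(model.param_names, gelman_rhat(draws))
    }
    worst = max(result.rhat.values())
    if worst >= RHAT_WARN_THRESHOLD:
        warnings.warn(
            f"convergence warning: max split R-hat {worst:.3f} >= {RHAT_WARN_THRESHOLD}",
            stacklevel=2,
        )
    return result


def _metropolis_gibbs(model, cfg: RunConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    m = cfg.n_chains
    theta = model.initial_values(rng, m)
    # cached posterior pieces; block updates recompute only what they change
    cur_base = model.base_part(theta)
    cur_re = model.re_part(theta)
    cur_g = model.glob_part(theta)
    if not (
        np.all(np.isfinite(cur_base))
        and np.all(np.isfinite(cur_re))
        and np.all(np.isfinite(cur_g))
    ):
        raise RuntimeError("non-finite log posterior at initialization")
    mu_affects_re = model.mu_affects_re
    scalars_affect_base = model.scalars_affect_base

    S = model.n_studies
    mu_idx = model.mu_indices
    delta_idx = model.delta_indices
    n_delta = len(delta_idx)
    slot_study = getattr(getattr(model, "arms", None), "slot_study", None)
    scalar_idx = np.asarray(model.scalar_indices, dtype=np.intp)

    ls_mu = np.full((m, S), np.log(0.5))
    ls_delta = np.full((m, n_delta), np.log(0.5))
    ls_scalar = np.full((m, len(scalar_idx)), np.log(0.2))
    ls_joint = np.zeros(m)
    joint = _JointAdapter(m, len(scalar_idx)) if len(scalar_idx) >= 2 else None
    ridge = getattr(model, "ridge_moves", [])
    ls_ridge = np.full((m, len(ridge)), np.log(0.5))
    target = 0.44
    if n_delta:
        # per-study joint proposals: lower target when several slots move together
        slots_per_study = np.bincount(slot_study, minlength=S)
        study_target = np.where(slots_per_study[slot_study] > 1, 0.3, 0.44)

    n_kept = cfg.n_kept
    draws = np.empty((m, n_kept, model.n_params))
    kept = 0
    total = cfg.burn_in + cfg.keep
    for t in range(total):
        adapting = t < cfg.burn_in
        gamma = min(0.5, 2.0 * (t + 1) ** -0.6) if adapting else 0.0

        # --- all study nuisances, accepted per study -----------------------
        prop = theta.copy()
        prop[:, mu_idx] += np.exp(ls_mu) * rng.standard_normal((m, S))
        pb = model.base_part(prop)
        dlp = pb - cur_base
        pre = None
        if mu_affects_re:
            pre = model.re_part(prop)
            dlp = dlp + pre - cur_re
        acc = np.log(rng.random((m, S))) < dlp
        theta[:, mu_idx] = np.where(acc, prop[:, mu_idx], theta[:, mu_idx])
        cur_base = np.where(acc, pb, cur_base)
        if pre is not None:
            cur_re = np.where(acc, pre, cur_re)
        if adapting:
            ls_mu += gamma * (acc - target)

        # --- all study relative effects, accepted per study ----------------
        if n_delta:
            prop = theta.copy()
            prop[:, delta_idx] += np.exp(ls_delta) * rng.standard_normal((m, n_delta))
            pb = model.base_part(prop)
            pre = model.re_part(prop)
            acc = np.log(rng.random((m, S))) < pb + pre - cur_base - cur_re
            acc_slot = acc[:, slot_study]
            theta[:, delta_idx] = np.where(acc_slot, prop[:, delta_idx], theta[:, delta_idx])
            cur_base = np.where(acc, pb, cur_base)
            cur_re = np.where(acc, pre, cur_re)
            if adapting:
                ls_delta += gamma * (acc_slot - study_target[None, :])

        def scalar_update(prop, extra_dlp=0.0):
            """Accept/reject a proposal that only moves scalar parameters."""
            nonlocal cur_base, cur_re, cur_g
            pre = model.re_part(prop)
            pg = model.glob_part(prop)
            dlp = (pre - cur_re).sum(axis=1) + pg - cur_g + extra_dlp
            pb = None
            if scalars_affect_base:
                pb = model.base_part(prop)
                dlp = dlp + (pb - cur_base).sum(axis=1)
            acc = np.log(rng.random(m)) < dlp
            accn = acc[:, None]
            cur_re = np.where(accn, pre, cur_re)
            cur_g = np.where(acc, pg, cur_g)
            if pb is not None:
                cur_base = np.where(accn, pb, cur_base)
            return acc

        # --- treatment / hyper / variance scalars, one at a time -----------
        for j, idx in enumerate(scalar_idx):
            prop = theta.copy()
            prop[:, idx] += np.exp(ls_scalar[:, j]) * rng.standard_normal(m)
            acc = scalar_update(prop)
            theta[:, idx] = np.where(acc, prop[:, idx], theta[:, idx])
            if adapting:
                ls_scalar[:, j] += gamma * (acc - target)

        # --- ridge moves ---------------------------------------------------
        # for Emax-type parameter blocks: shift log-ED50 and rescale Emax so
        # the effect at the agent's pivot dose is preserved (deterministic
        # map, Jacobian |dEmax'/dEmax| = c enters the acceptance ratio);
        # plain random walks cannot traverse this near-flat direction
        for j, (ie, il, pivot) in enumerate(ridge):
            # occasional long jumps traverse the ridge between the
            # data-supported region and the vague-prior tail
            stretch = np.where(rng.random(m) < 0.25, 5.0, 1.0)
            eta = stretch * np.exp(ls_ridge[:, j]) * rng.standard_normal(m)
            l0 = theta[:, il]
            logc = np.logaddexp(l0 + eta, np.log(pivot)) - np.logaddexp(
                l0, np.log(pivot)
            )
            prop = theta.copy()
            prop[:, il] = l0 + eta
            with np.errstate(over="ignore"):
                prop[:, ie] = theta[:, ie] * np.exp(logc)
            acc = scalar_update(prop, extra_dlp=logc)
            for col in (ie, il):
                theta[:, col] = np.where(acc, prop[:, col], theta[:, col])
            if adapting:
                ls_ridge[:, j] += gamma * (acc - target)

        # --- joint move over the scalar block ------------------------------
        # coordinate-wise proposals mix slowly along posterior ridges (e.g.
        # the Emax / log-ED50 correlation), so the scalars also get a joint
        # random-walk whose covariance is learned during burn-in
        if joint is not None:
            if adapting:
                joint.update(theta[:, scalar_idx])
            if joint.ready:
                if adapting and t % 25 == 0:
                    joint.refresh()
                for _ in range(2):
                    prop = theta.copy()
                    prop[:, scalar_idx] += np.exp(ls_joint)[:, None] * joint.propose(rng)
                    acc = scalar_update(prop)
                    theta[:, scalar_idx] = np.where(
                        acc[:, None], prop[:, scalar_idx], theta[:, scalar_idx]
                    )
                    if adapting:
                        ls_joint += gamma * (acc - 0.234)

        if not adapting and (t - cfg.burn_in) % cfg.thin == 0 and kept < n_kept:
            draws[:, kept, :] = theta
            kept += 1
    return draws


class _JointAdapter:
    """Per-chain running covariance of the scalar block (Welford update) and
    the scaled Cholesky factor used for joint random-walk proposals."""

    MIN_SAMPLES = 100

    def __init__(self, n_chains, k):
        self.m, self.k = n_chains, k
        self.count = 0
        self.mean = np.zeros((n_chains, k))
        self.m2 = np.zeros((n_chains, k, k))
        self._chol = None

    def update(self, x):
        self.count += 1
        d1 = x - self.mean
        self.mean += d1 / self.count
        d2 = x - self.mean
        self.m2 += np.einsum("mi,mj->mij", d1, d2)

    @property
    def ready(self):
        if self.count < self.MIN_SAMPLES:
            return False
        if self._chol is None:
            self.refresh()
        return self._chol is not None

    def refresh(self):
        cov = self.m2 / max(self.count - 1, 1)
        cov = cov + 1e-8 * np.eye(self.k)
        scale = 2.38**2 / self.k
        try:
            self._chol = np.linalg.cholesky(scale * cov)
        except np.linalg.LinAlgError:
            self._chol = None

    def propose(self, rng):
        z = rng.standard_normal((self.m, self.k))
        return np.einsum("mij,mj->mi", self._chol, z)


def _ensemble(model, cfg: RunConfig) -> np.ndarray:
    import emcee

    d = model.n_params
    n_walkers = max(2 * d + 2, 4 * cfg.n_chains)
    n_walkers += n_walkers % 2
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    p0 = model.initial_values(rng, n_walkers)
    sampler = emcee.EnsembleSampler(n_walkers, d, model.log_posterior, vectorize=True)
    sampler.random_state = np.random.RandomState(cfg.seed % (2**31)).get_state()
    burn_steps = max(1, cfg.burn_in)
    state = sampler.run_mcmc(p0, burn_steps, skip_initial_state_check=True)
    sampler.reset()
    sampler.run_mcmc(state, cfg.n_kept, thin_by=cfg.thin, skip_initial_state_check=True)
    chain = sampler.get_chain()  # (steps, walkers, d)
    # fold walkers into cfg.n_chains pseudo-chains for diagnostics
    steps = chain.shape[0]
    per = n_walkers // cfg.n_chains
    groups = [
        chain[:, c * per : (c + 1) * per, :].reshape(steps * per, d)
        for c in range(cfg.n_chains)
    ]
    k = min(g.shape[0] for g in groups)
    return np.stack([g[:k] for g in groups], axis=0)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor, floored at 1.

    ``draws`` is (n_chains, n_iter) or (n_chains, n_iter, n_params); each
    chain is split in half, and R-hat = sqrt(V-hat / W) with V-hat the
    weighted within/between variance estimate. Identical chains (or constant
    draws) give exactly 1. R-hat below 1 is finite-sample noise with no
    diagnostic meaning, hence the floor.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        return gelman_rhat(draws[:, :, None])[0]
    c, n, d = draws.shape
    if c < 2:
        raise ValueError("R-hat needs at least 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split for R-hat")
    split = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    w = split.var(axis=1, ddof=1).mean(axis=0)  # within-chain
    b = split.mean(axis=1).var(axis=0, ddof=1)  # between-chain (variance of means)
    vhat = (half - 1) / half * w + b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(vhat / w)
    r = np.where(w > 0, r, 1.0)
    return np.maximum(r, 1.0)


def effective_sample_size(chains: np.ndarray) -> float:
    """Pooled effective sample size via Geyer's initial monotone sequence."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    c, n = chains.shape
    if n < 4:
        return float(c * n)
    x = chains - chains.mean(axis=1, keepdims=True)
    # FFT autocovariance per chain, averaged
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    var0 = acov[:, 0].mean()
    if var0 == 0:
        return float(c * n)
    rho = acov.mean(axis=0) / var0
    # Geyer: sum consecutive pairs while positive and non-increasing
    tau = 1.0
    prev = np.inf
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
    return float(max(c * n / tau, 1.0))


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def default_transforms(param_names) -> dict:
    """Back-transform log-scale dose parameters: log_ed50[...] -> ed50[...]."""
    out = {}
    for p in param_names:
        if p.startswith("log_ed50") or p.startswith("mu_log_ed50"):
            out[p] = (p.replace("log_ed50", "ed50"), np.exp)
    return out


def summarize(fit_result: FitResult, transforms: dict | None = None) -> pd.DataFrame:
    """Median and equal-tailed 95% credible interval per parameter.

    ``transforms`` maps parameter name -> (reported name, draw-wise callable);
    transforms are applied to the draws before taking quantiles, so monotone
    transforms commute with the reported quantiles. By default log-ED50
    parameters are also reported as ED50 on the natural scale.
    """
    if transforms is None:
        transforms = default_transforms(fit_result.param_names)
    rows = []
    for p in fit_result.param_names:
        x = fit_result.get(p)
        rows.append(_quantile_row(p, x, fit_result.rhat.get(p)))
        if p in transforms:
            new_name, fn = transforms[p]
            rows.append(_quantile_row(new_name, fn(x), fit_result.rhat.get(p)))
    return pd.DataFrame(rows, columns=["parameter", "median", "lower", "upper", "rhat"])


def _quantile_row(name, x, rhat):
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return {"parameter": name, "median": med, "lower": lo, "upper": hi, "rhat": rhat}


def trace_data(fit_result: FitResult, names=None) -> pd.DataFrame:
    """Long-format draw table for external trace plots (chain, iteration, value)."""
    names = names or fit_result.param_names
    frames = []
    for p in names:
        ch = fit_result.chains(p)
        c, k = ch.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": p,
                    "chain": np.repeat(np.arange(c), k),
                    "iteration": np.tile(np.arange(k), c),
                    "value": ch.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
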