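# Methods

## The model

`mbnma` synthesizes arm-level evidence from randomized trials comparing
several agents, each at one or more doses, against a common (usually placebo)
reference. For a binary endpoint, arm k of study i contributes

    r_ik ~ Binomial(n_ik, p_ik)
    logit(p_ik) = mu_i             k = 1 (reference arm)
    logit(p_ik) = mu_i + delta_ik  k >= 2

The study baseline mu_i is always an independent, vaguely-distributed
nuisance parameter (N(0, 1000)), never a random effect, so that every
comparison remains anchored to its own concurrent control; putting a random
effect on baselines can bias relative effects when arm sizes are unbalanced.

The model families differ only in the mean structure of delta_ik:

* **Lumped NMA** — all doses of an agent share one node; s coded treatments
  give s − 1 basic parameters d, and every contrast is a difference of basic
  parameters (consistency by construction). When lumping makes two arms of a
  study identical, their within-agent relative effect is fixed to zero; such
  studies still inform heterogeneity.
* **Split NMA** — each (agent, standardized dose) pair is its own node.
* **MBNMA** — the consistency equations are applied at the level of a
  parametric dose-response curve: delta_ik has mean
  f(x_ik, t_ik) − f(x_i1, t_i1). Shipped forms: Emax
  (f = Emax_t · x / (ED50_t + x), ED50 sampled as log ED50 because a dose is
  positive; Emax unconstrained in sign), linear without intercept
  (f = d_t · x), linear with a per-agent intercept (f = b_t + d_t · x; the
  intercept exists only for active agents and represents non-linearity as
  the dose falls to zero). Any user-registered f with the same contract
  drops in unchanged.
* **UME** — one free mean per treatment pair compared head-to-head in at
  least one study; no consistency constraints; used only to probe
  inconsistency.

**Class effects (Emax only).** Emax_t and/or log ED50_t can be exchangeable
across agents, Emax_t ~ N(mu_Emax, sigma_Emax²) etc., borrowing strength when
the dose range is too poor to identify every agent's curve. Class means get
N(0, 1000) priors (the same vague treatment as other location parameters —
the choice was open); class SDs get uniform(0, 4) priors, except
uniform(0, 20) for sigma_Emax, which is otherwise prone to collapse.

**Random effects.** Between-study heterogeneity sits on delta (the outcome
scale), never on the dose-response parameters themselves — heterogeneity on
Emax/ED50 is known to cause identification trouble and complicates multi-arm
trials. One sigma is shared by all comparisons. The a − 1 relative effects
of an a-arm study are exchangeable multivariate normal with Var sigma² and
Cov sigma²/2, realized by sequential univariate conditionals: position j
(counting arms from 2) has conditional mean
d_j + (1/(j−1)) Σ_{h<j}(delta_h − d_h) and conditional variance
sigma²·j/(2(j−1)). A unit test verifies this equals the joint multivariate
normal density to 10⁻⁸.

**Placebo model.** Absolute predictions need a baseline. A separate model
fits mu_i ~ N(m, s²) to the placebo arms of placebo-controlled studies only.
It shares no parameters with any relative-effect model, so running it cannot
perturb the relative effects. It requires placebo arms in at least two
studies (s is unidentifiable from one).

**Prediction.** Response at (agent, dose) is the draw-wise inverse logit of
(anchor + f(x, t)). `typical_trial` anchors at draws of m (the mean of the
placebo distribution); `new_trial` additionally draws a study effect from
N(m, s²), widening intervals into prediction intervals. The two posteriors
are independent by construction and combined draw-by-draw; if their draw
counts differ the longer set is subsampled with a fixed seed. Doses beyond
an agent's maximum trialed standardized dose are allowed but flagged
`extrapolated`. A lumped NMA yields dose-constant predictions; a split NMA
predicts only at trialed doses.

## Priors and defaults

| parameter | prior | note |
|---|---|---|
| basic effects d, Emax, log ED50, b, slopes | N(0, 1000) | vague, log-odds scale |
| study nuisances mu_i | N(0, 1000) | independent per study |
| between-study SD sigma | uniform(0, 4) | half-normal(precision 100) available as a sensitivity option |
| class SDs | uniform(0, 4); uniform(0, 20) for sigma_Emax | |
| placebo-model m, s | N(0, 1000), uniform(0, 4) | |

Dose standardization happens at load time: dose_std = dose / common_dose per
agent (placebo is pinned at 0), so all dose-response parameters are in
common-dose multiples and comparable across agents. An empty common-dose
table declares the doses already standardized.

## Estimation

Runs use 3 independent chains, 40,000 kept iterations after 40,000 burn-in,
thinning 10, by default; a reduced preset (3 × 2000/2000, thin 1) serves
tests and simulation studies. The sampling contract is distributional — any
correct sampler is acceptable — and two backends are shipped:

* **Blocked adaptive Metropolis-within-Gibbs** (default, pure NumPy). Study
  nuisances and study relative effects are proposed for all studies at once
  and accepted per study (their conditionals factorize over studies);
  treatment-level, hyper and variance parameters are updated singly.
  Proposal scales adapt by Robbins-Monro (target acceptance 0.44, 0.3 for
  multi-slot study blocks, 0.234 for the joint move) during burn-in only, so
  the post-burn-in chain is Markovian. Two extra moves handle correlated
  posteriors: a joint random walk over the scalar block whose covariance is
  learned online during burn-in, and — for Emax models — per-agent "ridge"
  moves that shift log ED50 while rescaling Emax to preserve the effect at a
  pivot dose (the agent's lowest and highest trialed doses; the Jacobian of
  the deterministic rescaling enters the acceptance ratio). The ridge moves
  matter: the Emax likelihood is nearly flat along Emax, ED50 → ∞ with
  Emax/ED50 fixed, and plain random walks mix very slowly along it.
* **Ensemble** (`emcee`), used as an independent cross-check; a property
  test asserts both backends agree on posterior medians within 3 combined
  Monte Carlo standard errors.

Initial values are data-informed and overdispersed: baselines and relative
effects start at empirical logits/log-odds-ratios plus per-chain N(0, 0.5²)
jitter, SDs uniform in (0.1, 0.6). (Pure prior draws, even truncated, start
so far from the data under N(0, 1000) priors that they waste most of a short
burn-in.) All randomness derives from one master seed; identical seed,
configuration and backend reproduce draws bit-for-bit.

Convergence is monitored by split-chain R-hat (each chain halved, floored at
1 since values below 1 are noise), with a warning threshold of 1.05, plus
`trace_data()` for visual inspection. Effective sample sizes use Geyer's
initial monotone sequence estimator.

## Model criticism

Residual deviance per arm compares fitted with saturated binomial
likelihoods, with the 0·log 0 := 0 convention at boundary counts; a fitted
probability of exactly 0 or 1 is an error (degenerate fit), and clipping is
floating-point safety only (10⁻³⁰⁰). An adequate model contributes about 1
per data point, so Dbar/n near 1 indicates calibration. The effective number
of parameters uses the plug-in method, pD = Dbar − D(posterior-mean fit),
because default pD estimates of general MCMC software are unreliable for
non-linear models; the plug-in point is the posterior mean on the
probability scale (it pairs directly with the binomial deviance; the
linear-predictor scale is exposed as an option). Negative pD triggers a
warning, never silent acceptance. DIC = Dbar + pD; differences of three or
more between models on the same data are treated as meaningful, and
`compare_models` flags smaller gaps as not meaningful.

**Inconsistency screen.** The data are refitted with the UME model and the
per-point deviance contributions and sigma posteriors are paired. Points
with clearly larger contributions under the consistency model are local
inconsistency candidates. The qualitative flag raises when the UME sigma
median falls below 0.75 × the consistency-model sigma median. The margin is
a deliberate design choice: under consistent data the two sigma posteriors
estimate the same quantity, so a raw median comparison flags in about half
of datasets; requiring a 25% undercut keeps false flags rare while a
one-log-odds bias on a loop edge (which inflates the consistency sigma well
beyond that margin) is still detected essentially always. The threshold is
exposed as an argument.

**VPC.** For each arm the posterior predictive of r/n is simulated (study
baselines from their own draws; relative effects redrawn from
N(mean, sigma²) under random effects — the correct marginal of the
correlated multi-arm scheme; binomial sampling on top) and summarized as a
plot-ready table of observed value, predictive median and 95% interval.

## The synthetic-data generator

The generator runs the random-effects binomial MBNMA forward, so model and
generator share one definition of truth. Defaults emulate a typical
dose-ranging network of the kind the method targets (a seven-agent migraine
network is the canonical shape): one placebo hub carrying most evidence,
agents at 1–4 standardized doses in [0.25, 4], a minority of three-arm and
active–active trials (15% each) so multi-arm correlation and indirect
evidence are exercised, Emax truth, sigma 0.25, placebo log-odds
N(−1.5, 0.3²) (response around 18%), and arms of 150–200 patients. Studies
whose reference arm is active draw their baseline around m + f(x_ref) so
active-controlled trials have realistic baselines; since every fitted model
treats baselines as free nuisances, this affects no modelled quantity. The
layout guarantees each agent–dose combination at least one placebo-controlled
trial, which also guarantees a connected network. `inject_inconsistency`
regenerates only the studies on one loop edge with a log-odds offset added
to that edge's relative effect, leaving everything else byte-identical.

What the generator does not emulate: real networks have unbalanced arm
sizes, correlated design choices (doses chosen by earlier trials), sparse
placebo coverage for some agents, outcome misclassification and publication
bias. Passing recovery tests therefore shows the estimator is correct under
its own assumptions, not that those assumptions hold in any particular
literature.

## Problem sizes in the shipped checks

The acceptance-style checks run at sizes chosen to make their statistical
assertions sharp: parameter recovery uses 20 replicates of a 40-study,
4-agent Emax network with 200 patients per arm at the reduced run length;
the convergence contract uses one default-length run on the same fixture;
the inconsistency screen uses 10 studies per loop edge with 500 patients per
arm (sigma posteriors from fewer studies are too noisy for a reliable
median comparison either way). The sampler-equivalence and closed-form
checks run on one- and two-study networks where oracles are exact.

## Known limitations

* Only the binomial-logit likelihood is implemented; the linear-predictor
  machinery is link-generic, but other likelihoods would need a new arm
  structure.
* With vague priors and a narrow dose range, Emax and ED50 are only weakly
  identified; posteriors honestly show long ridge tails (ED50 far above the
  trialed range with proportionally inflated Emax). Class effects are the
  intended remedy, exactly as in practice.
* No node-splitting; the UME screen is global, not per-contrast.
* No meta-regression, time-course models, or continuous outcomes.
* The UME model cannot generate predictions (it has no consistent relative
  effects), and a split NMA predicts only at trialed doses.
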