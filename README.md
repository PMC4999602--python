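# mbnma — model-based network meta-analysis

Network meta-analysis (NMA) synthesizes randomized trials comparing many
treatments into one coherent set of relative effects, but it usually treats
the doses of a drug either as interchangeable ("lumped") or as unrelated
treatments ("split"). Model-based network meta-analysis (MBNMA) instead
embeds a parametric dose-response curve inside the NMA consistency
equations, so trials of many agents at many doses jointly estimate each
agent's curve — and support prediction at doses never trialed. `mbnma` is
for biostatisticians and pharmacometricians doing evidence synthesis of
dose-ranging trial networks (drug development, reimbursement comparisons).

For a binary endpoint, arm k of study i is modelled as

    r_ik ~ Binomial(n_ik, p_ik),   logit(p_ik) = mu_i + delta_ik   (delta_i1 = 0)

with study baselines mu_i as independent vague nuisances (concurrent control
is never broken). The relative effect of arm k vs arm 1 has mean

    f(x_ik, t_ik) − f(x_i1, t_i1)

for a dose-response function f — Emax: `f = Emax_t · x / (ED50_t + x)` —
evaluated at standardized doses x (multiples of each agent's common dose),
with placebo pinned at f = 0. Because every contrast is a difference of the
same curves, consistency of direct and indirect evidence holds by
construction. Random-effects versions give each study's relative effects an
exchangeable multivariate normal (variance σ², covariance σ²/2 for
multi-arm trials) with a single between-study σ. Emax and/or log-ED50 can
be made exchangeable across agents ("class effects") to borrow strength
when the trialed dose range alone cannot identify every curve. Classical
lumped/split NMA, the unrelated-mean-effects (UME) inconsistency model, a
separate placebo random-effects model for absolute predictions, and
plug-in-DIC model criticism are all included. See `docs/methods.md` for the
full model description, priors, sampler and design choices.

## Worked example

Simulate a 40-study network (4 agents + placebo, Emax truth with
Emax = 1.0/1.5/2.0/2.5, ED50 = 1 common dose, σ = 0.25, 200 patients per
arm), fit the Emax MBNMA with an exchangeable ED50, and predict:

```python
import mbnma as mb

truth = mb.TruthSpec(n_studies=40, sample_size=200, seed=7)
net, record = mb.simulate_network(truth)

spec = mb.ModelSpec(family="mbnma", dose_model="emax", effect="random",
                    class_effects={"ed50_exchangeable"})
fit = mb.fit(mb.build_mbnma(net, spec), mb.RunConfig.reduced(seed=1))
print(fit.summary())                      # medians + 95% CrIs, ED50 on natural scale

rep = mb.deviance_report(fit)             # residual deviance / plug-in DIC
pfit = mb.fit(mb.build_placebo_re(net), mb.RunConfig.reduced(seed=1))
pred = mb.predict(fit, pfit, {"C": [0.5, 1, 2, 4, 8]}, mode="typical_trial")
```

Output (abridged):

```
parameter  median  lower  upper   rhat
  emax[C]   2.045  1.584  2.581  1.028     # truth 2.0
  ed50[C]   0.812  0.311  1.558  1.038     # truth 1.0
    sigma   0.099  0.031  0.218  1.068

Dbar = 80.7 over 82 data points (~0.98 each), pD = 53.8, DIC = 134.4

agent  dose_std  median  lower  upper          mode  extrapolated
    C     0.500   0.326  0.281  0.387 typical_trial         False
    C     1.000   0.405  0.358  0.459 typical_trial         False
    C     2.000   0.483  0.438  0.534 typical_trial         False
    C     4.000   0.545  0.478  0.606 typical_trial         False
    C     8.000   0.585  0.497  0.666 typical_trial          True
```

Each data point contributes ≈ 1 to the residual deviance (adequate fit);
the predictions are absolute response probabilities for a typical trial,
anchored on the separately fitted placebo mean (posterior median −1.51
log-odds here, truth −1.5), with the never-trialed dose 8 flagged as
extrapolation. Emax parameters are log-odds ratios vs placebo; ED50 is in
common-dose multiples.

The same pipeline is scriptable from a shell:

```
mbnma simulate -c truth.yaml -o simdir
mbnma fit -d simdir/data.csv -c model.yaml -o fitdir
mbnma predict -f fitdir -c grid.yaml
mbnma check -d simdir/data.csv -c model.yaml -o checkdir   # UME screen
```

Real data load the same way: a delimited file with columns
`study, agent, dose, responders, sample_size` plus a common-dose table
(`mb.read_long_format("trials.csv", {"sumatriptan": 50.0, ...})`).

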