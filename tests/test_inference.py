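import warnings

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.special import expit

import mbnma as mb
from mbnma.inference import effective_sample_size, gelman_rhat

from conftest import make_arm


class TestRunConfig:
    def test_defaults(self):
        cfg = mb.RunConfig()
        assert (cfg.n_chains, cfg.burn_in, cfg.keep, cfg.thin) == (3, 40000, 40000, 10)

    def test_retained_draws_bookkeeping(self, two_arm_net):
        """Retained draws per chain equal keep // thin exactly."""
        cfg = mb.RunConfig(n_chains=2, burn_in=200, keep=900, thin=3, seed=1)
        model = mb.build_nma(two_arm_net, mb.ModelSpec(family="nma_split", effect="fixed"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mb.fit(model, cfg)
        assert fit.draws.shape == (2, 300, model.n_params)

    def test_short_keep_warns(self):
        with pytest.warns(UserWarning, match="100 retained"):
            mb.RunConfig(n_chains=2, burn_in=10, keep=50, thin=1)


class TestGelmanRhat:
    def test_identical_chains_give_exactly_one(self):
        x = np.random.default_rng(0).normal(size=500)
        draws = np.stack([x, x, x])
        assert gelman_rhat(draws) == 1.0

    def test_offset_chains_blow_up(self):
        """Two chains offset by a large constant: R-hat far above 1.1, and it
        matches the closed-form split-R-hat computed by hand."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 400)
        b = a + 50.0
        got = gelman_rhat(np.stack([a, b]))
        assert got > 10
        # independent closed form on the same four split halves
        halves = np.array([a[:200], a[200:], b[:200], b[200:]])
        w = halves.var(axis=1, ddof=1).mean()
        bvar = halves.mean(axis=1).var(ddof=1)
        want = np.sqrt((199 / 200 * w + bvar) / w)
        assert got == pytest.approx(want)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rhat(np.zeros((1, 100)))

    def test_floor_at_one(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 2000))
        assert gelman_rhat(draws) >= 1.0


class TestFitContract:
    def test_same_seed_same_draws(self, two_arm_net, quick_cfg):
        model = mb.build_nma(two_arm_net, mb.ModelSpec(family="nma_split", effect="fixed"))
        f1 = mb.fit(model, quick_cfg)
        f2 = mb.fit(model, quick_cfg)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_posterior_matches_numeric_integration(self, two_arm_net):
        """Fixed-effect fit of one 30/100-style arm: posterior mean of the
        reference-arm probability agrees with 2-D quadrature to 0.02."""
        arms = [
            make_arm("q1", "placebo", 0.0, 30, 100),
            make_arm("q1", "A", 1.0, 45, 100),
        ]
        net = mb.build_network(arms, {"A": 1.0})
        model = mb.build_nma(net, mb.ModelSpec(family="nma_split", effect="fixed"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mb.fit(model, mb.RunConfig.reduced(seed=9))
        p_mc = expit(fit.get("mu[q1]")).mean()

        sd = np.sqrt(1000.0)

        def post(mu, d):
            like = (
                expit(mu) ** 30 * (1 - expit(mu)) ** 70
                * expit(mu + d) ** 45 * (1 - expit(mu + d)) ** 55
            )
            prior = np.exp(-0.5 * (mu**2 + d**2) / sd**2)
            return like * prior

        z, _ = dblquad(lambda d, mu: post(mu, d), -4, 3, -4, 4)
        num, _ = dblquad(lambda d, mu: expit(mu) * post(mu, d), -4, 3, -4, 4)
        assert p_mc == pytest.approx(num / z, abs=0.02)

    def test_fixed_effect_recovers_simulated_truth(self):
        """20-study fixed-effect network, true d = 0.7: posterior median lands
        within 3 posterior SDs of the truth."""
        truth = mb.TruthSpec(
            agents=("A",),
            dose_model="linear",
            params={"A": (0.7,)},
            sigma=0.0,
            placebo_sd=0.3,
            n_studies=20,
            doses=(1.0,),
            sample_size=150,
            seed=21,
        )
        net, _ = mb.simulate_network(truth)
        model = mb.build_nma(net, mb.ModelSpec(family="nma_split", effect="fixed"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mb.fit(model, mb.RunConfig.reduced(seed=2))
        d = fit.get("d[A@1]")
        assert abs(np.median(d) - 0.7) < 3 * d.std()

    def test_sampler_backends_agree(self, two_arm_net):
        """Gibbs and ensemble backends agree on posterior medians within 3
        combined Monte Carlo standard errors (distributional contract)."""
        model = mb.build_nma(two_arm_net, mb.ModelSpec(family="nma_split", effect="fixed"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = mb.fit(model, mb.RunConfig(n_chains=3, burn_in=3000, keep=6000, thin=2, seed=3))
            f2 = mb.fit(
                model,
                mb.RunConfig(n_chains=3, burn_in=500, keep=1500, thin=2, seed=3),
                sampler="ensemble",
            )
        for p in model.param_names:
            m1, m2 = np.median(f1.get(p)), np.median(f2.get(p))
            tol = 3 * np.hypot(f1.mcse(p), f2.mcse(p))
            assert abs(m1 - m2) < max(tol, 0.02), p

    def test_unknown_backend(self, two_arm_net, quick_cfg):
        model = mb.build_nma(two_arm_net, mb.ModelSpec(family="nma_split", effect="fixed"))
        with pytest.raises(ValueError, match="backend"):
            mb.fit(model, quick_cfg, sampler="nuts")


class TestSummaries:
    def test_monotone_transform_commutes_with_quantiles(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        # exact at order statistics (monotone map preserves ranks) ...
        q = np.quantile(np.exp(x), [0.025, 0.5, 0.975], method="lower")
        np.testing.assert_array_equal(
            q, np.exp(np.quantile(x, [0.025, 0.5, 0.975], method="lower"))
        )
        # ... and to interpolation accuracy with the default method
        q_lin = np.quantile(np.exp(x), [0.025, 0.5, 0.975])
        np.testing.assert_allclose(
            q_lin, np.exp(np.quantile(x, [0.025, 0.5, 0.975])), rtol=1e-3
        )

    def test_ed50_back_transformed(self, emax_fit_session):
        *_, fit = emax_fit_session
        tbl = fit.summary().set_index("parameter")
        led = tbl.loc["log_ed50[A]"]
        nat = tbl.loc["ed50[A]"]
        assert nat["median"] == pytest.approx(np.exp(led["median"]))
        assert nat["lower"] > 0

    def test_constant_log_ed50_summary(self, emax_fit_session):
        """All-zero log-ED50 draws summarize to ED50 = 1 (1-1)."""
        *_, fit = emax_fit_session
        import copy

        f2 = copy.copy(fit)
        f2.draws = fit.draws.copy()
        j = fit.param_names.index("log_ed50[A]")
        f2.draws[:, :, j] = 0.0
        row = f2.summary().set_index("parameter").loc["ed50[A]"]
        assert (row["lower"], row["median"], row["upper"]) == (1.0, 1.0, 1.0)

    def test_interval_ordering(self, emax_fit_session):
        *_, fit = emax_fit_session
        tbl = fit.summary()
        assert (tbl["lower"] <= tbl["median"]).all()
        assert (tbl["median"] <= tbl["upper"]).all()

    def test_trace_data_long_format(self, emax_fit_session):
        *_, fit = emax_fit_session
        df = mb.trace_data(fit, names=["sigma"])
        assert set(df.columns) == {"parameter", "chain", "iteration", "value"}
        assert len(df) == fit.draws.shape[0] * fit.draws.shape[1]


class TestESS:
    def test_iid_draws_near_nominal(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(4, 2000))
        ess = effective_sample_size(chains)
        assert 0.5 * 8000 < ess <= 8000 * 1.5

    def test_correlated_chain_shrinks(self):
        rng = np.random.default_rng(5)
        x = np.zeros((2, 4000))
        for t in range(1, 4000):
            x[:, t] = 0.95 * x[:, t - 1] + rng.normal(size=2)
        assert effective_sample_size(x) < 1500
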