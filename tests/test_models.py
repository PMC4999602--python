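import numpy as np
import pytest
from scipy.stats import multivariate_normal

import mbnma as mb
from mbnma.models import ModelSpec, sequential_logpdf, multiarm_covariance

from conftest import make_arm


class TestMultiArmScheme:
    def test_two_arm_reduces_to_plain_normal(self):
        from scipy.stats import norm

        got = sequential_logpdf(np.array([0.4]), np.array([0.1]), sigma=0.7)
        assert got == pytest.approx(norm.logpdf(0.4, 0.1, 0.7))

    def test_three_arm_second_conditional_variance(self):
        """Second relative effect of a 3-arm study has conditional variance
        sigma^2 * 3/4 — verified against direct 2x2 covariance inversion."""
        sigma = 1.0
        cov = multiarm_covariance(2, sigma)
        v_cond = cov[1, 1] - cov[1, 0] ** 2 / cov[0, 0]
        assert v_cond == pytest.approx(0.75)
        assert sigma**2 * 3 / (2 * 2) == pytest.approx(v_cond)

    @pytest.mark.parametrize("q", [2, 3])
    def test_matches_multivariate_normal_oracle(self, q):
        """Sequential-conditional joint density == MVN density (Var sigma^2,
        Cov sigma^2/2) on random draws, to 1e-8."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            sigma = rng.uniform(0.2, 2.0)
            means = rng.normal(0, 1, q)
            delta = rng.normal(0, 2, q)
            want = multivariate_normal.logpdf(delta, means, multiarm_covariance(q, sigma))
            got = sequential_logpdf(delta, means, sigma)
            assert got == pytest.approx(want, abs=1e-8)


class TestNMA:
    def test_contrasts_from_basic_parameters(self, small_net):
        model = mb.build_nma(
            mb.to_lumped(small_net), ModelSpec(family="nma_lumped", effect="fixed")
        )
        theta = np.zeros((1, model.n_params))
        theta[0, model.param_names.index("d[A]")] = 0.4
        theta[0, model.param_names.index("d[B]")] = 1.0
        assert model.contrast(theta, "A", "B")[0] == pytest.approx(0.6)

    def test_basic_parameter_count(self):
        truth = mb.triptan_like_truth(seed=4)
        net, _ = mb.simulate_network(truth, seed=4)
        model = mb.build_nma(net, ModelSpec(family="nma_lumped", effect="fixed"))
        assert len(model.basic_parameters()) == len(net.agents) - 1

    def test_lumped_within_agent_delta_constrained_to_zero(self):
        """Arms coded like the reference under lumping get no relative effect."""
        arms = [
            make_arm("s1", "placebo", 0, 5, 30),
            make_arm("s1", "A", 1.0, 10, 30),
            make_arm("s1", "A", 2.0, 12, 30),
        ]
        net = mb.to_lumped(mb.build_network(arms))
        model = mb.build_nma(net, ModelSpec(family="nma_lumped", effect="random"))
        # one slot (A vs placebo); the two A arms share it
        assert model.arms.n_slots == 1
        assert list(model.arms.arm_slot) == [-1, 0, 0]
        # non-placebo study whose both arms are the same lumped agent
        arms2 = [
            make_arm("s2", "A", 1.0, 10, 30),
            make_arm("s2", "A", 2.0, 12, 30),
        ] + arms
        net2 = mb.to_lumped(mb.build_network(arms2))
        model2 = mb.build_nma(net2, ModelSpec(family="nma_lumped", effect="random"))
        s2_slots = [
            s
            for s, st in zip(model2.arms.arm_slot, model2.arms.arm_study)
            if model2.arms.study_ids[st] == "s2"
        ]
        assert s2_slots == [-1, -1]

    def test_disconnected_network_rejected_with_components(self):
        arms = [
            make_arm("s1", "placebo", 0, 5, 20),
            make_arm("s1", "A", 1.0, 8, 20),
            make_arm("s2", "B", 1.0, 8, 20),
            make_arm("s2", "C", 1.0, 9, 20),
        ]
        net = mb.build_network(arms)
        with pytest.raises(ValueError, match="disconnected"):
            mb.build_nma(net, ModelSpec(family="nma_split", effect="fixed"))


class TestMBNMA:
    def test_fixed_effect_linear_predictor_composition(self, two_arm_net):
        """logit(p) of the active arm is mu + f(x) under a fixed-effect fit."""
        model = mb.build_mbnma(
            two_arm_net, ModelSpec(family="mbnma", dose_model="emax", effect="fixed")
        )
        theta = np.zeros((1, model.n_params))
        theta[0, model.param_names.index("mu[t1]")] = -1.0
        theta[0, model.param_names.index("emax[A]")] = 2.0
        theta[0, model.param_names.index("log_ed50[A]")] = 0.0
        from scipy.special import expit

        probs = model.fitted_probs(theta)[0]
        assert probs[0] == pytest.approx(expit(-1.0))
        assert probs[1] == pytest.approx(expit(-1.0 + mb.emax_f(1.0, 2.0, 0.0)))

    def test_class_effect_parameters_present(self, small_net):
        spec = ModelSpec(
            family="mbnma",
            dose_model="emax",
            effect="random",
            class_effects={"emax_exchangeable", "ed50_exchangeable"},
        )
        model = mb.build_mbnma(small_net, spec)
        for p in ("mu_emax", "sigma_emax", "mu_log_ed50", "sigma_log_ed50"):
            assert p in model.param_names
        # 2 class means + 2 class SDs + 2 agents x 2 params + sigma
        n_scalars = len(model.scalar_indices)
        assert n_scalars == 4 + 4 + 1

    def test_class_effect_needs_two_agents(self, two_arm_net):
        spec = ModelSpec(
            family="mbnma", dose_model="emax", class_effects={"ed50_exchangeable"}
        )
        with pytest.raises(ValueError, match="2 active agents"):
            mb.build_mbnma(two_arm_net, spec)

    def test_class_effects_require_emax_model(self):
        with pytest.raises(ValueError, match="not supported"):
            ModelSpec(family="mbnma", dose_model="linear", class_effects={"emax_exchangeable"})


class TestUME:
    def test_loop_has_three_free_means(self, small_net):
        """Loop A-B, A-P, B-P: 3 UME means vs 2 basic NMA parameters."""
        lumped = mb.to_lumped(small_net)
        ume = mb.build_ume(lumped, ModelSpec(family="ume", effect="random"))
        # small_net has A at two doses -> use lumped coding via agent-level net
        # pairs: P-A, P-B, A-B
        nma = mb.build_nma(lumped, ModelSpec(family="nma_lumped", effect="random"))
        assert len(ume.treat_names) == 3
        assert len(nma.basic_parameters()) == 2

    def test_never_compared_pairs_get_no_parameter(self):
        arms = [
            make_arm("s1", "placebo", 0, 5, 20),
            make_arm("s1", "A", 1.0, 8, 20),
            make_arm("s2", "placebo", 0, 5, 20),
            make_arm("s2", "B", 1.0, 9, 20),
        ]
        net = mb.build_network(arms)
        ume = mb.build_ume(net, ModelSpec(family="ume", effect="fixed"))
        assert len(ume.treat_names) == 2  # P-A and P-B only, no A-B

    def test_multiarm_contributes_each_observed_contrast(self, small_net):
        ume = mb.build_ume(small_net, ModelSpec(family="ume", effect="random"))
        s3_slots = [
            s
            for s, st in zip(ume.arms.arm_slot, ume.arms.arm_study)
            if ume.arms.study_ids[st] == "s3" and s >= 0
        ]
        assert len(s3_slots) == 2  # A@1 and B@1 vs the placebo reference


class TestPlaceboRE:
    def test_single_placebo_study_rejected(self, two_arm_net):
        with pytest.raises(ValueError, match=">= 2 studies"):
            mb.build_placebo_re(two_arm_net)

    def test_no_shared_parameters_with_relative_effect_model(self, small_net):
        """Separation preserves concurrent control: the placebo model and the
        MBNMA share no parameters by construction."""
        pmodel = mb.build_placebo_re(small_net)
        model = mb.build_mbnma(small_net, ModelSpec(family="mbnma", dose_model="emax"))
        placebo_scalars = {pmodel.param_names[i] for i in pmodel.scalar_indices}
        mbnma_scalars = {model.param_names[i] for i in model.scalar_indices}
        assert placebo_scalars == {"m", "s"}
        assert placebo_scalars.isdisjoint(mbnma_scalars)
        # each model owns its nuisances; nothing is shared state
        assert pmodel is not model

    def test_half_probability_data_center_near_zero(self, quick_cfg):
        """Placebo arms at r/n = 1/2 with large n concentrate m near 0 log-odds."""
        arms = []
        for i in range(6):
            arms += [
                make_arm(f"p{i}", "placebo", 0, 500, 1000),
                make_arm(f"p{i}", "A", 1.0, 600, 1000),
            ]
        net = mb.build_network(arms)
        pmodel = mb.build_placebo_re(net)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = mb.fit(pmodel, mb.RunConfig.reduced(seed=3))
        assert abs(np.median(fit.get("m"))) < 0.1


class TestSpecSerialization:
    def test_model_spec_round_trip(self):
        spec = ModelSpec(
            family="mbnma",
            dose_model="emax",
            effect="random",
            class_effects={"ed50_exchangeable"},
        )
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_invalid_family(self):
        with pytest.raises(ValueError, match="unknown family"):
            ModelSpec(family="meta_regression")

    def test_ume_takes_no_dose_model(self):
        with pytest.raises(ValueError, match="no dose model"):
            ModelSpec(family="ume", dose_model="emax")
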