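import numpy as np
import pytest

import mbnma as mb


def make_arm(study, agent, dose, r, n):
    return mb.Arm(
        study_id=study,
        agent=agent,
        dose_raw=dose,
        dose_std=dose,
        responders=r,
        sample_size=n,
    )


@pytest.fixture
def small_net():
    """Three studies: P-A, A-B, three-arm P-A-B; A at two doses."""
    arms = [
        make_arm("s1", "placebo", 0.0, 10, 50),
        make_arm("s1", "A", 1.0, 20, 50),
        make_arm("s2", "A", 2.0, 25, 60),
        make_arm("s2", "B", 1.0, 30, 60),
        make_arm("s3", "placebo", 0.0, 12, 55),
        make_arm("s3", "A", 1.0, 22, 55),
        make_arm("s3", "B", 1.0, 28, 55),
    ]
    return mb.build_network(arms, {"A": 1.0, "B": 1.0})


@pytest.fixture
def two_arm_net():
    """Single placebo-controlled two-arm study (10/50 vs 20/50)."""
    arms = [
        make_arm("t1", "placebo", 0.0, 10, 50),
        make_arm("t1", "A", 1.0, 20, 50),
    ]
    return mb.build_network(arms, {"A": 1.0})


@pytest.fixture
def reduced_cfg():
    return mb.RunConfig.reduced(seed=42)


@pytest.fixture
def quick_cfg():
    """Very short run for shape/plumbing tests (summaries will be noisy)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mb.RunConfig(n_chains=2, burn_in=300, keep=300, thin=1, seed=7)


@pytest.fixture(scope="session")
def emax_fit_session():
    """One moderate random-effects Emax fit shared across test modules."""
    truth = mb.TruthSpec(n_studies=20, sample_size=150, seed=11)
    net, record = mb.simulate_network(truth)
    model = mb.build_mbnma(net, mb.ModelSpec(family="mbnma", dose_model="emax"))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mb.fit(model, mb.RunConfig.reduced(seed=5))
    return truth, net, record, fit


def seeded_rng(seed=0):
    return np.random.default_rng(seed)
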