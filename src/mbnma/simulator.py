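"""Synthetic trial-network generator with known truth.

The generator runs the binomial-logit random-effects MBNMA forward: for each
study it draws a baseline log-odds, draws correlated study-level relative
effects around the dose-response means (same exchangeable multi-arm scheme
the models assume), and draws binomial counts. The default layout mirrors a
typical dose-ranging evidence base: one placebo hub carrying most of the
evidence, several agents each trialed at a few standardized doses (multiples
of a common dose), a minority of three-arm and active-vs-active trials so
multi-arm correlation and indirect evidence are exercised.

The truth record returned next to the network enables parameter-recovery
scoring and lets :func:`inject_inconsistency` regenerate outcomes on one edge
of a loop with a log-odds offset, to exercise the inconsistency screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .dose_response import get_dose_response
from .models import sequential_draw
from .trial_data import PLACEBO, Arm, TrialNetwork, build_network, is_placebo


@dataclass
class TruthSpec:
    """The data-generating truth.

    ``params`` maps agent -> per-agent dose-response parameters in the order
    of the dose model's parameter block (e.g. (emax, log_ed50)). ``doses``
    lists the standardized doses at which each agent may be trialed (a dict
    per agent, or one list shared by all agents). ``designs`` optionally
    pins the exact treatment list of every study, overriding the random
    layout; entries are lists of (agent, dose) with ("placebo", 0) allowed.
    """

    agents: tuple[str, ...] = ("A", "B", "C", "D")
    dose_model: str = "emax"
    params: dict = field(
        default_factory=lambda: {
            "A": (1.0, 0.0),
            "B": (1.5, 0.0),
            "C": (2.0, 0.0),
            "D": (2.5, 0.0),
        }
    )
    sigma: float = 0.25
    placebo_mean: float = -1.5
    placebo_sd: float = 0.3
    n_studies: int = 40
    doses: object = (0.5, 1.0, 2.0, 4.0)
    sample_size: int = 200
    p_three_arm: float = 0.15
    p_active_active: float = 0.15
    designs: list | None = None
    seed: int = 0

    def __post_init__(self):
        self.agents = tuple(self.agents)
        self.params = {a: tuple(float(x) for x in v) for a, v in self.params.items()}
        def _doses(v):
            try:
                return tuple(float(x) for x in v)
            except TypeError:
                return (float(v),)

        if isinstance(self.doses, dict):
            self.doses = {a: _doses(v) for a, v in self.doses.items()}
        else:
            self.doses = _doses(self.doses)

    def dose_list(self, agent) -> list[float]:
        if isinstance(self.doses, dict):
            return list(self.doses[agent])
        return list(self.doses)

    def to_dict(self):
        d = asdict(self)
        d["agents"] = list(self.agents)
        d["params"] = {a: list(v) for a, v in self.params.items()}
        if not isinstance(self.doses, dict):
            d["doses"] = list(self.doses)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["agents"] = tuple(d.get("agents", ()))
        if "params" in d:
            d["params"] = {a: tuple(v) for a, v in d["params"].items()}
        return cls(**d)


def triptan_like_truth(seed: int = 0) -> TruthSpec:
    """A layout shaped like a 7-agent migraine-treatment network: ~70 RCTs,
    one placebo anchor, agents at 1-4 standardized doses in [0.25, 4]."""
    agents = tuple("agent%d" % i for i in range(1, 8))
    rng = np.random.default_rng(seed)
    params = {
        a: (float(rng.uniform(1.0, 2.5)), float(rng.normal(0.0, 0.3))) for a in agents
    }
    doses = {
        a: sorted(
            rng.choice([0.25, 0.5, 1.0, 2.0, 4.0], size=rng.integers(1, 5), replace=False)
        )
        for a in agents
    }
    return TruthSpec(
        agents=agents,
        params=params,
        doses=doses,
        n_studies=70,
        sigma=0.25,
        placebo_mean=-1.5,
        placebo_sd=0.4,
        sample_size=150,
        seed=seed,
    )


# ---------------------------------------------------------------------------


def _random_designs(truth: TruthSpec, rng) -> list[list[tuple[str, float]]]:
    combos = [(a, d) for a in truth.agents for d in truth.dose_list(a)]
    if truth.n_studies < len(combos):
        raise ValueError(
            f"layout infeasible: {len(combos)} agent-dose combinations but only "
            f"{truth.n_studies} studies"
        )
    designs = []
    # guarantee every combination at least one placebo-controlled trial
    for combo in combos:
        designs.append([(PLACEBO, 0.0), combo])
    while len(designs) < truth.n_studies:
        u = rng.random()
        if u < truth.p_three_arm and len(truth.agents) >= 2:
            a, b = rng.choice(len(truth.agents), size=2, replace=False)
            designs.append(
                [
                    (PLACEBO, 0.0),
                    _pick(truth, truth.agents[a], rng),
                    _pick(truth, truth.agents[b], rng),
                ]
            )
        elif u < truth.p_three_arm + truth.p_active_active and len(truth.agents) >= 2:
            a, b = rng.choice(len(truth.agents), size=2, replace=False)
            designs.append([_pick(truth, truth.agents[a], rng), _pick(truth, truth.agents[b], rng)])
        else:
            i = rng.integers(len(truth.agents))
            designs.append([(PLACEBO, 0.0), _pick(truth, truth.agents[i], rng)])
    return designs


def _pick(truth, agent, rng):
    doses = truth.dose_list(agent)
    return (agent, float(doses[rng.integers(len(doses))]))


def _f_true(truth: TruthSpec, agent, dose) -> float:
    if is_placebo(agent):
        return 0.0
    dm = get_dose_response(truth.dose_model)
    return float(dm.evaluate(float(dose), np.asarray(truth.params[agent], dtype=float)))


def _simulate_study(truth, design, study_id, rng, offset_map=None):
    """Outcomes for one study; arm 1 is the first design entry."""
    ref_agent, ref_dose = design[0]
    f_ref = _f_true(truth, ref_agent, ref_dose)
    mu = rng.normal(truth.placebo_mean + f_ref, truth.placebo_sd)
    means = np.array(
        [_f_true(truth, a, d) - f_ref for a, d in design[1:]], dtype=float
    )
    if offset_map:
        for j, (a, d) in enumerate(design[1:]):
            means[j] += offset_map.get((a, d), 0.0) - offset_map.get((ref_agent, ref_dose), 0.0)
    if truth.sigma > 0 and len(means):
        delta = sequential_draw(means, truth.sigma, rng)
    else:
        delta = means
    arms = []
    for k, (agent, dose) in enumerate(design):
        lin = mu if k == 0 else mu + delta[k - 1]
        r = int(rng.binomial(truth.sample_size, expit(lin)))
        arms.append(
            Arm(
                study_id=study_id,
                agent=agent,
                dose_raw=float(dose),
                dose_std=float(dose),
                responders=r,
                sample_size=truth.sample_size,
            )
        )
    return arms


def simulate_network(truth: TruthSpec, seed: int | None = None):
    """Generate a synthetic network; returns (TrialNetwork, truth record).

    Deterministic given the seed (``truth.seed`` unless overridden). Doses
    are emitted already standardized (common dose 1 per agent).
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    designs = (
        [list(map(tuple, d)) for d in truth.designs]
        if truth.designs is not None
        else _random_designs(truth, rng)
    )
    for d in designs:
        if len(d) < 2:
            raise ValueError("every study design needs at least 2 arms")
    arms = []
    for i, design in enumerate(designs):
        arms.extend(_simulate_study(truth, design, f"s{i + 1:03d}", rng))
    common = {a: 1.0 for a in truth.agents}
    net = build_network(arms, common)
    record = {
        "truth": truth.to_dict(),
        "seed": int(seed),
        "designs": [[list(t) for t in d] for d in designs],
        "inconsistency": None,
    }
    return net, record


def inject_inconsistency(net: TrialNetwork, record: dict, loop, offset: float, seed: int = 1):
    """Bias one edge of a loop and regenerate only the studies on it.

    ``loop`` is a treatment triple ((agent, dose) pairs; ("placebo", 0)
    allowed); the offset (log-odds) is applied to the direct comparisons of
    the LAST TWO treatments of the loop: in every study containing both, the
    relative effect of the second vs the first is shifted by ``offset``.
    Other studies are untouched. Returns (new network, updated record).
    """
    truth = TruthSpec.from_dict(record["truth"])
    loop = [(a, float(d)) for a, d in loop]
    u, v = loop[-2], loop[-1]
    designs = [[(a, float(d)) for a, d in ds] for ds in record["designs"]]
    on_edge = [i for i, ds in enumerate(designs) if u in ds and v in ds]
    if not on_edge:
        raise ValueError(f"no study directly compares {u} and {v}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB1A5]))
    # +offset on v relative to u, routed through whichever arm is the reference
    offset_map = {v: offset, u: 0.0}
    new_studies = []
    for i, st in enumerate(net.studies):
        if i in on_edge:
            arms = _simulate_study(truth, designs[i], st.study_id, rng, offset_map)
            new_studies.extend(arms)
        else:
            new_studies.extend(st.arms)
    out = build_network(list(new_studies), net.common_doses, net.level)
    new_record = dict(record)
    new_record["inconsistency"] = {
        "loop": [list(t) for t in loop],
        "edge": [list(u), list(v)],
        "offset": float(offset),
        "studies": [net.studies[i].study_id for i in on_edge],
        "seed": int(seed),
    }
    return out, new_record
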