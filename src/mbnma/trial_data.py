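"""Arm-level trial data: containers, I/O, dose standardization, network structure.

The data model is long-format arm-level evidence from randomized trials: one
row per trial arm carrying the agent, the dose, and a binomial outcome
(responders out of analysed). Doses are standardized at load time to multiples
of each agent's "common" dose; every downstream model sees only the
standardized dose. Placebo is a distinguished agent pinned at dose 0 and acts
as the network reference.

A network can be coded at two levels:

* ``treatment`` ("split"): each (agent, standardized dose) pair is a node;
* ``agent`` ("lumped"): all doses of an agent collapse onto one node.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import pandas as pd

PLACEBO = "placebo"

REQUIRED_COLUMNS = ("study", "agent", "dose", "responders", "sample_size")


def is_placebo(agent: str) -> bool:
    return str(agent).strip().lower() == PLACEBO


@dataclass(frozen=True)
class Arm:
    """One trial arm: binomial outcome at an (agent, dose) combination."""

    study_id: str
    agent: str
    dose_raw: float
    dose_std: float
    responders: int
    sample_size: int

    def __post_init__(self):
        if self.sample_size <= 0:
            raise ValueError(
                f"study {self.study_id!r}: sample_size must be positive, got {self.sample_size}"
            )
        if not 0 <= self.responders <= self.sample_size:
            raise ValueError(
                f"study {self.study_id!r}: responders ({self.responders}) must lie in "
                f"[0, sample_size={self.sample_size}]"
            )
        if self.dose_raw < 0 or self.dose_std < 0:
            raise ValueError(f"study {self.study_id!r}: negative dose")
        if is_placebo(self.agent) != (self.dose_std == 0):
            raise ValueError(
                f"study {self.study_id!r}: dose_std must be 0 exactly for placebo arms "
                f"and positive for active arms (agent={self.agent!r}, dose_std={self.dose_std})"
            )


@dataclass(frozen=True)
class Study:
    """An ordered collection of arms sharing one randomization; arm 0 is the reference."""

    study_id: str
    arms: tuple[Arm, ...]

    def __post_init__(self):
        if len(self.arms) < 2:
            raise ValueError(f"study {self.study_id!r}: single-arm studies are not usable")
        if any(a.study_id != self.study_id for a in self.arms):
            raise ValueError(f"study {self.study_id!r}: arms carry mismatched study ids")

    @property
    def reference_arm(self) -> Arm:
        return self.arms[0]


@dataclass(frozen=True)
class TrialNetwork:
    """A set of studies plus the agent/treatment coding used to connect them.

    ``level`` selects the coding: ``"treatment"`` (split; the default) or
    ``"agent"`` (lumped). ``duplicate_coded_studies`` lists studies that
    contain several arms mapping to the same coded node (this only happens
    under lumping); the model layer constrains the within-node relative
    effect of such arms to zero.
    """

    studies: tuple[Study, ...]
    common_doses: dict[str, float] = field(default_factory=dict)
    level: str = "treatment"

    def __post_init__(self):
        if self.level not in ("treatment", "agent"):
            raise ValueError(f"unknown coding level {self.level!r}")
        if not self.studies:
            raise ValueError("empty network")

    # ---- node codings ---------------------------------------------------

    @property
    def agents(self) -> list[str]:
        """Agents with the reference (placebo) first, then alphabetically.

        Sorting (rather than input order) makes the network ordering — and
        with it the reference-arm tie-break and every parameter index —
        invariant to how the rows were fed in.
        """
        seen: set[str] = set()
        has_placebo = False
        for st in self.studies:
            for a in st.arms:
                if is_placebo(a.agent):
                    has_placebo = True
                else:
                    seen.add(a.agent)
        return ([PLACEBO] if has_placebo else []) + sorted(seen)

    @property
    def treatments(self) -> list[tuple[str, float]]:
        """(agent, dose_std) pairs; placebo (if present) first, then by agent order and dose."""
        agents = self.agents
        combos = {
            (a.agent if not is_placebo(a.agent) else PLACEBO, a.dose_std)
            for st in self.studies
            for a in st.arms
        }
        return sorted(combos, key=lambda t: (agents.index(t[0]), t[1]))

    def coded(self, arm: Arm):
        """The node this arm maps to under the current coding level."""
        agent = PLACEBO if is_placebo(arm.agent) else arm.agent
        if self.level == "agent":
            return agent
        return (agent, arm.dose_std)

    @property
    def nodes(self) -> list:
        if self.level == "agent":
            return self.agents
        return self.treatments

    @property
    def duplicate_coded_studies(self) -> list[str]:
        out = []
        for st in self.studies:
            codes = [self.coded(a) for a in st.arms]
            if len(set(codes)) < len(codes):
                out.append(st.study_id)
        return out

    @property
    def n_arms(self) -> int:
        return sum(len(st.arms) for st in self.studies)

    def arms_table(self) -> pd.DataFrame:
        rows = [
            {
                "study": a.study_id,
                "agent": a.agent,
                "dose": a.dose_raw,
                "dose_std": a.dose_std,
                "responders": a.responders,
                "sample_size": a.sample_size,
            }
            for st in self.studies
            for a in st.arms
        ]
        return pd.DataFrame(rows)


# ---- construction -------------------------------------------------------


def _order_reference_first(arms: list[Arm], node_order: dict) -> tuple[Arm, ...]:
    """Reference-arm tie-break: placebo if present, else lowest treatment index."""
    ref = None
    for a in arms:
        if is_placebo(a.agent):
            ref = a
            break
    if ref is None:
        ref = min(arms, key=lambda a: node_order[(a.agent, a.dose_std)])
    rest = [a for a in arms if a is not ref]
    return (ref,) + tuple(rest)


def build_network(
    arms: list[Arm], common_doses: dict[str, float] | None = None, level: str = "treatment"
) -> TrialNetwork:
    """Group arms into studies (input order preserved) and normalize reference arms."""
    by_study: dict[str, list[Arm]] = {}
    for a in arms:
        by_study.setdefault(a.study_id, []).append(a)
    # global treatment ordering for the tie-break (placebo first, then by
    # first-appearance agent order and dose)
    tmp = TrialNetwork(
        studies=tuple(
            Study(sid, tuple(sarms)) for sid, sarms in by_study.items()
        ),
        common_doses=dict(common_doses or {}),
        level=level,
    )
    node_order = {t: i for i, t in enumerate(tmp.treatments)}
    studies = tuple(
        Study(sid, _order_reference_first(sarms, node_order))
        for sid, sarms in by_study.items()
    )
    return TrialNetwork(studies=studies, common_doses=dict(common_doses or {}), level=level)


def read_long_format(path, common_doses) -> TrialNetwork:
    """Read long-format arm-level data (CSV/TSV) and standardize doses.

    ``common_doses`` maps agent -> common dose in the same raw units as the
    file's ``dose`` column; it may also be a path to a two-column
    (agent, common_dose) delimited file. Placebo needs no entry. Standardized
    dose is ``dose / common_doses[agent]``, e.g. 100 mg of an agent whose
    common dose is 50 mg becomes 2.0. An empty table (``{}`` or ``None``)
    declares the doses already standardized; a non-empty table must cover
    every active agent.
    """
    df = _read_table(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if common_doses is None:
        common_doses = {}
    if not isinstance(common_doses, dict):
        cd = _read_table(common_doses)
        if not {"agent", "common_dose"} <= set(cd.columns):
            raise ValueError("common-dose table needs columns: agent, common_dose")
        common_doses = dict(zip(cd["agent"], cd["common_dose"].astype(float)))
    for agent, c in common_doses.items():
        if c <= 0:
            raise ValueError(f"common dose for {agent!r} must be positive")

    arms = []
    for row in df.itertuples(index=False):
        agent = str(row.agent)
        dose = float(row.dose)
        if dose < 0:
            raise ValueError(f"study {row.study!r}: negative dose {dose}")
        if is_placebo(agent):
            dose_std = 0.0
        elif not common_doses:  # doses arrive pre-standardized
            dose_std = dose
        else:
            if agent not in common_doses:
                raise ValueError(f"agent {agent!r} has no entry in the common-dose table")
            dose_std = dose / common_doses[agent]
        arms.append(
            Arm(
                study_id=str(row.study),
                agent=agent,
                dose_raw=dose,
                dose_std=dose_std,
                responders=int(row.responders),
                sample_size=int(row.sample_size),
            )
        )
    return build_network(arms, common_doses)


def write_long_format(net: TrialNetwork, path) -> None:
    """Write the network back to delimited text (inverse of :func:`read_long_format`)."""
    df = net.arms_table().drop(columns=["dose_std"])
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


# ---- coding transforms --------------------------------------------------


def to_lumped(net: TrialNetwork) -> TrialNetwork:
    """Collapse treatment coding to agent labels ("all doses equivalent").

    Studies with several arms of one agent are reported by
    ``duplicate_coded_studies`` on the result; the model layer fixes the
    within-agent relative effect of such arm pairs to zero.
    """
    return replace(net, level="agent")


def to_split(net: TrialNetwork) -> TrialNetwork:
    """Code each (agent, dose_std) pair as its own treatment node.

    Warns (does not fail) if the split graph is disconnected — such a network
    cannot be fitted jointly but is still inspectable.
    """
    out = replace(net, level="treatment")
    ok, comps = connectivity(out)
    if not ok:
        warnings.warn(
            f"split network is disconnected into {len(comps)} components: {comps}",
            stacklevel=2,
        )
    return out


# ---- graph structure ----------------------------------------------------


def _graph(net: TrialNetwork, level: str | None = None) -> nx.Graph:
    level = level or net.level
    coded_net = replace(net, level=level)
    g = nx.Graph()
    g.add_nodes_from(map(_node_label, coded_net.nodes))
    for st in net.studies:
        codes = sorted({_node_label(coded_net.coded(a)) for a in st.arms}, key=str)
        for u, v in itertools.combinations(codes, 2):
            if g.has_edge(u, v):
                g[u][v]["n_comparisons"] += 1
            else:
                g.add_edge(u, v, n_comparisons=1)
    return g


def _node_label(node):
    if isinstance(node, tuple):
        agent, dose = node
        return f"{agent}@{dose:g}"
    return node


def connectivity(net: TrialNetwork, level: str | None = None):
    """(connected?, list of components) of the coded comparison graph."""
    g = _graph(net, level)
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    return len(comps) == 1, comps


def network_summary(net: TrialNetwork, level: str | None = None) -> pd.DataFrame:
    """Edge table of the evidence network: one row per compared node pair.

    ``n_comparisons`` counts within-study comparisons: a study contributes one
    comparison to every unordered pair of distinct coded nodes among its arms
    (so a three-arm study increments three edges). ``df.attrs["connected"]``
    flags whole-graph connectivity.
    """
    g = _graph(net, level)
    rows = [
        {"node_a": str(u), "node_b": str(v), "n_comparisons": d["n_comparisons"]}
        for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "n_comparisons"])
    df.attrs["connected"] = nx.is_connected(g) if g.number_of_nodes() else False
    return df


def expected_comparison_count(net: TrialNetwork) -> int:
    """Sum over studies of C(#distinct coded arms, 2); equals the edge-table total."""
    total = 0
    for st in net.studies:
        k = len({net.coded(a) for a in st.arms})
        total += math.comb(k, 2)
    return total
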