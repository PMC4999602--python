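import math

import numpy as np
import pandas as pd
import pytest

import mbnma as mb
from mbnma.trial_data import expected_comparison_count

from conftest import make_arm


def write_csv(tmp_path, rows, name="data.csv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=["study", "agent", "dose", "responders", "sample_size"]).to_csv(
        path, index=False
    )
    return path


class TestReadLongFormat:
    def test_dose_standardization(self, tmp_path):
        """100 mg of an agent with a 50 mg common dose -> standardized dose 2."""
        path = write_csv(
            tmp_path,
            [
                ("s1", "placebo", 0, 10, 50),
                ("s1", "sumatriptan", 100, 20, 50),
                ("s2", "placebo", 0, 9, 40),
                ("s2", "sumatriptan", 50, 15, 40),
            ],
        )
        net = mb.read_long_format(path, {"sumatriptan": 50.0})
        tbl = net.arms_table().set_index(["study", "agent"])
        assert tbl.loc[("s1", "sumatriptan"), "dose_std"] == 2.0
        assert tbl.loc[("s2", "sumatriptan"), "dose_std"] == 1.0  # common dose itself
        assert (tbl.loc[(slice(None), "placebo"), "dose_std"] == 0).all()

    def test_common_doses_from_file(self, tmp_path):
        data = write_csv(
            tmp_path,
            [("s1", "placebo", 0, 5, 20), ("s1", "A", 40, 8, 20)],
        )
        cd = tmp_path / "common.csv"
        pd.DataFrame({"agent": ["A"], "common_dose": [20.0]}).to_csv(cd, index=False)
        net = mb.read_long_format(data, cd)
        assert net.arms_table()["dose_std"].max() == 2.0

    @pytest.mark.parametrize(
        "rows, message",
        [
            ([("s1", "placebo", 0, 5, 20)], "single-arm"),
            (
                [("s1", "placebo", 0, 25, 20), ("s1", "A", 1, 5, 20)],
                "responders",
            ),
            (
                [("s1", "placebo", 0, 5, 20), ("s1", "A", -1, 5, 20)],
                "negative dose",
            ),
            (
                [("s1", "placebo", 0, 5, 20), ("s1", "B", 1, 5, 20)],
                "common-dose",
            ),
        ],
    )
    def test_invalid_inputs_rejected(self, tmp_path, rows, message):
        path = write_csv(tmp_path, rows)
        with pytest.raises(ValueError, match=message):
            mb.read_long_format(path, {"A": 1.0})

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"study": ["s1"], "agent": ["A"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="dose"):
            mb.read_long_format(path, {"A": 1.0})

    def test_round_trip(self, tmp_path, small_net):
        """Writing then reading reproduces the network field-for-field."""
        path = tmp_path / "rt.csv"
        mb.write_long_format(small_net, path)
        back = mb.read_long_format(path, small_net.common_doses)
        assert back.studies == small_net.studies
        assert back.agents == small_net.agents

    def test_dose_std_invariant_to_raw_units(self, tmp_path):
        """Rescaling raw doses and common dose together leaves dose_std fixed."""
        for scale in (1.0, 1000.0, 0.001):
            path = write_csv(
                tmp_path,
                [
                    ("s1", "placebo", 0, 10, 50),
                    ("s1", "A", 100 * scale, 20, 50),
                    ("s2", "placebo", 0, 10, 50),
                    ("s2", "A", 25 * scale, 20, 50),
                ],
            )
            net = mb.read_long_format(path, {"A": 50.0 * scale})
            assert sorted(
                a.dose_std for st in net.studies for a in st.arms if a.agent == "A"
            ) == [0.5, 2.0]


class TestReferenceArm:
    def test_placebo_first(self, small_net):
        for st in small_net.studies:
            if any(a.agent == "placebo" for a in st.arms):
                assert st.reference_arm.agent == "placebo"

    def test_non_placebo_tiebreak_lowest_treatment_index(self, small_net):
        s2 = next(st for st in small_net.studies if st.study_id == "s2")
        # network treatment ordering puts A before B
        assert s2.reference_arm.agent == "A"


class TestNetworkSummary:
    def test_two_study_chain(self):
        arms = [
            make_arm("s1", "placebo", 0, 5, 20),
            make_arm("s1", "A", 1.0, 8, 20),
            make_arm("s2", "A", 1.0, 8, 20),
            make_arm("s2", "B", 1.0, 9, 20),
        ]
        net = mb.build_network(arms)
        df = mb.network_summary(net, level="agent")
        edges = {frozenset((r.node_a, r.node_b)): r.n_comparisons for r in df.itertuples()}
        assert edges == {frozenset({"placebo", "A"}): 1, frozenset({"A", "B"}): 1}
        assert df.attrs["connected"]

    def test_split_disconnection(self):
        """Same agent at different doses in disjoint studies: no shared node."""
        arms = [
            make_arm("s1", "placebo", 0, 5, 20),
            make_arm("s1", "A", 1.0, 8, 20),
            make_arm("s2", "A", 2.0, 8, 20),
            make_arm("s2", "B", 1.0, 9, 20),
        ]
        net = mb.build_network(arms)
        assert mb.network_summary(net, level="agent").attrs["connected"]
        assert not mb.network_summary(net, level="treatment").attrs["connected"]

    def test_three_arm_counts_all_pairs(self, small_net):
        df = mb.network_summary(small_net, level="agent")
        edges = {frozenset((r.node_a, r.node_b)): r.n_comparisons for r in df.itertuples()}
        # s1: P-A; s2: A-B; s3: P-A, P-B, A-B
        assert edges[frozenset({"placebo", "A"})] == 2
        assert edges[frozenset({"placebo", "B"})] == 1
        assert edges[frozenset({"A", "B"})] == 2

    def test_total_comparisons_equals_choose2_sum(self, small_net):
        for level in ("agent", "treatment"):
            df = mb.network_summary(small_net, level=level)
            coded = mb.trial_data.to_lumped(small_net) if level == "agent" else small_net
            assert df["n_comparisons"].sum() == expected_comparison_count(coded)


class TestCodings:
    def test_to_lumped_flags_duplicate_agent_studies(self):
        arms = [
            make_arm("s1", "placebo", 0, 5, 30),
            make_arm("s1", "suma", 1.0, 10, 30),
            make_arm("s1", "suma", 2.0, 12, 30),
            make_arm("s2", "placebo", 0, 5, 30),
            make_arm("s2", "suma", 1.0, 10, 30),
        ]
        net = mb.build_network(arms)
        lumped = mb.to_lumped(net)
        assert lumped.level == "agent"
        assert lumped.duplicate_coded_studies == ["s1"]
        assert net.duplicate_coded_studies == []  # distinct at treatment level

    def test_lumped_basic_parameter_count(self, small_net):
        lumped = mb.to_lumped(small_net)
        model = mb.build_nma(lumped, mb.ModelSpec(family="nma_lumped", effect="fixed"))
        s = len(lumped.agents)
        assert len(model.basic_parameters()) == s - 1

    def test_to_split_nodes(self, small_net):
        split = mb.to_split(small_net)
        # placebo, A@1, A@2, B@1
        assert len(split.nodes) == 4
        assert split.nodes[0] == ("placebo", 0.0)

    def test_to_split_warns_on_disconnection(self):
        arms = [
            make_arm("s1", "placebo", 0, 5, 20),
            make_arm("s1", "A", 1.0, 8, 20),
            make_arm("s2", "A", 2.0, 8, 20),
            make_arm("s2", "B", 1.0, 9, 20),
        ]
        net = mb.build_network(arms)
        with pytest.warns(UserWarning, match="disconnected"):
            mb.to_split(net)

    def test_split_node_count_bounds(self):
        """7 agents + placebo, 1-4 doses each -> between 8 and 29 nodes."""
        truth = mb.triptan_like_truth(seed=2)
        net, _ = mb.simulate_network(truth, seed=2)
        n_nodes = len(mb.to_split(net).nodes)
        assert 8 <= n_nodes <= 29


class TestArmValidation:
    def test_placebo_dose_must_be_zero(self):
        with pytest.raises(ValueError, match="placebo"):
            make_arm("s1", "placebo", 1.0, 5, 20)

    def test_active_dose_must_be_positive(self):
        with pytest.raises(ValueError):
            make_arm("s1", "A", 0.0, 5, 20)
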