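"""Co-occurrence odds ratios, temporal ordering, and network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import ehrstates as e

from conftest import cooccurrence_brute, true_snapshot_states


def labels_df(timelines: dict[str, list[int]]) -> pd.DataFrame:
    rows = [
        (pid, b, s)
        for pid, seq in timelines.items()
        for b, s in enumerate(seq)
        if s is not None
    ]
    return pd.DataFrame(rows, columns=["patient_id", "bin_index", "state"])


class TestCooccurrenceOdds:
    def test_direct_cell_arithmetic(self):
        # 30 patients with both, 10 i-only, 10 j-only, 50 neither
        timelines = {}
        for n, (i_has, j_has) in zip(
            (30, 10, 10, 50), ((1, 1), (1, 0), (0, 1), (0, 0))
        ):
            for r in range(n):
                seq = []
                if i_has:
                    seq.append(0)
                if j_has:
                    seq.append(1)
                if not seq:
                    seq = [2]
                timelines[f"{i_has}{j_has}_{r}"] = seq
        out = e.cooccurrence_odds(labels_df(timelines), n_states=3)
        row = out[(out["state_i"] == 0) & (out["state_j"] == 1)].iloc[0]
        assert row[["n11", "n10", "n01", "n00"]].tolist() == [30, 10, 10, 50]
        assert row["odds_ratio"] == pytest.approx(15.0)
        assert row["significant"]

    def test_symmetry_in_pair(self):
        rng = np.random.default_rng(0)
        inc = pd.DataFrame(rng.random((60, 3)) < 0.4)
        out = e.cooccurrence_from_incidence(inc)
        swapped = e.cooccurrence_from_incidence(inc[[1, 0, 2]].set_axis([0, 1, 2], axis=1))
        a = out[(out["state_i"] == 0) & (out["state_j"] == 1)]["odds_ratio"].iloc[0]
        b = swapped[(swapped["state_i"] == 0) & (swapped["state_j"] == 1)]["odds_ratio"].iloc[0]
        assert a == pytest.approx(b)

    @settings(max_examples=30, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_matches_patient_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_patients = int(rng.integers(10, 100))
        n_states = int(rng.integers(2, 6))
        patient_states = {
            f"p{i}": set(
                rng.choice(n_states, size=rng.integers(1, n_states + 1), replace=False).tolist()
            )
            for i in range(n_patients)
        }
        df = labels_df({p: sorted(s) for p, s in patient_states.items()})
        out = e.cooccurrence_odds(df, n_states=n_states).set_index(["state_i", "state_j"])
        oracle = cooccurrence_brute(patient_states, n_states)
        for (i, j), (n11, n10, n01, n00, orr) in oracle.items():
            row = out.loc[(i, j)]
            assert row[["n11", "n10", "n01", "n00"]].tolist() == [n11, n10, n01, n00]
            assert row["odds_ratio"] == pytest.approx(orr)

    def test_zero_cell_correction_flagged(self):
        timelines = {f"a{r}": [0, 1] for r in range(10)}
        timelines.update({f"b{r}": [2] for r in range(10)})
        out = e.cooccurrence_odds(labels_df(timelines), n_states=3)
        row = out[(out["state_i"] == 0) & (out["state_j"] == 1)].iloc[0]
        assert row["zero_cell_corrected"]
        assert np.isfinite(row["odds_ratio"])

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            e.cooccurrence_odds(labels_df({"p": [0]}), n_states=1)


class TestOrderingProbabilities:
    def test_always_first_gives_probability_one(self):
        timelines = {f"p{r}": [0, 0, 1] for r in range(5)}
        out = e.ordering_probabilities(labels_df(timelines)).set_index(
            ["state_i", "state_j"]
        )
        assert out.loc[(0, 1), "p_before"] == 1.0
        assert out.loc[(1, 0), "p_before"] == 0.0

    def test_antisymmetry_on_generated_cohort(self, flat_cohort, flat_matrix):
        matrix, _ = flat_matrix
        df = matrix.rows.copy()
        df["state"] = true_snapshot_states(flat_cohort, matrix)
        out = e.ordering_probabilities(df)
        idx = out.set_index(["state_i", "state_j"])["p_before"]
        for (i, j), p in idx.items():
            assert idx[(j, i)] == pytest.approx(1.0 - p)

    def test_median_transition_time(self):
        timelines = {
            "p1": [0, None, 1],   # first 0 at bin 0, first 1 at bin 2: delta 2
            "p2": [0, 1],          # delta 1
            "p3": [0, None, None, None, 1],  # delta 4
        }
        out = e.ordering_probabilities(labels_df(timelines)).set_index(
            ["state_i", "state_j"]
        )
        assert out.loc[(0, 1), "median_bins"] == 2.0

    def test_never_cooccurring_pair_missing(self):
        timelines = {"p1": [0], "p2": [1]}
        out = e.ordering_probabilities(labels_df(timelines))
        assert out.empty


class TestBuildNetwork:
    @staticmethod
    def cooc_row(i, j, orr, significant=True):
        return {
            "state_i": i, "state_j": j, "n11": 10, "n10": 5, "n01": 5, "n00": 10,
            "odds_ratio": orr, "ci_low": orr * 0.8 if significant else 0.9,
            "ci_high": orr * 1.2, "significant": significant,
            "zero_cell_corrected": False,
        }

    @staticmethod
    def order_rows(i, j, p_ij, med_ij=2.0, med_ji=3.0, n_both=20):
        return [
            {"state_i": i, "state_j": j, "n_both": n_both,
             "n_i_first": int(p_ij * n_both), "p_before": p_ij, "median_bins": med_ij},
            {"state_i": j, "state_j": i, "n_both": n_both,
             "n_i_first": n_both - int(p_ij * n_both), "p_before": 1 - p_ij,
             "median_bins": med_ji},
        ]

    def test_or_below_threshold_no_edge(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 1.2)]),
            pd.DataFrame(self.order_rows(0, 1, 0.9)),
            n_states=2,
        )
        assert net.graph.number_of_edges() == 0

    def test_insignificant_or_no_edge(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 5.0, significant=False)]),
            pd.DataFrame(self.order_rows(0, 1, 0.9)),
            n_states=2,
        )
        assert net.graph.number_of_edges() == 0

    def test_band_midpoint_is_bidirectional(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(self.order_rows(0, 1, 0.5)),
            n_states=2,
        )
        assert net.graph.has_edge(0, 1) and net.graph.has_edge(1, 0)
        assert net.graph.edges[0, 1]["bidirectional"]
        # annotation: mean of the two directional medians
        assert net.graph.edges[0, 1]["median_bins"] == pytest.approx(2.5)

    def test_directed_edge_and_roles(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(self.order_rows(0, 1, 0.9)),
            n_states=3,
        )
        assert net.graph.has_edge(0, 1) and not net.graph.has_edge(1, 0)
        assert net.graph.edges[0, 1]["median_bins"] == pytest.approx(2.0)
        assert net.start_states == [0]
        assert net.end_states == [1]
        assert net.graph.nodes[2]["role"] == "isolated"

    def test_reverse_direction_edge(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(self.order_rows(0, 1, 0.2)),
            n_states=2,
        )
        assert net.graph.has_edge(1, 0) and not net.graph.has_edge(0, 1)
        assert net.graph.edges[1, 0]["median_bins"] == pytest.approx(3.0)

    def test_empty_edge_set_is_valid(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 1.0, significant=False)]),
            pd.DataFrame(self.order_rows(0, 1, 0.5)),
            n_states=2,
        )
        assert net.graph.number_of_nodes() == 2
        assert net.edge_table().empty

    def test_edge_table_lists_bidirectional_once(self):
        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(self.order_rows(0, 1, 0.5)),
            n_states=2,
        )
        assert len(net.edge_table()) == 1
        assert net.edge_table()["direction"].iloc[0] == "bidirectional"

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        net = e.build_network(
            pd.DataFrame([self.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(self.order_rows(0, 1, 0.9)),
            n_states=2,
        )
        net.write_graphml(tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == 1


class TestAnnotations:
    def base_net(self):
        return e.build_network(
            pd.DataFrame([TestBuildNetwork.cooc_row(0, 1, 2.0)]),
            pd.DataFrame(TestBuildNetwork.order_rows(0, 1, 0.9)),
            n_states=2,
        )

    def test_join_fidelity(self):
        net = self.base_net()
        clinical = pd.DataFrame(
            {"cluster": [0, 1], "median_age": [55.0, 70.0], "pct_female": [40.0, 60.0]}
        )
        risk = pd.DataFrame(
            {"cluster": [0], "event_type": ["stroke"], "present_pct": [2.0],
             "future_risk_pct": [5.0]}
        )
        out = e.overlay_network_annotations(net, clinical, risk)
        assert out.graph.nodes[1]["median_age"] == 70.0
        assert out.graph.nodes[0]["future_risk_pct__stroke"] == 5.0

    def test_demographics_only(self):
        net = self.base_net()
        clinical = pd.DataFrame({"cluster": [0, 1], "median_age": [55.0, 70.0]})
        out = e.overlay_network_annotations(net, clinical, risk=None)
        assert out.graph.nodes[0]["median_age"] == 55.0

    def test_unknown_cluster_raises(self):
        net = self.base_net()
        clinical = pd.DataFrame({"cluster": [7], "median_age": [55.0]})
        with pytest.raises(KeyError, match="7"):
            e.overlay_network_annotations(net, clinical)


class TestNullCalibration:
    def test_independent_states_rarely_significant(self):
        """Product-occurrence null: ~5% of OR CIs exclude 1."""
        rng = np.random.default_rng(42)
        n_sig = n_pairs = 0
        for _ in range(30):
            inc = pd.DataFrame(rng.random((600, 6)) < rng.uniform(0.2, 0.5, size=6))
            out = e.cooccurrence_from_incidence(inc)
            n_sig += int(out["significant"].sum())
            n_pairs += len(out)
        rate = n_sig / n_pairs
        se = np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate - 0.05) <= 3 * se + 0.01  # Wald CI is approximate
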