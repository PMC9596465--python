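"""The temporal disease-state progression network.

Two patient-level statistics drive the network.  For every unordered state
pair {i, j}, a 2x2 table over patients (has state i anywhere in the
timeline x has state j) gives the co-occurrence odds ratio

    OR_ij = (n_ij * n_!i!j) / (n_i!j * n_!ij)

with a Haldane-Anscombe 0.5 correction when a cell is empty and a Wald 95%
CI on the log scale; pairs whose CI includes 1 are masked.  For every
ordered pair, among patients holding both states the fraction whose first
occurrence of i precedes j gives the ordering probability p_ij (with one
state per snapshot first-occurrence bins cannot tie, so p_ij + p_ji = 1),
and the median of firstBin(j) - firstBin(i) over those patients is the
median transition time in 30-day bins (calendar bins, gaps included).

Edges are significant pairs with OR above a threshold (1.33 by default),
directed i->j when p_ij > 0.55, j->i when p_ij < 0.45, and bidirectional in
between; nodes with only outgoing arrows are start states, only incoming
arrows end states.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

DEFAULT_OR_THRESHOLD = 1.33
DEFAULT_BIDIR_BAND = (0.45, 0.55)
Z_95 = 1.959963984540054


def patient_state_incidence(labels_df: pd.DataFrame, n_states: int | None = None) -> pd.DataFrame:
    """Boolean patient x state table: does the state occur anywhere in the
    patient's timeline.  ``labels_df`` has columns patient_id, bin_index,
    state."""
    if n_states is None:
        n_states = int(labels_df["state"].max()) + 1
    inc = pd.crosstab(labels_df["patient_id"], labels_df["state"]) > 0
    return inc.reindex(columns=range(n_states), fill_value=False)


def cooccurrence_from_incidence(incidence: pd.DataFrame) -> pd.DataFrame:
    """Per unordered pair: the four patient-level cells, OR, Wald 95% CI,
    and the significance flag (CI excludes 1)."""
    M = incidence.to_numpy(dtype=np.int64)
    n_patients, K = M.shape
    if K < 2:
        raise ValueError("need at least 2 states for co-occurrence analysis")
    both = M.T @ M
    counts = M.sum(axis=0)
    rows = []
    for i, j in itertools.combinations(range(K), 2):
        n11 = int(both[i, j])
        n10 = int(counts[i] - n11)
        n01 = int(counts[j] - n11)
        n00 = int(n_patients - n11 - n10 - n01)
        cells = np.array([n11, n10, n01, n00], dtype=float)
        corrected = bool((cells == 0).any())
        if corrected:
            logger.debug("zero cell for pair (%d, %d): 0.5 correction applied", i, j)
            cells = cells + 0.5
        orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
        se = float(np.sqrt((1.0 / cells).sum()))
        lo = float(np.exp(np.log(orr) - Z_95 * se))
        hi = float(np.exp(np.log(orr) + Z_95 * se))
        rows.append(
            {
                "state_i": i,
                "state_j": j,
                "n11": n11,
                "n10": n10,
                "n01": n01,
                "n00": n00,
                "odds_ratio": float(orr),
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 1.0 or hi < 1.0),
                "zero_cell_corrected": corrected,
            }
        )
    return pd.DataFrame(rows)


def cooccurrence_odds(
    labels_df: pd.DataFrame, n_states: int | None = None
) -> pd.DataFrame:
    """Patient-level co-occurrence odds ratios for all state pairs."""
    return cooccurrence_from_incidence(patient_state_incidence(labels_df, n_states))


def ordering_probabilities(labels_df: pd.DataFrame) -> pd.DataFrame:
    """First-occurrence ordering statistics for every ordered state pair.

    Returns one row per ordered pair (i, j) that co-occurs in at least one
    patient: the number of co-occurring patients, the count and probability
    of i's first occurrence preceding j's, and the median transition time
    firstBin(j) - firstBin(i) in bins over the patients where i comes
    first.  Ties (possible only if the one-state-per-snapshot contract is
    violated upstream) are dropped with a warning.
    """
    firsts = (
        labels_df.groupby(["patient_id", "state"])["bin_index"].min().reset_index()
    )
    pairs = firsts.merge(firsts, on="patient_id", suffixes=("_i", "_j"))
    pairs = pairs[pairs["state_i"] < pairs["state_j"]]
    ties = pairs["bin_index_i"] == pairs["bin_index_j"]
    if ties.any():
        logger.warning("%d tied first-occurrence pairs dropped", int(ties.sum()))
        pairs = pairs[~ties]
    rows = []
    for (i, j), sub in pairs.groupby(["state_i", "state_j"]):
        i_first = sub["bin_index_i"] < sub["bin_index_j"]
        n_both = int(len(sub))
        n_i_first = int(i_first.sum())
        delta_ij = (sub["bin_index_j"] - sub["bin_index_i"])[i_first]
        delta_ji = (sub["bin_index_i"] - sub["bin_index_j"])[~i_first]
        rows.append(
            {
                "state_i": int(i),
                "state_j": int(j),
                "n_both": n_both,
                "n_i_first": n_i_first,
                "p_before": n_i_first / n_both,
                "median_bins": float(delta_ij.median()) if len(delta_ij) else np.nan,
            }
        )
        rows.append(
            {
                "state_i": int(j),
                "state_j": int(i),
                "n_both": n_both,
                "n_i_first": n_both - n_i_first,
                "p_before": 1.0 - n_i_first / n_both,
                "median_bins": float(delta_ji.median()) if len(delta_ji) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProgressionNetwork:
    """Directed progression graph plus the tables it was built from."""

    graph: nx.DiGraph
    cooccurrence: pd.DataFrame
    ordering: pd.DataFrame

    @property
    def start_states(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("role") == "start"]

    @property
    def end_states(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("role") == "end"]

    def directed_edges(self) -> set[tuple[int, int]]:
        """Arcs of strictly directed (non-bidirectional) edges."""
        return {
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if not d.get("bidirectional", False)
        }

    def edge_table(self) -> pd.DataFrame:
        rows = []
        seen = set()
        for u, v, d in self.graph.edges(data=True):
            if d.get("bidirectional") and (v, u) in seen:
                continue
            seen.add((u, v))
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "odds_ratio": d["odds_ratio"],
                    "ci_low": d["ci_low"],
                    "ci_high": d["ci_high"],
                    "direction": "bidirectional" if d.get("bidirectional") else "directed",
                    "p_order": d["p_order"],
                    "median_bins": d["median_bins"],
                }
            )
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    cooccurrence: pd.DataFrame,
    ordering: pd.DataFrame,
    or_threshold: float = DEFAULT_OR_THRESHOLD,
    bidir_band: tuple[float, float] = DEFAULT_BIDIR_BAND,
    snapshot_counts: dict[int, int] | None = None,
    n_states: int | None = None,
) -> ProgressionNetwork:
    """Assemble the progression network from the two statistics tables.

    An edge exists iff the pair's OR is significant (CI excludes 1) and
    above ``or_threshold`` and an ordering probability is defined.  The
    direction follows p_ij against the bidirectional band; bidirectional
    edges are stored as two arcs flagged ``bidirectional`` whose median
    transition annotation is the mean of the two directional medians.
    Nodes with only outgoing arrows are labeled start states, only incoming
    arrows end states.
    """
    lo_band, hi_band = bidir_band
    if n_states is None:
        n_states = int(cooccurrence[["state_i", "state_j"]].to_numpy().max()) + 1
    G = nx.DiGraph()
    for s in range(n_states):
        G.add_node(
            s, n_snapshots=int((snapshot_counts or {}).get(s, 0)), role="isolated"
        )
    order_idx = (
        ordering.set_index(["state_i", "state_j"]) if len(ordering) else None
    )
    edges = cooccurrence[
        cooccurrence["significant"] & (cooccurrence["odds_ratio"] > or_threshold)
    ]
    for _, row in edges.iterrows():
        i, j = int(row["state_i"]), int(row["state_j"])
        if order_idx is None or (i, j) not in order_idx.index:
            continue  # pair never co-occurs in order data: undefined p
        o_ij = order_idx.loc[(i, j)]
        o_ji = order_idx.loc[(j, i)]
        p_ij = float(o_ij["p_before"])
        attrs = {
            "odds_ratio": float(row["odds_ratio"]),
            "ci_low": float(row["ci_low"]),
            "ci_high": float(row["ci_high"]),
        }
        if p_ij > hi_band:
            G.add_edge(
                i, j, p_order=p_ij, median_bins=float(o_ij["median_bins"]),
                bidirectional=False, **attrs,
            )
        elif p_ij < lo_band:
            G.add_edge(
                j, i, p_order=1 - p_ij, median_bins=float(o_ji["median_bins"]),
                bidirectional=False, **attrs,
            )
        else:
            med = np.nanmean(
                [float(o_ij["median_bins"]), float(o_ji["median_bins"])]
            )
            G.add_edge(i, j, p_order=p_ij, median_bins=float(med),
                       bidirectional=True, **attrs)
            G.add_edge(j, i, p_order=1 - p_ij, median_bins=float(med),
                       bidirectional=True, **attrs)
    if G.number_of_edges() == 0:
        logger.warning("empty edge set: network has only isolated nodes")
    for s in G.nodes:
        out_deg, in_deg = G.out_degree(s), G.in_degree(s)
        if out_deg and not in_deg:
            role = "start"
        elif in_deg and not out_deg:
            role = "end"
        elif in_deg or out_deg:
            role = "intermediate"
        else:
            role = "isolated"
        G.nodes[s]["role"] = role
    return ProgressionNetwork(graph=G, cooccurrence=cooccurrence, ordering=ordering)


def overlay_network_annotations(
    network: ProgressionNetwork,
    clinical: pd.DataFrame | None = None,
    risk: pd.DataFrame | None = None,
) -> ProgressionNetwork:
    """Join per-state summary tables onto the network nodes (no computation
    beyond the join).  Raises if a summarized cluster is unknown."""
    G = network.graph
    if clinical is not None:
        for _, row in clinical.iterrows():
            c = int(row["cluster"])
            if c not in G.nodes:
                raise KeyError(f"clinical summary refers to unknown cluster {c}")
            for col in clinical.columns:
                if col != "cluster":
                    G.nodes[c][col] = row[col]
    if risk is not None and len(risk):
        for (c, et), sub in risk.groupby(["cluster", "event_type"]):
            c = int(c)
            if c not in G.nodes:
                raise KeyError(f"risk table refers to unknown cluster {c}")
            G.nodes[c][f"present_pct__{et}"] = float(sub["present_pct"].iloc[0])
            G.nodes[c][f"future_risk_pct__{et}"] = float(
                sub["future_risk_pct"].iloc[0]
            )
    return network
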