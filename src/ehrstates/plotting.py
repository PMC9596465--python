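"""Figure and report generation for a completed pipeline run.

Produces the standard visual summaries: stability corridors (mean J with
5-95% quantile bands per K, one panel per f_d), the state dendrogram next
to a centroid heatmap, and the progression network drawing with node sizes
proportional to snapshot counts.  Display conventions for the per-state
report: phenotypes with OR > 2, or prevalence > 50%, are called out.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch

OR_CALLOUT = 2.0
PREVALENCE_CALLOUT = 50.0


def plot_stability_corridors(profile, path: Path) -> None:
    summary = profile.summary()
    fds = sorted(summary["f_d"].unique(), reverse=True)
    fig, axes = plt.subplots(
        1, len(fds), figsize=(3 * len(fds), 3), sharey=True, squeeze=False
    )
    for ax, fd in zip(axes[0], fds):
        sub = summary[np.isclose(summary["f_d"], fd)].sort_values("K")
        ax.fill_between(sub["K"], sub["J_lo"], sub["J_hi"], alpha=0.3)
        ax.plot(sub["K"], sub["J"], marker="o", ms=3)
        ax.set_title(f"$f_d$ = {fd:g}")
        ax.set_xlabel("K")
    axes[0][0].set_ylabel("J")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_hierarchy_heatmap(result, path: Path, max_features: int = 50) -> None:
    tree = result.hierarchy
    fig, (ax_h, ax_d) = plt.subplots(
        1, 2, figsize=(10, 4), width_ratios=[3, 1]
    )
    dendro = sch.dendrogram(
        tree.linkage,
        labels=[f"state {i}" for i in tree.leaf_ids],
        orientation="right",
        ax=ax_d,
    )
    order = dendro["leaves"]
    centroids = result.runs[result.k_star].centroids
    var = centroids.var(axis=0)
    top = np.argsort(var)[::-1][:max_features]
    ax_h.imshow(centroids[np.asarray(order)][:, top], aspect="auto", cmap="viridis")
    ax_h.set_yticks(range(len(order)), [f"state {i}" for i in order])
    ax_h.set_xlabel("top-variance complaint features")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_network(network, path: Path) -> None:
    G = network.graph
    pos = nx.spring_layout(G, seed=0)
    sizes = [100 + G.nodes[n].get("n_snapshots", 0) * 0.5 for n in G.nodes]
    colors = {
        "start": "tab:green", "end": "tab:red",
        "intermediate": "tab:blue", "isolated": "lightgray",
    }
    node_colors = [colors[G.nodes[n].get("role", "isolated")] for n in G.nodes]
    fig, ax = plt.subplots(figsize=(6, 5))
    nx.draw_networkx(G, pos, ax=ax, node_size=sizes, node_color=node_colors,
                     font_size=8, arrows=True)
    edge_labels = {
        (u, v): f"{d['median_bins']:.0f}" for u, v, d in G.edges(data=True)
        if np.isfinite(d.get("median_bins", np.nan))
    }
    nx.draw_networkx_edge_labels(G, pos, edge_labels=edge_labels, ax=ax, font_size=7)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def state_report_markdown(result) -> str:
    """Per-state Markdown tables from the bundle's own numbers."""
    lines = ["# Disease state report", ""]
    lines.append(f"Stable K: {result.stable_ks}; reporting at K = {result.k_star}.")
    lines.append("")
    for c in sorted(np.unique(result.labels)):
        lines.append(f"## State {c}")
        if result.clinical is not None:
            row = result.clinical[result.clinical["cluster"] == c].iloc[0]
            lines.append(
                f"- snapshots: {int(row['n_snapshots'])}; patients: "
                f"{int(row['n_patients'])}; % female: {row['pct_female']:.1f}; "
                f"median age: {row['median_age']:.1f} y; "
                f"mortality: {row['mortality_pct']:.2f}%"
            )
        if result.enrichment is not None:
            sub = result.enrichment[result.enrichment["cluster"] == c]
            called = sub[
                (sub["odds_ratio"] > OR_CALLOUT)
                | (sub["prevalence_pct"] > PREVALENCE_CALLOUT)
            ].sort_values("odds_ratio", ascending=False)
            for _, r in called.head(10).iterrows():
                lines.append(
                    f"- {r['phenotype']}: prevalence {r['prevalence_pct']:.1f}% "
                    f"(cohort {r['cohort_prevalence_pct']:.1f}%), "
                    f"OR {r['odds_ratio']:.2f}"
                )
        lines.append("")
    return "\n".join(lines)


def render_reports(result, config) -> Path:
    """Write all figures and the Markdown report; raises a named error if a
    bundle component required by a figure is missing."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.profile is None:
        raise ValueError("bundle is missing the stability profile")
    plot_stability_corridors(result.profile, out / "stability_corridors.png")
    if result.hierarchy is not None:
        plot_hierarchy_heatmap(result, out / "hierarchy_heatmap.png")
    plot_network(result.network, out / "network.png")
    (out / "state_report.md").write_text(state_report_markdown(result))
    return out
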