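"""End-to-end orchestration: configuration, the full run, 2D embedding, and
report rendering.

``run_pipeline`` chains the stages — mention table to snapshot matrix,
K-means sweep with stability bootstrap, stable-K selection and hierarchy,
per-state characterization, event risk, progression network — and writes a
reproducible output bundle (tidy TSVs, MatrixMarket matrix, Newick tree,
GraphML network) together with a run manifest recording seeds and the
record-count funnel at every filter stage.

Defaults mirror the published analysis settings (30-day bins, 10-mention
exclusion, 99% vocabulary coverage, K in 2..30, f_d schedule 0.5 * 2^-m,
1000 replicates, alpha 0.05, OR edge threshold 1.33, bidirectional band
[0.45, 0.55]); replicate counts and the K range are freely reducible so the
pipeline also runs at desk scale.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from . import characterize, events as events_mod, network as network_mod
from . import snapshots as snap_mod
from . import stability as stab_mod
from ._exceptions import SchemaError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; every run writes a config echo."""

    mentions_path: str | None = None
    events_path: str | None = None
    demographics_path: str | None = None
    bmi_path: str | None = None
    output_dir: str = "ehrstates_run"
    bin_width: int = 30
    min_mentions: int = 10
    vocab_coverage: float = 0.99
    k_range: tuple[int, int] = (2, 30)
    fd_schedule: tuple[float, ...] = stab_mod.DEFAULT_FD_SCHEDULE
    n_reps: int = 1000
    alpha: float = 0.05
    test_method: str = "ranksum"
    compute_semantic: bool = True
    or_threshold: float = 1.33
    bidir_band: tuple[float, float] = (0.45, 0.55)
    seed: int = 0
    phenotype_map_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.k_range = tuple(cfg.k_range)
        cfg.fd_schedule = tuple(cfg.fd_schedule)
        cfg.bidir_band = tuple(cfg.bidir_band)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["fd_schedule"] = list(self.fd_schedule)
        d["bidir_band"] = list(self.bidir_band)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    matrix: snap_mod.SnapshotMatrix
    funnel: dict
    runs: dict
    profile: stab_mod.StabilityProfile
    stable_ks: list[int]
    k_star: int
    labels: np.ndarray
    hierarchy: stab_mod.HierarchyTree | None
    enrichment: pd.DataFrame | None
    clinical: pd.DataFrame | None
    event_labels: events_mod.EventLabels | None
    risk: pd.DataFrame | None
    network: network_mod.ProgressionNetwork
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    mentions: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    demographics: pd.DataFrame | None = None,
    bmi: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the output bundle.

    Input tables may be passed in memory or read from the paths in
    ``config``.  Any stage failure propagates with the stage named in the
    log; the manifest's funnel lets mention conservation be checked at every
    filter step.
    """
    if mentions is None:
        if config.mentions_path is None:
            raise SchemaError("no mention table: pass `mentions` or set mentions_path")
        mentions = pd.read_csv(config.mentions_path)
    if events is None and config.events_path:
        events = pd.read_csv(config.events_path)
    if demographics is None and config.demographics_path:
        demographics = pd.read_csv(config.demographics_path)
    if bmi is None and config.bmi_path:
        bmi = pd.read_csv(config.bmi_path)

    logger.info("stage: snapshot matrix")
    matrix, funnel = snap_mod.build_snapshot_matrix(
        mentions,
        bin_width=config.bin_width,
        min_mentions=config.min_mentions,
        coverage=config.vocab_coverage,
    )

    logger.info("stage: k-means sweep + stability bootstrap")
    k_lo, k_hi = config.k_range
    ks = range(k_lo, k_hi + 1)
    runs = stab_mod.run_kmeans_sweep(matrix, ks, seed=config.seed)
    profile = stab_mod.bootstrap_stability(
        matrix,
        ks,
        fd_schedule=config.fd_schedule,
        n_reps=config.n_reps,
        seed=config.seed,
        ref_runs=runs,
        compute_semantic=config.compute_semantic,
        alpha=config.alpha,
        test_method=config.test_method,
    )
    stable_ks = stab_mod.select_stable_k(profile)
    k_star = stable_ks[-1] if stable_ks else max(ks)
    labels = runs[k_star].labels

    hierarchy = None
    if len(stable_ks) >= 2:
        logger.info("stage: hierarchy over stable K %s", stable_ks)
        hierarchy = stab_mod.build_hierarchy(runs, stable_ks, m_star=k_star)
    else:
        logger.info("single stable K: hierarchy step skipped")

    logger.info("stage: characterization")
    pheno_map = characterize.load_phenotype_map(config.phenotype_map_path)
    presence = characterize.phenotype_presence(matrix, pheno_map)
    enrichment = characterize.phenotype_enrichment(presence, labels)

    event_labels = None
    risk = None
    if events is not None and len(events):
        logger.info("stage: event risk")
        event_labels = events_mod.label_events(
            matrix.rows, matrix.anchors, events, bin_width=config.bin_width
        )
        risk = events_mod.state_risk_table(labels, event_labels)

    clinical = None
    if demographics is not None:
        clinical = characterize.clinical_summary(
            matrix.rows, labels, demographics, matrix.anchors,
            bmi=bmi, event_labels=event_labels, bin_width=config.bin_width,
        )

    logger.info("stage: progression network")
    labels_df = matrix.rows.copy()
    labels_df["state"] = labels
    cooc = network_mod.cooccurrence_odds(labels_df, n_states=k_star)
    ordering = network_mod.ordering_probabilities(labels_df)
    snapshot_counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    net = network_mod.build_network(
        cooc, ordering,
        or_threshold=config.or_threshold,
        bidir_band=config.bidir_band,
        snapshot_counts=snapshot_counts,
        n_states=k_star,
    )
    net = network_mod.overlay_network_annotations(net, clinical, risk)

    manifest = {
        "seed": config.seed,
        "funnel": funnel,
        "stable_ks": stable_ks,
        "k_star": k_star,
        "n_network_edges": int(len(net.edge_table())),
    }
    result = PipelineResult(
        matrix=matrix, funnel=funnel, runs=runs, profile=profile,
        stable_ks=stable_ks, k_star=k_star, labels=labels,
        hierarchy=hierarchy, enrichment=enrichment, clinical=clinical,
        event_labels=event_labels, risk=risk, network=net, manifest=manifest,
    )
    if write:
        write_bundle(result, config)
    return result


def write_bundle(result: PipelineResult, config: PipelineConfig) -> Path:
    """Serialize the output bundle under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_echo.yaml")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    m = result.matrix
    scipy.io.mmwrite(out / "tfidf.mtx", m.tfidf)
    m.rows.assign(state=result.labels).to_csv(
        out / "snapshot_labels.tsv", sep="\t", index=False
    )
    pd.Series(m.vocabulary, name="concept_id").to_csv(
        out / "vocabulary.tsv", sep="\t", index=False
    )
    result.profile.to_tsv(out / "stability.tsv")
    if result.hierarchy is not None:
        (out / "hierarchy.nwk").write_text(result.hierarchy.to_newick())
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "phenotype_enrichment.tsv", sep="\t", index=False)
    if result.clinical is not None:
        result.clinical.to_csv(out / "clinical_summary.tsv", sep="\t", index=False)
    if result.risk is not None:
        result.risk.to_csv(out / "event_risk.tsv", sep="\t", index=False)
    result.network.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    result.network.write_graphml(out / "network.graphml")
    return out


def embed_2d(matrix, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Deterministic t-SNE embedding of the snapshots (N x 2), for cluster
    maps and event-density overlays; purely a visualization aid."""
    from sklearn.manifold import TSNE

    X = matrix.dense_tfidf() if hasattr(matrix, "dense_tfidf") else np.asarray(matrix)
    n = X.shape[0]
    if n <= perplexity:
        raise ValueError(
            f"perplexity {perplexity} requires more than {int(perplexity)} snapshots"
        )
    tsne = TSNE(n_components=2, random_state=seed, init="pca", perplexity=perplexity)
    return tsne.fit_transform(X)


def render_reports(result: PipelineResult, config: PipelineConfig) -> Path:
    """Figures and a Markdown per-state report for a completed run; see
    :mod:`ehrstates.plotting`."""
    from . import plotting

    return plotting.render_reports(result, config)
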