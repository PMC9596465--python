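"""Cluster-stability bootstrapping, stable-K selection, and the state hierarchy.

Disease states are hard K-means partitions of the snapshot matrix.  Because
K-means will happily partition anything, the number of states K is chosen by
*stability under subsampling*: for each K a reference partition is compared
with partitions of random subsamples holding a fraction ``f_d`` of the rows,
using two datapoint-weighted statistics.

The Jaccard stability of a reference partition ``C_ref`` against a
bootstrap partition ``C_boot`` of a common point set of size N is

    J = (1/N) * sum_ij  n_ij * J_ij,      J_ij = |c_i ∩ c_j| / |c_i ∪ c_j|

where ``n_ij`` is the contingency count between reference cluster i and
bootstrap cluster j.  J = 1 iff the two partitions are identical (up to
cluster relabeling).  The *semantic* analogue replaces J_ij with the overlap
of the clusters' significantly enriched complaint vocabularies,

    S_ij = |v_ref_i ∩ v_boot_j| / |v_boot_j|,

so it measures whether the clusters keep meaning the same complaints, not
just containing the same points.  K values at which the mean J over
replicates (at f_d = 0.5) is a strict local maximum are the *stable* K; the
partitions at all stable K are then combined into a complete-linkage
dendrogram over the finest stable partition's clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: geometric subsampling schedule 0.5 * 2^-m, m = 0..6
DEFAULT_FD_SCHEDULE = tuple(0.5 * 2.0**-m for m in range(7))
DEFAULT_N_REPS = 1000
DEFAULT_K_RANGE = range(2, 31)


@dataclass
class ClusteringRun:
    """A hard partition of the snapshots for one K."""

    K: int
    labels: np.ndarray
    centroids: np.ndarray
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        if len(np.unique(self.labels)) != self.K:
            logger.warning("run with K=%d produced an empty cluster", self.K)


def _as_matrix(matrix) -> np.ndarray:
    """Accept a SnapshotMatrix or a plain array."""
    if hasattr(matrix, "dense_tfidf"):
        return matrix.dense_tfidf()
    return np.asarray(matrix, dtype=np.float64)


def run_kmeans_sweep(
    matrix,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    n_init: int = 10,
) -> dict[int, ClusteringRun]:
    """Reference K-means partitions for every K in ``k_range``.

    Uses k-means++ initialization with ``n_init`` restarts, keeping the best
    inertia.  On unit-L2 TF-IDF rows Euclidean K-means is equivalent to
    cosine-based clustering up to a monotone transform of the distance.
    """
    X = _as_matrix(matrix)
    ks = sorted(set(int(k) for k in k_range))
    if ks and ks[0] < 2:
        raise ValueError("K must be at least 2")
    if ks and ks[-1] >= X.shape[0]:
        raise ValueError("K must be smaller than the number of snapshots")
    runs: dict[int, ClusteringRun] = {}
    ss = np.random.SeedSequence(seed)
    for k, child in zip(ks, ss.spawn(len(ks))):
        rs = int(child.generate_state(1)[0] % (2**31))
        km = KMeans(n_clusters=k, n_init=n_init, random_state=rs).fit(X)
        runs[k] = ClusteringRun(
            K=k,
            labels=km.labels_.astype(np.int32),
            centroids=km.cluster_centers_,
            seed=rs,
            inertia=float(km.inertia_),
        )
    return runs


def _contingency(ref_labels: np.ndarray, boot_labels: np.ndarray) -> np.ndarray:
    ref_labels = np.asarray(ref_labels)
    boot_labels = np.asarray(boot_labels)
    if ref_labels.shape != boot_labels.shape:
        raise ValueError(
            "reference and bootstrap labels must cover the same point set"
        )
    if ref_labels.size == 0:
        raise ValueError("empty common point set")
    n_i = ref_labels.max() + 1
    n_j = boot_labels.max() + 1
    n = np.zeros((n_i, n_j), dtype=np.int64)
    np.add.at(n, (ref_labels, boot_labels), 1)
    return n


def jaccard_stability(ref_labels, boot_labels) -> float:
    """Datapoint-weighted mean pairwise Jaccard overlap between partitions.

    Both label arrays must be aligned on the same (sub)sampled point set.
    Invariant to relabeling of clusters in either argument; equals 1 iff the
    partitions coincide.
    """
    n = _contingency(ref_labels, boot_labels)
    N = n.sum()
    a = n.sum(axis=1, keepdims=True)  # reference cluster sizes
    b = n.sum(axis=0, keepdims=True)  # bootstrap cluster sizes
    union = a + b - n
    with np.errstate(invalid="ignore", divide="ignore"):
        jij = np.where(union > 0, n / union, 0.0)
    return float((n * jij).sum() / N)


def semantic_stability(
    ref_vocabs: dict[int, set],
    boot_vocabs: dict[int, set],
    ref_labels,
    boot_labels,
) -> float:
    """Datapoint-weighted overlap of significant complaint vocabularies.

    ``S_ij = |v_ref_i ∩ v_boot_j| / |v_boot_j|``; a bootstrap cluster with
    an empty significant vocabulary contributes ``S_ij = 0`` (no evidence of
    semantic agreement).
    """
    if ref_vocabs is None or boot_vocabs is None:
        raise ValueError("significant vocabularies are required for both runs")
    n = _contingency(ref_labels, boot_labels)
    N = n.sum()
    s = 0.0
    empty_seen = False
    for i in range(n.shape[0]):
        vi = ref_vocabs.get(i, set())
        for j in range(n.shape[1]):
            if n[i, j] == 0:
                continue
            vj = boot_vocabs.get(j, set())
            if not vj:
                empty_seen = True
                continue
            s += n[i, j] * len(vi & vj) / len(vj)
    if empty_seen:
        logger.debug("bootstrap cluster with empty significant vocabulary: S_ij=0")
    return float(s / N)


@dataclass
class StabilityProfile:
    """Tidy per-replicate stability values with summary helpers."""

    values: pd.DataFrame  # columns: K, f_d, replicate, J, S (S may be NaN)
    n_reps: int
    fd_schedule: tuple[float, ...]
    k_values: tuple[int, ...]

    def summary(self, statistic: str = "mean") -> pd.DataFrame:
        """Per-(K, f_d) summary of J and S (mean by default, median optional)
        with 5-95% corridors."""
        g = self.values.groupby(["K", "f_d"])
        out = g.agg(
            J=("J", statistic),
            S=("S", statistic),
            J_lo=("J", lambda x: x.quantile(0.05)),
            J_hi=("J", lambda x: x.quantile(0.95)),
        ).reset_index()
        return out

    def mean_j(self, f_d: float, statistic: str = "mean") -> pd.Series:
        sub = self.values[np.isclose(self.values["f_d"], f_d)]
        if sub.empty:
            raise ValueError(f"profile has no f_d = {f_d}")
        return sub.groupby("K")["J"].agg(statistic)

    def mean_s(self, f_d: float, statistic: str = "mean") -> pd.Series:
        sub = self.values[np.isclose(self.values["f_d"], f_d)]
        if sub.empty:
            raise ValueError(f"profile has no f_d = {f_d}")
        return sub.groupby("K")["S"].agg(statistic)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index=False)


def bootstrap_stability(
    matrix,
    k_range=DEFAULT_K_RANGE,
    fd_schedule=DEFAULT_FD_SCHEDULE,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    ref_runs: dict[int, ClusteringRun] | None = None,
    compute_semantic: bool = True,
    alpha: float = 0.05,
    boot_n_init: int = 2,
    ref_n_init: int = 10,
    test_method: str = "ranksum",
) -> StabilityProfile:
    """Subsampling bootstrap of J (and optionally S) over a (K, f_d) grid.

    For each replicate, ``floor(f_d * N)`` rows are sampled *without*
    replacement, K-means is re-run on the subsample, and the statistics are
    computed against the reference partition restricted to the sampled rows
    (the only restriction under which the contingency counts are well
    defined).  Cells whose subsample would be smaller than K are skipped
    with a warning.
    """
    from .characterize import significant_vocabularies

    X = _as_matrix(matrix)
    N = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if ref_runs is None:
        ref_runs = run_kmeans_sweep(X, ks, seed=seed, n_init=ref_n_init)
    ref_vocabs: dict[int, dict[int, set]] = {}
    if compute_semantic:
        for k in ks:
            ref_vocabs[k] = significant_vocabularies(
                X, ref_runs[k].labels, alpha=alpha, method=test_method
            )
    ss = np.random.SeedSequence(seed + 1)
    rng = np.random.default_rng(ss)
    records = []
    for k in ks:
        ref = ref_runs[k]
        for f_d in fd_schedule:
            n_sub = int(np.floor(f_d * N))
            if n_sub < k:
                logger.warning(
                    "skipping K=%d, f_d=%g: subsample of %d rows is smaller "
                    "than K", k, f_d, n_sub,
                )
                continue
            for rep in range(n_reps):
                idx = rng.choice(N, size=n_sub, replace=False)
                rs = int(rng.integers(0, 2**31))
                km = KMeans(n_clusters=k, n_init=boot_n_init, random_state=rs)
                boot_labels = km.fit_predict(X[idx])
                j = jaccard_stability(ref.labels[idx], boot_labels)
                s = np.nan
                if compute_semantic:
                    boot_vocabs = significant_vocabularies(
                        X[idx], boot_labels, alpha=alpha, method=test_method
                    )
                    s = semantic_stability(
                        ref_vocabs[k], boot_vocabs, ref.labels[idx], boot_labels
                    )
                records.append((k, f_d, rep, j, s))
    values = pd.DataFrame(records, columns=["K", "f_d", "replicate", "J", "S"])
    return StabilityProfile(
        values=values,
        n_reps=n_reps,
        fd_schedule=tuple(fd_schedule),
        k_values=tuple(ks),
    )


def _local_maxima(series: pd.Series) -> list[int]:
    """Strict local maxima over the K grid; endpoints compare one-sided."""
    ks = list(series.index)
    vals = series.to_numpy()
    out = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or vals[i] > vals[i - 1]
        right_ok = i == len(ks) - 1 or vals[i] > vals[i + 1]
        if left_ok and right_ok:
            out.append(int(k))
    return out


def select_stable_k(
    profile: StabilityProfile,
    f_d: float = 0.5,
    statistic: str = "mean",
    strict: bool = False,
) -> list[int]:
    """Stable cluster counts: strict local maxima of the summary J at
    ``f_d`` (0.5 by default).

    With ``strict=True``, K must additionally be a local maximum of the
    semantic statistic S at the same f_d and a J local maximum at every
    smaller f_d present in the profile (persistence of the maximum as data
    shrinks).
    """
    mean_j = profile.mean_j(f_d, statistic)
    stable = set(_local_maxima(mean_j))
    if strict:
        mean_s = profile.mean_s(f_d, statistic)
        if mean_s.notna().any():
            stable &= set(_local_maxima(mean_s))
        for fd2 in profile.fd_schedule:
            if fd2 < f_d - 1e-12:
                sub = profile.values[np.isclose(profile.values["f_d"], fd2)]
                if sub.empty:
                    continue
                stable &= set(_local_maxima(sub.groupby("K")["J"].agg(statistic)))
    return sorted(stable)


@dataclass
class HierarchyTree:
    """Complete-linkage dendrogram over the finest stable partition.

    ``linkage`` is a scipy linkage matrix over the ``m_star`` fine clusters;
    ``split_k`` annotates each merge (internal node, indexed as in the
    linkage matrix) with the smallest stable K at which its two branches
    map to different coarse clusters, i.e. the K at which the split first
    appears.
    """

    linkage: np.ndarray
    leaf_ids: list[int]
    m_star: int
    split_k: dict[int, int | None] = field(default_factory=dict)
    distance_matrix: np.ndarray | None = None

    def merge_order(self) -> list[tuple[set, set]]:
        """Leaf sets joined at each merge, in merge order."""
        members: dict[int, set] = {i: {i} for i in range(self.m_star)}
        out = []
        for step, (a, b, _, _) in enumerate(self.linkage):
            sa, sb = members[int(a)], members[int(b)]
            out.append((sa, sb))
            members[self.m_star + step] = sa | sb
        return out

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from the linkage heights."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(
            self.linkage, [f"state_{i}" for i in self.leaf_ids]
        )
        return str(tree)


def cross_k_distance(
    fine_labels: np.ndarray, coarse_labels: np.ndarray
) -> np.ndarray:
    """Pairwise distances between fine clusters through a coarser partition.

    Each fine cluster is profiled by its vector of Jaccard indices against
    the coarse clusters; fine clusters that dissolve into the same coarse
    clusters get similar profiles.  The distance is the Euclidean distance
    between profiles.
    """
    n = _contingency(fine_labels, coarse_labels).astype(float)
    a = n.sum(axis=1, keepdims=True)
    b = n.sum(axis=0, keepdims=True)
    union = a + b - n
    with np.errstate(invalid="ignore", divide="ignore"):
        jij = np.where(union > 0, n / union, 0.0)
    diff = jij[:, None, :] - jij[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def build_hierarchy(
    runs: dict[int, ClusteringRun],
    stable_ks: list[int],
    m_star: int | None = None,
) -> HierarchyTree:
    """Cross-K dendrogram over the clusters of the finest stable K.

    For each coarser stable K the fine clusters are compared through the
    cluster-pair Jaccard matrix; the resulting distance matrices are
    averaged over all coarser stable K and agglomerated with complete
    linkage.
    """
    stable_ks = sorted(set(int(k) for k in stable_ks))
    if len(stable_ks) < 2:
        raise ValueError("hierarchy undefined: need at least 2 stable K values")
    if m_star is None:
        m_star = stable_ks[-1]
    coarser = [k for k in stable_ks if k < m_star]
    fine = runs[m_star].labels
    dists = [cross_k_distance(fine, runs[k].labels) for k in coarser]
    D = np.mean(dists, axis=0)
    condensed = D[np.triu_indices(m_star, k=1)]
    Z = sch.linkage(condensed, method="complete")

    # annotate each merge with the K at which the split first appears
    dominant: dict[int, np.ndarray] = {}
    for k in coarser:
        n = _contingency(fine, runs[k].labels)
        dominant[k] = n.argmax(axis=1)  # fine cluster -> dominant coarse cluster
    split_k: dict[int, int | None] = {}
    members: dict[int, set] = {i: {i} for i in range(m_star)}
    for step, (a, b, _, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        members[m_star + step] = sa | sb
        found = None
        for k in coarser:
            da = {int(dominant[k][i]) for i in sa}
            db = {int(dominant[k][i]) for i in sb}
            if da.isdisjoint(db):
                found = k
                break
        split_k[step] = found if found is not None else m_star
    return HierarchyTree(
        linkage=Z,
        leaf_ids=list(range(m_star)),
        m_star=m_star,
        split_k=split_k,
        distance_matrix=D,
    )
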