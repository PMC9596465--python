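"""From complaint mentions to the snapshot-by-complaint matrix.

The clustering unit of the whole pipeline is the *snapshot*: all positively
mentioned complaints of one patient aggregated inside one 30-day window,
anchored at the patient's first mention.  This module implements the four
preparation steps — polarity filtering, 30-day binning, cohort exclusion
(any patient with a snapshot below a minimum mention count is dropped
entirely), and frequency-based vocabulary truncation — followed by
log-TF / smoothed-IDF vectorization with L2 row normalization, yielding the
``N x V`` matrix ``P`` that downstream clustering consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from ._exceptions import EmptyCohortError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_MENTION_COLUMNS = ("patient_id", "timestamp", "concept_id", "polarity")

#: default 30-day bin width, in days
DEFAULT_BIN_WIDTH = 30
#: default patient-level exclusion threshold: any snapshot with fewer
#: mentions than this removes the whole patient
DEFAULT_MIN_MENTIONS = 10
#: default cumulative mention-mass coverage of the truncated vocabulary
DEFAULT_VOCAB_COVERAGE = 0.99


def _timestamps_to_days(ts: pd.Series) -> np.ndarray:
    """Coerce timestamps to integer day offsets.

    Accepts integer/float day offsets directly, or ISO-8601 date strings /
    datetimes (converted to days since the Unix epoch; only differences are
    ever used downstream).
    """
    if pd.api.types.is_numeric_dtype(ts):
        return ts.to_numpy().astype(np.int64)
    parsed = pd.to_datetime(ts, errors="coerce", format="mixed")
    bad = parsed.isna()
    if bad.any():
        first = ts.index[bad][0]
        raise SchemaError(
            f"unparseable timestamp {ts.loc[first]!r} at row {first}"
        )
    return (parsed.astype("int64") // (86_400 * 10**9)).to_numpy()


def _check_mention_schema(mentions: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_MENTION_COLUMNS if c not in mentions.columns]
    if missing:
        raise SchemaError(f"mention table is missing columns: {missing}")


def filter_polarity(mentions: pd.DataFrame) -> pd.DataFrame:
    """Keep only positive-polarity mentions, preserving row order.

    Negated complaints ("no evidence of heart failure") carry no information
    about what the patient *has* and are removed before binning.
    """
    if "polarity" not in mentions.columns:
        raise SchemaError("mention table is missing the 'polarity' column")
    keep = mentions["polarity"].astype(str).str.lower().isin(("pos", "positive"))
    return mentions.loc[keep]


@dataclass
class SnapshotCounts:
    """Long-format snapshot counts plus per-patient bin anchors.

    Attributes
    ----------
    counts
        One row per (patient_id, bin_index, concept_id) with the aggregated
        mention ``count`` in that 30-day bin.
    anchors
        Per-patient day offset of the first mention; bin ``b`` spans days
        ``[anchor + b*bin_width, anchor + (b+1)*bin_width)``.
    bin_width
        Bin width in days.
    """

    counts: pd.DataFrame
    anchors: pd.Series
    bin_width: int = DEFAULT_BIN_WIDTH

    def totals(self) -> pd.DataFrame:
        """Per-snapshot mention totals (patient_id, bin_index, mention_total)."""
        return (
            self.counts.groupby(["patient_id", "bin_index"], sort=True)["count"]
            .sum()
            .rename("mention_total")
            .reset_index()
        )


def bin_snapshots(
    mentions: pd.DataFrame, bin_width: int = DEFAULT_BIN_WIDTH
) -> SnapshotCounts:
    """Aggregate positive mentions into per-patient 30-day snapshots.

    Bins are half-open ``[start, start + bin_width)`` day windows anchored at
    each patient's first mention, so the bin index is
    ``floor((t - t_first) / bin_width)``.  Windows in which a patient has no
    mentions simply yield no snapshot.
    """
    _check_mention_schema(mentions)
    if mentions.empty:
        raise EmptyCohortError("no mentions left after filtering")
    m = mentions[["patient_id", "concept_id"]].copy()
    if (m["concept_id"].astype(str) == "").any():
        raise SchemaError("empty concept_id encountered")
    m["day"] = _timestamps_to_days(mentions["timestamp"])
    anchors = m.groupby("patient_id")["day"].min().rename("anchor")
    m = m.join(anchors, on="patient_id")
    m["bin_index"] = (m["day"] - m["anchor"]) // bin_width
    counts = (
        m.groupby(["patient_id", "bin_index", "concept_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return SnapshotCounts(counts=counts, anchors=anchors, bin_width=bin_width)


def apply_cohort_exclusion(
    snapshots: SnapshotCounts,
    min_mentions: int = DEFAULT_MIN_MENTIONS,
    patient_level: bool = True,
) -> tuple[SnapshotCounts, pd.DataFrame]:
    """Drop sparse snapshots and, by default, their entire patients.

    A patient with *any* snapshot holding fewer than ``min_mentions``
    mentions is removed with all of their snapshots (the boundary is strict:
    exactly ``min_mentions`` mentions is kept).  With
    ``patient_level=False`` only the offending snapshots are dropped.

    Returns the retained snapshots and an exclusion report listing each
    excluded patient with the reason.
    """
    totals = snapshots.totals()
    if totals.empty:
        raise EmptyCohortError("empty cohort: no snapshots to filter")
    sparse = totals[totals["mention_total"] < min_mentions]
    if patient_level:
        bad_patients = sparse["patient_id"].unique()
        keep = ~snapshots.counts["patient_id"].isin(bad_patients)
        report = (
            sparse.groupby("patient_id")["mention_total"]
            .min()
            .rename("min_snapshot_mentions")
            .reset_index()
        )
        report["reason"] = f"snapshot with < {min_mentions} mentions"
    else:
        bad_keys = set(zip(sparse["patient_id"], sparse["bin_index"]))
        keys = list(zip(snapshots.counts["patient_id"], snapshots.counts["bin_index"]))
        keep = ~pd.Series([k in bad_keys for k in keys], index=snapshots.counts.index)
        report = sparse.rename(columns={"mention_total": "min_snapshot_mentions"}).copy()
        report["reason"] = f"snapshot with < {min_mentions} mentions (snapshot-level)"
    kept = snapshots.counts.loc[keep]
    if kept.empty:
        raise EmptyCohortError("empty cohort: every patient was excluded")
    kept_anchors = snapshots.anchors[
        snapshots.anchors.index.isin(kept["patient_id"].unique())
    ]
    return (
        SnapshotCounts(kept.reset_index(drop=True), kept_anchors, snapshots.bin_width),
        report,
    )


def truncate_vocabulary(
    snapshots: SnapshotCounts,
    coverage: float = DEFAULT_VOCAB_COVERAGE,
    mode: str = "mass",
) -> list[str]:
    """Restrict the vocabulary to the most frequent complaints.

    ``mode="mass"`` (default) returns the smallest prefix of complaints,
    sorted by descending total mention count (ties broken lexicographically),
    whose cumulative mention count reaches ``coverage`` of all mentions.
    Under the power-law frequency distribution typical of clinical concepts
    this removes a long tail of rare terms.  ``mode="rank"`` instead keeps
    the top ``coverage`` fraction of *concepts* by rank.
    """
    if snapshots.counts.empty:
        raise EmptyCohortError("empty cohort: no snapshots")
    freq = (
        snapshots.counts.groupby("concept_id")["count"]
        .sum()
        .reset_index()
        .sort_values(["count", "concept_id"], ascending=[False, True])
    )
    if mode == "rank":
        n_keep = max(1, int(np.ceil(coverage * len(freq))))
        return freq["concept_id"].head(n_keep).tolist()
    if mode != "mass":
        raise ValueError(f"unknown truncation mode {mode!r}")
    cum = freq["count"].cumsum()
    target = coverage * freq["count"].sum()
    n_keep = int(np.searchsorted(cum.to_numpy(), target - 1e-9) + 1)
    return freq["concept_id"].head(n_keep).tolist()


@dataclass
class SnapshotMatrix:
    """The ``N x V`` snapshot representation used for clustering.

    ``tfidf`` rows are unit L2 norm: entry = ``(1 + ln(count)) * idf`` with
    the smoothed inverse document frequency
    ``idf = ln((1 + N) / (1 + df)) + 1``, then row-normalized.  The raw
    ``counts`` view is retained for characterization and reporting.
    """

    rows: pd.DataFrame  # columns: patient_id, bin_index
    vocabulary: list[str]
    counts: sp.csr_matrix
    tfidf: sp.csr_matrix
    anchors: pd.Series = field(default=None, repr=False)
    bin_width: int = DEFAULT_BIN_WIDTH

    @property
    def n_snapshots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_patients(self) -> int:
        return self.rows["patient_id"].nunique()

    def dense_tfidf(self) -> np.ndarray:
        return np.asarray(self.tfidf.todense())


def vectorize(
    snapshots: SnapshotCounts,
    vocabulary: list[str],
    sublinear_tf: bool = True,
    smooth_idf: bool = True,
) -> SnapshotMatrix:
    """Build the TF-IDF snapshot matrix over a fixed vocabulary.

    Snapshots whose every complaint fell outside the vocabulary would yield
    an all-zero row that cannot be L2-normalized; they are excluded with a
    logged warning.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    c = snapshots.counts
    vocab_index = {v: i for i, v in enumerate(vocabulary)}
    in_vocab = c["concept_id"].isin(vocab_index)
    c = c.loc[in_vocab]
    if c.empty:
        raise EmptyCohortError("no in-vocabulary mentions")
    row_keys = pd.MultiIndex.from_frame(c[["patient_id", "bin_index"]])
    all_keys = pd.MultiIndex.from_frame(
        snapshots.counts[["patient_id", "bin_index"]]
    ).unique()
    kept_keys = row_keys.unique().sort_values()
    dropped = len(all_keys) - len(kept_keys)
    if dropped:
        logger.warning(
            "%d snapshots had no in-vocabulary complaints and were dropped",
            dropped,
        )
    row_codes = kept_keys.get_indexer(row_keys)
    col_codes = c["concept_id"].map(vocab_index).to_numpy()
    counts = sp.csr_matrix(
        (c["count"].to_numpy(dtype=np.float64), (row_codes, col_codes)),
        shape=(len(kept_keys), len(vocabulary)),
    )
    transformer = TfidfTransformer(
        norm="l2", use_idf=True, smooth_idf=smooth_idf, sublinear_tf=sublinear_tf
    )
    tfidf = transformer.fit_transform(counts)
    rows = pd.DataFrame(
        {"patient_id": kept_keys.get_level_values(0),
         "bin_index": kept_keys.get_level_values(1)}
    )
    return SnapshotMatrix(
        rows=rows,
        vocabulary=list(vocabulary),
        counts=counts,
        tfidf=sp.csr_matrix(tfidf),
        anchors=snapshots.anchors,
        bin_width=snapshots.bin_width,
    )


def build_snapshot_matrix(
    mentions: pd.DataFrame,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_mentions: int = DEFAULT_MIN_MENTIONS,
    coverage: float = DEFAULT_VOCAB_COVERAGE,
) -> tuple[SnapshotMatrix, dict]:
    """Convenience wrapper running the full preparation chain.

    Returns the matrix and a funnel of record counts after each stage
    (mentions in, positive mentions, patients before/after exclusion,
    vocabulary size before/after truncation, snapshots clustered).
    """
    positive = filter_polarity(mentions)
    if positive.empty:
        raise EmptyCohortError("empty cohort: no positive-polarity mentions")
    snaps = bin_snapshots(positive, bin_width=bin_width)
    n_patients_in = snaps.anchors.size
    kept, report = apply_cohort_exclusion(snaps, min_mentions=min_mentions)
    vocab_full = kept.counts["concept_id"].nunique()
    vocab = truncate_vocabulary(kept, coverage=coverage)
    matrix = vectorize(kept, vocab)
    funnel = {
        "mentions_total": int(len(mentions)),
        "mentions_positive": int(len(positive)),
        "patients_before_exclusion": int(n_patients_in),
        "patients_excluded": int(report["patient_id"].nunique()) if len(report) else 0,
        "patients_final": int(matrix.n_patients),
        "vocabulary_full": int(vocab_full),
        "vocabulary_truncated": int(len(vocab)),
        "snapshots_final": int(matrix.n_snapshots),
    }
    return matrix, funnel
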