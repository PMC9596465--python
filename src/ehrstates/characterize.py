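"""What each disease state *is*: enriched complaints, grouped phenotypes,
and clinical characteristics.

A state's distinctive complaints are found by a one-sided (greater)
comparison of each TF-IDF feature inside the cluster against all other
snapshots — rank-sum (Mann-Whitney) by default, since sparse TF-IDF columns
are far from normal; Welch's t is available.  Bonferroni correction is
applied over the feature family within each cluster's test battery, and the
surviving features form the cluster's significant vocabulary V_s.

Individual extracted complaints are far more granular than the phenotypes a
clinician reasons about, so a keyword map folds them into ~50 grouped
phenotypes (all the anemia variants match the "anemia" keyword, and so on),
for which per-state prevalence and odds ratios are reported.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
import yaml

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def _dense(matrix_or_x) -> np.ndarray:
    if hasattr(matrix_or_x, "dense_tfidf"):
        return matrix_or_x.dense_tfidf()
    if sp.issparse(matrix_or_x):
        return np.asarray(matrix_or_x.todense())
    return np.asarray(matrix_or_x, dtype=np.float64)


def _feature_pvalues_greater(
    X: np.ndarray, mask: np.ndarray, method: str = "ranksum"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided (greater) p-value per column for in-mask vs out-of-mask rows.

    Returns (statistics, p-values).  Columns constant across both groups get
    p = 1 (no evidence, not an error).
    """
    a, b = X[mask], X[~mask]
    if method == "ranksum":
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = st.mannwhitneyu(
                a, b, alternative="greater", axis=0, method="asymptotic"
            )
    elif method in ("welch", "ttest"):
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = st.ttest_ind(
                a, b, axis=0, equal_var=False, alternative="greater"
            )
    else:
        raise ValueError(f"unknown test method {method!r}")
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    constant = (a.max(axis=0) == a.min(axis=0)) & (b.max(axis=0) == b.min(axis=0)) & (
        a.max(axis=0) == b.max(axis=0)
    )
    p = np.where(np.isnan(p) | constant, 1.0, p)
    return stat, p


def test_cluster_features(
    matrix,
    labels,
    cluster: int,
    alpha: float = DEFAULT_ALPHA,
    method: str = "ranksum",
    feature_names: list[str] | None = None,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Significantly overrepresented features of one cluster.

    Tests, for every feature, the one-sided null that its TF-IDF values
    inside ``cluster`` are not stochastically greater than in the rest of
    the cohort; Bonferroni-adjusts over the feature family and returns the
    features with adjusted p < alpha, sorted by raw p ascending.
    """
    X = _dense(matrix)
    labels = np.asarray(labels)
    mask = labels == cluster
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(
            f"cluster {cluster} needs >= 2 snapshots on each side of the split"
        )
    if feature_names is None:
        feature_names = getattr(matrix, "vocabulary", None) or [
            f"f{i}" for i in range(X.shape[1])
        ]
    stat, p = _feature_pvalues_greater(X, mask, method=method)
    n_tests = X.shape[1]
    out = pd.DataFrame(
        {
            "concept_id": feature_names,
            "statistic": stat,
            "p_raw": p,
            "p_adj": np.minimum(1.0, p * n_tests),
        }
    ).sort_values(["p_raw", "concept_id"], kind="mergesort", ignore_index=True)
    out["cluster"] = cluster
    out["alpha"] = alpha
    if significant_only:
        out = out[out["p_adj"] < alpha].reset_index(drop=True)
    return out


def significant_vocabularies(
    matrix,
    labels,
    alpha: float = DEFAULT_ALPHA,
    method: str = "ranksum",
) -> dict[int, set]:
    """Per-cluster significant feature index sets (V_s), for all clusters.

    Feature *indices* (not names) are used so the result is comparable
    across runs on subsamples of the same matrix.  Clusters too small to
    test contribute an empty vocabulary.
    """
    X = _dense(matrix)
    labels = np.asarray(labels)
    n_tests = X.shape[1]
    vocabs: dict[int, set] = {}
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            vocabs[int(c)] = set()
            continue
        _, p = _feature_pvalues_greater(X, mask, method=method)
        vocabs[int(c)] = set(np.flatnonzero(p * n_tests < alpha).tolist())
    return vocabs


# ---------------------------------------------------------------------------
# grouped phenotypes


def load_phenotype_map(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the phenotype -> keyword map (YAML), ordered as declared.

    Without a path, the package's default map of 50 cardiovascular-domain
    phenotypes is used; it is a user-replaceable convention, not a clinical
    standard.
    """
    if path is None:
        text = (
            resources.files("ehrstates").joinpath("data/phenotypes.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not raw:
        raise ValueError("phenotype map is empty")
    return {str(k): [str(w) for w in v] for k, v in raw.items()}


def assign_phenotypes(
    concepts: list[str],
    pheno_map: dict[str, list[str]],
    display_names: dict[str, str] | None = None,
) -> dict[str, str | None]:
    """Map each concept to at most one phenotype by case-insensitive
    substring keyword match on its display string; on overlapping keyword
    hits the first-declared phenotype wins."""
    if not pheno_map:
        raise ValueError("phenotype map is empty")
    out: dict[str, str | None] = {}
    for cid in concepts:
        display = (display_names or {}).get(cid, cid).lower()
        hit = None
        for pheno, keywords in pheno_map.items():
            if any(kw.lower() in display for kw in keywords):
                hit = pheno
                break
        out[cid] = hit
    return out


def phenotype_presence(
    matrix,
    pheno_map: dict[str, list[str]],
    display_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Boolean snapshot x phenotype table: a snapshot has a phenotype iff
    any of its complaints maps to it."""
    assignment = assign_phenotypes(matrix.vocabulary, pheno_map, display_names)
    phenos = list(pheno_map)
    counts = matrix.counts
    presence = np.zeros((counts.shape[0], len(phenos)), dtype=bool)
    for j, pheno in enumerate(phenos):
        cols = [
            i for i, cid in enumerate(matrix.vocabulary) if assignment[cid] == pheno
        ]
        if cols:
            presence[:, j] = np.asarray(
                (counts[:, cols] > 0).sum(axis=1)
            ).ravel() > 0
    return pd.DataFrame(presence, columns=phenos)


def odds_ratio_2x2(
    n11: float, n10: float, n01: float, n00: float
) -> tuple[float, bool]:
    """Odds ratio of a 2x2 table with Haldane-Anscombe 0.5 correction when
    any cell is zero.  Returns (OR, corrected?)."""
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    n11, n10, n01, n00 = cells
    return float((n11 * n00) / (n10 * n01)), corrected


def phenotype_enrichment(
    presence: pd.DataFrame, labels
) -> pd.DataFrame:
    """Per-(cluster, phenotype) prevalence and odds ratio.

    Prevalence is the percentage of the cluster's snapshots carrying the
    phenotype; the OR comes from the 2x2 in-cluster x phenotype-present
    table over all snapshots, with the cohort-wide prevalence attached for
    comparison.
    """
    labels = np.asarray(labels)
    rows = []
    total = len(presence)
    for c in np.unique(labels):
        mask = labels == c
        n_in = int(mask.sum())
        for pheno in presence.columns:
            has = presence[pheno].to_numpy()
            n11 = int((has & mask).sum())
            n10 = int((~has & mask).sum())
            n01 = int((has & ~mask).sum())
            n00 = total - n11 - n10 - n01
            orr, corrected = odds_ratio_2x2(n11, n10, n01, n00)
            rows.append(
                {
                    "cluster": int(c),
                    "phenotype": pheno,
                    "n_snapshots": n_in,
                    "prevalence_pct": 100.0 * n11 / n_in,
                    "cohort_prevalence_pct": 100.0 * (n11 + n01) / total,
                    "odds_ratio": orr,
                    "zero_cell_corrected": corrected,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical characteristics

#: ages above 90 years are capped at this many days
AGE_CAP_DAYS = 32_872


def clinical_summary(
    rows: pd.DataFrame,
    labels,
    demographics: pd.DataFrame,
    anchors: pd.Series,
    bmi: pd.DataFrame | None = None,
    event_labels=None,
    bin_width: int = 30,
    mortality_event: str = "in_hospital_mortality",
) -> pd.DataFrame:
    """Per-state clinical characteristics.

    Age per snapshot is the patient's age (days) on first entering the
    snapshot window, capped at 32,872 days (90 years) and converted to
    years; the per-cluster median is reported.  BMI per snapshot is the mean
    of measurements falling inside the 30-day window, with the fraction of
    snapshots contributing; snapshots without a birth date or without BMI
    measurements are omitted from the respective medians.  In-hospital
    mortality prevalence uses the present-event flags when ``event_labels``
    (from :func:`ehrstates.events.label_events`) are provided.
    """
    labels = np.asarray(labels)
    df = rows.copy().reset_index(drop=True)
    df["cluster"] = labels
    demo = demographics.set_index("patient_id")
    df = df.join(demo, on="patient_id")
    missing_birth = df["birth_date"].isna()
    if missing_birth.any():
        logger.warning(
            "%d snapshots lack a birth date and are omitted from age medians",
            int(missing_birth.sum()),
        )
    anchor = df["patient_id"].map(anchors)
    start_day = anchor + df["bin_index"] * bin_width
    age_days = (start_day - df["birth_date"]).clip(upper=AGE_CAP_DAYS)
    df["age_years"] = age_days / 365.25

    if bmi is not None and len(bmi):
        b = bmi.copy()
        b["anchor"] = b["patient_id"].map(anchors)
        b = b.dropna(subset=["anchor"])
        b["bin_index"] = (b["timestamp"] - b["anchor"]) // bin_width
        snap_bmi = (
            b.groupby(["patient_id", "bin_index"])["bmi"].mean().rename("bmi_mean")
        )
        df = df.join(snap_bmi, on=["patient_id", "bin_index"])
    else:
        df["bmi_mean"] = np.nan

    mortality = np.zeros(len(df), dtype=bool)
    if event_labels is not None and mortality_event in event_labels.present.columns:
        mortality = event_labels.present[mortality_event].to_numpy()
    df["mortality"] = mortality

    out = []
    for c in np.unique(labels):
        sub = df[df["cluster"] == c]
        out.append(
            {
                "cluster": int(c),
                "n_snapshots": int(len(sub)),
                "n_patients": int(sub["patient_id"].nunique()),
                "pct_female": 100.0
                * (sub["sex"].astype(str).str.upper() == "F").mean(),
                "median_age": float(sub["age_years"].median()),
                "median_bmi": (
                    float(sub["bmi_mean"].median())
                    if sub["bmi_mean"].notna().any()
                    else float("nan")
                ),
                "bmi_fraction": float(sub["bmi_mean"].notna().mean()),
                "mortality_pct": 100.0 * float(sub["mortality"].mean()),
            }
        )
    return pd.DataFrame(out)
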