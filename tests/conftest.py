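import numpy as np
import pandas as pd
import pytest

import ehrstates as e


@pytest.fixture(scope="session")
def flat_cohort():
    """Small flat 3-state cohort used across modules."""
    spec = e.CohortSpec(
        n_patients=150, vocab_size=300, n_states=3, hierarchy=None,
        signature_lift=20.0, seed=11,
        event_rates={"in_hospital_mortality": np.array([0.0, 0.02, 0.25])},
    )
    return e.generate_cohort(spec)


@pytest.fixture(scope="session")
def flat_matrix(flat_cohort):
    matrix, funnel = e.build_snapshot_matrix(flat_cohort.mentions)
    return matrix, funnel


@pytest.fixture(scope="session")
def hier_cohort():
    """2 superclusters x 2 sibling states, for hierarchy recovery."""
    spec = e.CohortSpec(
        n_patients=300, vocab_size=400, n_states=4,
        hierarchy=((0, 1), (2, 3)), signature_lift=20.0, seed=2,
    )
    return e.generate_cohort(spec)


@pytest.fixture(scope="session")
def hier_matrix(hier_cohort):
    matrix, _ = e.build_snapshot_matrix(hier_cohort.mentions)
    return matrix


def true_snapshot_states(cohort, matrix) -> np.ndarray:
    """Ground-truth state per matrix row, aligned by (patient, bin)."""
    truth = cohort.truth.snapshot_states.set_index(["patient_id", "bin_index"])[
        "state"
    ]
    key = pd.MultiIndex.from_frame(matrix.rows[["patient_id", "bin_index"]])
    aligned = truth.reindex(key)
    assert not aligned.isna().any(), "snapshot without ground-truth state"
    return aligned.to_numpy().astype(int)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def jaccard_brute(ref_labels, boot_labels) -> float:
    """Direct double loop over all (reference, bootstrap) cluster pairs."""
    ref_labels = np.asarray(ref_labels)
    boot_labels = np.asarray(boot_labels)
    N = len(ref_labels)
    total = 0.0
    for i in np.unique(ref_labels):
        ci = set(np.flatnonzero(ref_labels == i))
        for j in np.unique(boot_labels):
            cj = set(np.flatnonzero(boot_labels == j))
            n_ij = len(ci & cj)
            if n_ij:
                total += n_ij * len(ci & cj) / len(ci | cj)
    return total / N


def semantic_brute(ref_vocabs, boot_vocabs, ref_labels, boot_labels) -> float:
    ref_labels = np.asarray(ref_labels)
    boot_labels = np.asarray(boot_labels)
    N = len(ref_labels)
    total = 0.0
    for i in np.unique(ref_labels):
        ci = set(np.flatnonzero(ref_labels == i))
        vi = ref_vocabs.get(int(i), set())
        for j in np.unique(boot_labels):
            cj = set(np.flatnonzero(boot_labels == j))
            n_ij = len(ci & cj)
            vj = boot_vocabs.get(int(j), set())
            if n_ij and vj:
                total += n_ij * len(vi & vj) / len(vj)
    return total / N


def tfidf_brute(counts: np.ndarray) -> np.ndarray:
    """Log TF, smoothed IDF, L2 rows — written straight from the formulas."""
    n, v = counts.shape
    df = (counts > 0).sum(axis=0)
    idf = np.log((1 + n) / (1 + df)) + 1
    out = np.zeros_like(counts, dtype=float)
    for i in range(n):
        for j in range(v):
            if counts[i, j] > 0:
                out[i, j] = (1 + np.log(counts[i, j])) * idf[j]
        norm = np.sqrt((out[i] ** 2).sum())
        if norm > 0:
            out[i] /= norm
    return out


def cooccurrence_brute(patient_states: dict, n_states: int) -> dict:
    """Patient-set-intersection 2x2 oracle: pair -> (n11, n10, n01, n00, OR)."""
    out = {}
    patients = list(patient_states)
    for i in range(n_states):
        for j in range(i + 1, n_states):
            has_i = {p for p in patients if i in patient_states[p]}
            has_j = {p for p in patients if j in patient_states[p]}
            n11 = len(has_i & has_j)
            n10 = len(has_i - has_j)
            n01 = len(has_j - has_i)
            n00 = len(patients) - n11 - n10 - n01
            cells = [n11, n10, n01, n00]
            if 0 in cells:
                cells = [c + 0.5 for c in cells]
            orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
            out[(i, j)] = (n11, n10, n01, n00, orr)
    return out
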