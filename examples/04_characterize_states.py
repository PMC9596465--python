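"""Characterize each discovered state: enriched complaints and clinical traits.

After clustering, each state is described by (i) its significantly
overrepresented complaints — one-sided rank-sum per TF-IDF feature against
the rest of the cohort, Bonferroni-corrected — and (ii) demographics.  On
this planted cohort the recovered vocabulary of each cluster should contain
exactly that state's signature concepts.
"""

import ehrstates as e

cohort = e.generate_cohort(
    e.CohortSpec(n_patients=200, vocab_size=300, n_states=3, hierarchy=None, seed=1)
)
matrix, _ = e.build_snapshot_matrix(cohort.mentions)
labels = e.run_kmeans_sweep(matrix, [3], seed=0)[3].labels

for c in range(3):
    sig = e.test_cluster_features(matrix, labels, c, alpha=0.05)
    top = sig["concept_id"].head(5).tolist()
    print(f"cluster {c}: {len(sig)} significant complaints; top by p: {top}")

print()
print("planted signatures for comparison:")
for s, names in cohort.truth.signatures.items():
    print(f"  state {s}: {names[:5]} ...")

clinical = e.clinical_summary(
    matrix.rows, labels, cohort.demographics, matrix.anchors, bmi=cohort.bmi
)
print()
print(clinical.round(2).to_string(index=False))
print()
print("Ages are capped at 90 y; BMI medians use only in-window measurements")
print("(bmi_fraction = share of snapshots contributing).")
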