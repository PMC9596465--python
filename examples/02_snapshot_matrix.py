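"""From raw mentions to the TF-IDF snapshot matrix.

Runs the preparation chain step by step — positive-polarity filtering,
30-day binning, the 10-mention patient exclusion, 99% vocabulary
truncation, log-TF-IDF with L2 rows — and prints the record-count funnel.
The funnel is the shape of the cohort the clustering actually sees.
"""

import numpy as np

import ehrstates as e

cohort = e.generate_cohort(
    e.CohortSpec(n_patients=200, vocab_size=300, n_states=3, hierarchy=None, seed=1)
)

positive = e.filter_polarity(cohort.mentions)
snaps = e.bin_snapshots(positive)
kept, report = e.apply_cohort_exclusion(snaps, min_mentions=10)
vocab = e.truncate_vocabulary(kept, coverage=0.99)
matrix = e.vectorize(kept, vocab)

print(f"mentions in:                 {len(cohort.mentions)}")
print(f"positive mentions:           {len(positive)}")
print(f"patients before exclusion:   {snaps.anchors.size}")
print(f"patients excluded (<10):     {report['patient_id'].nunique() if len(report) else 0}")
print(f"vocabulary before truncation:{kept.counts['concept_id'].nunique():6d}")
print(f"vocabulary after 99% mass:   {len(vocab):6d}")
print(f"snapshot matrix:             {matrix.n_snapshots} x {len(matrix.vocabulary)}")

norms = np.sqrt(np.asarray(matrix.tfidf.multiply(matrix.tfidf).sum(axis=1)))
print(f"max |row L2 norm - 1|:       {np.abs(norms - 1).max():.2e}")
print()
print("Every row is one patient-month; unit norms mean cluster distances")
print("compare complaint *profiles*, not record volumes.")
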