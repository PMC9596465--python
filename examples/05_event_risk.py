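"""Quantify present and future clinical-event risk per disease state.

Each snapshot is flagged *present* (the event fell inside its 30-day
window) or *pre-event* (it strictly precedes the patient's first
event-containing snapshot).  Per-state prevalences of the two flags give
near-term risk and future risk.  Here mortality is planted in state 2, so
present risk should peak in the cluster recovering it.
"""

import numpy as np

import ehrstates as e

cohort = e.generate_cohort(
    e.CohortSpec(
        n_patients=300, vocab_size=300, n_states=3, hierarchy=None, seed=1,
        transition_matrix=np.array(
            [[0.6, 0.1, 0.3], [0.1, 0.8, 0.1], [0.0, 0.0, 1.0]]
        ),
        event_rates={"in_hospital_mortality": np.array([0.0, 0.0, 0.25])},
    )
)
matrix, _ = e.build_snapshot_matrix(cohort.mentions)
labels = e.run_kmeans_sweep(matrix, [3], seed=0)[3].labels

event_labels = e.label_events(matrix.rows, matrix.anchors, cohort.events)
risk = e.state_risk_table(labels, event_labels)
print(risk.round(2).to_string(index=False))
print()
print("present_pct: events inside the cluster's snapshots; future_risk_pct:")
print("cluster snapshots that precede a patient's first event snapshot.")
print("The event was planted in state 2 (absorbing), entered mostly from")
print("state 0 - so one cluster dominates present risk and its upstream")
print("cluster carries the future risk.")
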