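# ehrstates

Hypothesis-free discovery of **disease states** and **progression networks**
from longitudinal EHR complaint mentions.

Chronic syndromes such as heart failure present with heterogeneous mixes of
comorbidities, symptoms, and severities that top-down classifications
(functional scores, single biomarkers) capture poorly.  `ehrstates`
implements a data-driven alternative for anyone holding a long table of
NLP-extracted clinical concept mentions (*complaints*) with timestamps and
polarity: it segments each patient's record into month-long snapshots,
clusters the snapshots into recurring disease states, characterizes each
state clinically, and assembles a directed network describing how patients
move between states over time.  A synthetic cohort generator with planted
states, hierarchy, transitions, and event enrichment provides ground truth
for validating every stage.

## The method

1. **Snapshots.**  Negative-polarity mentions are removed; positive
   mentions are aggregated into half-open 30-day bins anchored at each
   patient's first record.  Patients with any snapshot under 10 mentions
   are excluded.  The vocabulary is truncated to the most frequent
   complaints covering 99% of mention mass, and snapshots are vectorized
   as log TF, smoothed IDF, L2-normalized rows of a matrix
   `P ∈ R^(N×V)`:  `p = (1 + ln c) · (ln((1+N)/(1+df)) + 1)`, row-scaled to
   unit norm.

2. **States and K selection.**  K-means partitions `P` for K = 2…30.  For
   each K, the reference partition `C_ref` is compared with partitions of
   random subsamples holding a fraction `f_d ∈ {0.5, 0.25, …, 1/128}` of
   rows, via the datapoint-weighted Jaccard stability

   `J(C_ref, C_fd) = (1/N) Σ_i Σ_j n_ij · J_ij`, `J_ij = |c_i ∩ c_j| / |c_i ∪ c_j|`,

   and its semantic analogue `S` with
   `S_ij = |v_ref,i ∩ v_fd,j| / |v_fd,j|` over the clusters' significantly
   enriched complaint vocabularies (1000 replicates by default).  K values
   where mean J at `f_d = 0.5` is a strict local maximum are *stable*; the
   partitions at all stable K are combined into a complete-linkage
   dendrogram over the finest stable partition's clusters.

3. **Characterization.**  Per state: one-sided rank-sum (or Welch) tests
   with Bonferroni correction yield the significant complaint vocabulary
   `V_s`; a keyword map folds complaints into ~50 grouped phenotypes with
   per-state prevalence and odds ratios; demographics are summarized with
   ages capped at 90 years and BMI averaged within each 30-day window.

4. **Event risk.**  Each snapshot is flagged *present* (event inside its
   window) or *pre-event* (strictly before the patient's first
   event-containing snapshot); per-state prevalences of the flags give
   near-term and future risk.

5. **Progression network.**  Patient-level co-occurrence odds ratios
   `OR_ij = (n_ij · n_¬i¬j)/(n_i¬j · n_¬ij)` (Haldane-corrected, Wald 95%
   CI) combined with first-occurrence ordering probabilities `p_ij` give a
   directed graph: significant pairs with OR > 1.33 become edges, directed
   when `p_ij` leaves [0.45, 0.55], annotated with median transition times
   in 30-day bins; nodes with only outgoing (incoming) arrows are start
   (end) states.

## Worked example

`examples/` contains one narrative script per capability.  Selecting the
number of states on a cohort with a planted 2-supercluster × 2-sibling
hierarchy (`python examples/03_stability_select_k.py`) prints:

```
mean J at f_d = 0.5 (1.0 = partition fully reproducible):
  K = 2:  J = 1.000
  K = 3:  J = 0.860
  K = 4:  J = 0.949
  K = 5:  J = 0.731
  K = 6:  J = 0.551
stable K (local maxima): [2, 4]   planted truth: 2 and 4
...
merge order: [[1, 3], [0, 2], [0, 1, 2, 3]]
```

Both planted hierarchy levels appear as stability maxima — splitting two
true states (K = 3) or splitting beyond the truth (K = 5, 6) is punished —
and the dendrogram joins the planted sibling states before anything else.
The network example (`06_progression_network.py`) recovers exactly the
planted transitions 0→1, 0→2, 3→2 as directed edges with the correct
start/end labels, and `07_full_pipeline.py` runs every stage end to end and
writes the full output bundle (labels, stability table, newick tree,
GraphML network, figures, Markdown report).

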