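# Methods

## Model and assumptions

The pipeline treats a patient's record as a sequence of 30-day *snapshots*,
each summarized by the multiset of positively mentioned complaints, and
assumes that (i) recurring clinical situations leave recognizable complaint
profiles, (ii) a hard one-state-per-snapshot assignment is an acceptable
approximation (multimorbidity is expressed by which complaints co-occur
*within* a state, not by multi-assignment), and (iii) a state count K is
trustworthy only if the partition is reproducible under subsampling.  The
temporal analysis is deliberately first-order: pairwise co-occurrence and
first-occurrence ordering, not full trajectory models.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| bin width | 30 | days | clinically meaningful month-scale resolution; disease state can change month to month |
| min mentions per snapshot | 10 | mentions | patients with any sparser snapshot are removed entirely (strict `< 10`); snapshot-level dropping is available |
| vocabulary coverage | 0.99 | mention mass | smallest most-frequent concept set covering 99% of mentions; under a power-law vocabulary this removes a long rare tail. A rank-quantile mode exists |
| TF-IDF | log TF, smoothed IDF, L2 | — | `1 + ln c` damps templated/copy-pasted text; unit rows make distances compare profiles, not volumes. Both formula switches are explicit |
| K range | 2–30 | — | K = 1 is rejected; K must stay below N |
| f_d schedule | 0.5 · 2⁻ᵐ, m = 0..6 | fraction | geometric decay probes how little data still supports the partition |
| replicates | 1000 | — | reducible for desk-scale runs; subsampling is without replacement, the reference is restricted to the subsample (only way the contingency n_ij is defined) |
| α | 0.05 | — | Bonferroni family = one cluster's feature battery (|V| tests); a global family is a config option |
| enrichment test | rank-sum (greater) | — | sparse TF-IDF columns are far from normal; Welch t is switchable |
| OR edge threshold | 1.33 | — | emphasizes stronger associations in the network |
| bidirectional band | [0.45, 0.55] | ordering probability | near-ties in ordering are drawn as bidirectional arrows; their median transition annotation is the mean of the two directional medians |
| age cap | 32,872 days (90 y) | days | de-identification-style cap before computing medians |

Numerical conventions: bins are half-open `[start, start+30)` anchored at
each patient's first record and translation-invariant; truncation ties
break lexicographically; constant features get p = 1 rather than an error;
empty bootstrap vocabularies contribute S_ij = 0 (no evidence of semantic
agreement); all-zero TF-IDF rows (every complaint out of vocabulary) are
dropped with a warning since they cannot be L2-normalized; 2×2 tables with
an empty cell get the Haldane–Anscombe 0.5 correction, flagged in the
output; CIs on odds ratios are Wald on the log scale; ordering ties are
impossible under one state per snapshot and are dropped with a warning if
upstream input violates that contract.

## Stable-K selection and hierarchy

K is *stable* when mean J over replicates at f_d = 0.5 is a strict local
maximum over the examined K grid (endpoints compare one-sided).  The mean
is the default summary (median switchable); a strict mode additionally
requires an S local maximum and persistence of the J maximum at every
smaller f_d.  J-only is the default because S depends on the enrichment
test's power at small subsamples, which makes the strict mode very
conservative on small cohorts.  The hierarchy compares the finest stable
partition with each coarser stable partition through the cluster-pair
Jaccard matrix; each fine cluster is profiled by its row of Jaccard indices
and fine-cluster distances are Euclidean between profiles, averaged over
all coarser stable K, then agglomerated with complete linkage.  Each merge
is annotated with the smallest stable K at which its two branches fall in
different coarse clusters.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes:
Zipf-distributed background complaint frequencies (default exponent 1.5,
matching the heavy-tailed rank-frequency laws of clinical concept
extraction); G latent states whose disjoint signature complaint sets are
background-lifted by a multiplicative factor and renormalized; an optional
two-level hierarchy realized by a signature block shared between sibling
states; Markov state dynamics with geometric dwell via self-transitions and
absorbing end states; Poisson mention counts per bin (default mean 30, so
the 10-mention exclusion bites only occasionally); a configurable
negative-polarity fraction (default 0.1); occasional empty bins (default
rate 0.05) representing months without a visit, which exercise downstream
bin-dropping; state-dependent Bernoulli event emission; and per-state
demographics (age/sex fixed by the patient's initial state, BMI following
the current state).  Timeline lengths are a configurable distribution
(default geometric with p = 0.16, median 4 bins, matching the month-scale
medians typical of hospital-system cohorts).  Each patient's first bin
always contains a positive mention at day offset 0 so that generated bin
indices survive polarity filtering and downstream binning exactly.

What the generator does **not** emulate — and hence what passing recovery
tests cannot show: real complaint vocabularies are ontology-structured and
synonym-ridden; real states overlap far more and drift within a timeline;
visit frequency correlates with severity; documentation habits differ by
department; polarity errors are systematic, not Bernoulli.  Recovery
results certify the *machinery* (given the assumed structure, the pipeline
finds it), not clinical validity on any particular health system's data.

## Validation experiment design

Recovery conditions were fixed once: the hierarchy cohort uses 2,000
patients, 2 superclusters × 2 siblings, signature lift 20, geometric
timeline p = 0.2 (median 4 bins, ~10,000 snapshots), K ∈ [2, 6], 100
bootstrap replicates at f_d = 0.5.  The progression cohort plants a
5-state depth-1 DAG (0→1, 0→2, 3→2, state 4 isolated; fixed 6-bin
timelines; entry mix 40/15/45% at states 0/3/4) with one event emitted only
in state 1.  The DAG is depth-1 by design: co-occurrence odds ratios
necessarily mark the transitive closure of deeper chains (every patient
reaching the end of a chain passed its start), so "recovered edges equal
planted direct edges" is only a meaningful target when direct and
transitive edge sets coincide.  Calibration uses 1,000 label permutations
for the feature tests and a product-occurrence (independent Bernoulli
patient × state incidence) null for the odds ratios — Markov timelines with
random lengths are *not* a null, because timeline length confounds all
has-state indicators upward.  The stability-decay experiment uses a weaker
lift (5) so that the breakdown under shrinking f_d is visible rather than
saturated at J ≈ 1.  These problem sizes keep the whole validation battery
in the low minutes on a single CPU.

## Known limitations

K-means with Euclidean distance on unit rows approximates cosine
clustering but inherits K-means' preference for comparably sized, convex
clusters.  Wald CIs on odds ratios are asymptotic and anti-conservative for
very sparse pairs (the zero-cell flag marks where correction fired).  The
keyword-based phenotype map is substring matching, not ontology traversal;
homonyms will mis-group.  Edge significance is uncorrected across the
K(K−1)/2 pairs by default (Bonferroni switchable).  t-SNE coordinates are
a visualization aid only and carry no quantitative guarantees.
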