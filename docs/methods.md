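# Methods

## The analysis pipeline

`comorbnet` treats each inpatient as one *transaction*: the set of
3-character ICD-10 categories retained after aggregation and chapter
filtering. All downstream quantities — itemset supports, rule metrics,
co-occurrence edge weights, per-patient comorbidity counts — are functions
of these transactions, so the coding step fixes the semantics of everything
else.

### ICD-10 aggregation and exclusion

Raw codes are uppercased, stripped of whitespace and dot suffixes, and
truncated to the first letter plus two digits; anything that does not then
match `[A-Z][0-9]{2}` is rejected with the offending value. Aggregation to
3-character categories trades specificity for density: full subcategory
codes are too sparse to support itemset mining at meaningful thresholds.

The default exclusion policy removes chapters F (mental and behavioural
disorders — inconsistently screened and coded in inpatient records), S and
T plus V–Y (injuries and their external causes), and Q (congenital
conditions). The external-cause chapters V–Y are grouped with S/T because
ICD-10 files injury causation there; the policy is a configurable set of
letters and letter ranges, not baked in.

Patients whose retained category set is empty are dropped at ingestion. The
comorbidity cohort for the main analyses is patients with ≥ 2 retained
categories (`min_conditions`, configurable); the comorbidity count is the
retained-category count minus any configured index-disease codes, and by
default counts all retained categories including HIV codes — pass
`index_codes={"B20", ...}` to count strictly non-index conditions.

### WHO stage proxy

When CD4 counts are unavailable, advanced HIV disease is proxied by WHO
clinical stage 3/4 conditions in the discharge diagnoses. The
category→stage mapping ships as an editable CSV
(`comorbnet/data/who_stage_map.csv`) with an illustrative default derived
from WHO clinical staging guidance; a patient's stage is the maximum mapped
stage over their categories, 1 when nothing maps. Clinical content is
deliberately data, not code — sites should review the mapping against local
coding practice.

### Apriori mining

`mine_frequent` is a textbook level-wise Apriori: L1 from singleton counts;
level k+1 candidates formed by joining two frequent k-itemsets sharing a
(k−1)-prefix; candidates with any infrequent k-subset pruned (downward
closure); support counted with per-item transaction bitsets and intersection
popcounts. The behavioural contract is exact counts, verified against
`brute_force_frequent`, an exhaustive enumerator (guarded to ≤ 20 items)
that serves as the independent oracle in the test suite.

Rules enumerate every bipartition X → Y of each frequent itemset of size
≥ 2 — both directions, as comorbidity rule tables conventionally list them
— and keep those with confidence ≥ 0.20 and lift ≥ 1.0. The default
thresholds (support 0.20, confidence 0.20, lift 1.0, max length 4) balance
interpretability against rule explosion in ~600-category data. Conviction
at confidence 1 is reported as `inf` (the formula's pole). Table-facing
output rounds half-away-from-zero to two decimals, matching how such tables
are conventionally printed; all internal arithmetic is unrounded.

### Temporal comparison

Patients are assigned to admission periods by their *first* admission year
(default), keeping each patient in exactly one period so period patient
counts partition the cohort; `per_admission` assignment is available when
admission-level stratification is wanted. Because X → Y and Y → X always
share one support, the top-k list is built over orientation-free canonical
patterns: rules are ranked by support, canonicalized in rank order,
deduplicated, and the *deduplicated* list is cut at k = 20 — otherwise
paired directions would waste half the list. Jaccard similarity between two
periods' pattern sets is |A∩B|/|A∪B|, rejected as undefined when both sets
are empty.

### Co-occurrence networks

Edge weight(u, v) = number of transactions containing both categories, so
edge weights equal pair-itemset counts — a cross-module identity asserted in
tests. Two selection policies:

- `top_k_edges` (period networks): the k = 20 heaviest edges.
- `node_budget` (overall network): edges are added in rank order
  (descending weight, then lexicographic pair for deterministic ties);
  an edge that would push the node count past `node_max` = 34 is skipped
  and later edges still considered; addition stops once the node count
  reaches `node_min` = 24. This makes the 24–34-node budget a hard
  guarantee whenever the full graph has ≥ 24 nodes.

Betweenness centrality is computed on the unweighted retained topology
(hop-count geodesics, fractional credit across equal-length paths,
normalized by (n−1)(n−2)/2), because published hub tables report values in
[0, 1] and no weighted-path scheme is standard for co-occurrence graphs;
graphs with < 3 nodes get all zeros (degenerate normalizer). Local
clustering is likewise unweighted, with degree-< 2 nodes contributing 0.
Brandes' algorithm (via networkx) is validated against an exhaustive
path-enumeration oracle on random small graphs.

### Statistics

Comorbidity counts are summarized as median (P25, P75) using linear
interpolation (the inclusive convention; recorded in the run log since
quartile conventions differ across software). Mann–Whitney U uses midranks,
a tie-corrected normal approximation with continuity correction, and
reports the smaller of U₁/U₂. Kruskal–Wallis H uses the tie-correction
divisor 1 − ΣT/(N³−N) (scipy), with ε² = H/(N−1) as effect size. Dunn's
post-hoc z for groups i, j is

    z = (meanR_i − meanR_j) / sqrt(S · (1/n_i + 1/n_j)),
    S = N(N+1)/12 − Σ(t³−t)/(12(N−1)),

computed on the pooled midranks, with two-sided p-values Holm-adjusted
(statsmodels). A Kolmogorov–Smirnov normality check is reported in the run
log only; it gates nothing downstream. For length-of-stay-style strata with
≥ 3 groups the pipeline reports Kruskal–Wallis; U vs H pairing for ordinal
strata is ambiguous in parts of the applied literature, so the test name is
always written next to the statistic.

## The synthetic cohort generator

### Model

Noisy-OR latent blocks. Patient draws z_b ~ Bernoulli(π_b) per block; given
z, category i is present with probability

    P(i | z) = 1 − (1 − p_i) · Π_{b: z_b=1, i∈b} (1 − q_{b,i}).

This was chosen over simpler copula or mixture schemes because it plants
controllable positive pairwise *and* higher-order associations while keeping
exact closed forms for 1- and 2-item supports:

    P(i)   = 1 − (1−p_i) Π_b (1 − π_b q_{b,i})
    P(i∧j) = 1 − F_i − F_j + (1−p_i)(1−p_j) Π_b (1 − π_b (q_i + q_j − q_i q_j))

with F_i the marginal failure probability. `planted_truth` enumerates these
for all singletons and within-block pairs; a pair is *positive* when
P(i∧j) > P(i)P(j) + 1e−12. The miner's recovery of planted pairs is checked
against these closed forms, not against another simulation.

All randomness flows from one `numpy` Generator seeded by the spec's seed,
in a fixed draw order, so cohorts are byte-reproducible. Demographics
(gender, age bracket, residence) are drawn independently of the disease
process — subgroup comparisons on synthetic data should be null, which is
itself a useful check. Admission counts are shifted-geometric with mean 2;
lengths of stay are lognormal (mean ≈ 11 days); patient-level categories are
scattered uniformly across admissions.

### The default study cohort

`study_spec()` emulates the structure of a high-burden HIV inpatient
cohort: 3,000 patients, ~600 categories (25 named hubs + a long-tail filler
background p_k ≈ 0.55/(k+6) + a few excluded-chapter codes that exercise the
filter), a six-year admission mixture weighted toward 2019–2022, and four
blocks — immunosuppression (B20/B37/B99/…, π = 0.55), metabolic
(E87/E46/D64/…, π = 0.60), respiratory (J18/E87/E46/…, π = 0.25), and an
advanced-disease block (π = 0.28) spreading moderate activation across many
organ-system categories to supply the long right tail. Parameters were set
once to yield a right-skewed per-patient count with median ≈ 9 and quartiles
near 7 and 12–13, and hub prevalences ordered E87 > B20 ≈ B37 ≈ E46 ≈ D64.

What the generator does *not* emulate: real ICD-10 ontology structure
(filler codes are placeholders), coding drift across years, within-patient
correlation between admission timing and disease onset, treatment effects,
or outcome variables. Passing tests therefore demonstrate that the pipeline
recovers known planted structure under realistic sparsity and skew — not
that any clinical finding generalizes.

### Problem sizes

The test suite exercises convergence at n = 10,000 patients on small
universes, oracle equivalence on 100 random transaction sets (≤ 30
transactions, ≤ 8 items), betweenness on 50 random graphs (≤ 8 nodes), and
the end-to-end pipeline on a 1,200-patient cohort; the acceptance script
runs the full 3,000-patient default cohort. These sizes give stable
estimates (binomial s.e. < 0.01 at n = 3,000) while keeping the whole suite
in the tens of seconds.

## Numerical choices and degenerate inputs

- Support thresholding compares counts as `count ≥ min_support·n − 1e−9`
  to avoid float-boundary misclassification.
- Rule/ranking ties break deterministically: descending support, descending
  lift, then lexicographic antecedent/consequent.
- Itemsets of size 1 are mined (rule metrics need them) but excluded from
  pattern-facing outputs, which start at pairs.
- conviction = ∞ serialized as `inf` in CSV.
- Empty inputs are rejected with stage-labeled errors (`read:`, `ingest:`,
  `cohort:`); the pipeline writes nothing until every stage has succeeded,
  so failed runs leave no partial bundles.
- Pipeline outputs use a fixed float format (`%.10g`), making repeat runs
  byte-identical.

## Known limitations

- Admission-level transactions attribute each diagnosis to a single
  admission (the generator scatters patient-level categories), so
  admission-level supports are not a validated emulation target; the
  patient-level path is the primary, tested route.
- Rule significance is threshold-based, as is conventional for Apriori
  screens; no multiplicity-corrected inference is attached to individual
  rules (Holm adjustment applies to the Dunn post-hoc family only).
- The WHO stage map is illustrative; stage tallies on synthetic data have
  no clinical meaning.
- Betweenness ignores edge weights by design; with weighted geodesics the
  hub ranking could differ.
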