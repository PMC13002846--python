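# comorbnet

Comorbidity pattern mining and disease co-occurrence network analysis for
inpatient ICD-10 diagnosis data.

People living with HIV on long-term antiretroviral therapy accumulate
substantial comorbidity: opportunistic infections, metabolic and nutritional
disorders, and organ-system complications that co-occur in characteristic
combinations and shift over time. `comorbnet` turns raw inpatient diagnosis
records into an analysis of those combinations: which diseases cluster
together, how strongly, how the patterns change across admission periods,
and which diseases sit at the hub of the co-occurrence network. It is aimed
at epidemiologists and clinical data scientists working with hospital EHR
extracts, and ships a synthetic cohort generator with closed-form ground
truth so every stage of the pipeline can be validated analytically.

## What it computes

**Coding.** Raw ICD-10 codes are aggregated to 3-character categories
(letter + two digits, `B20.7 → B20`), chapter-level exclusions are applied
(mental disorders F, injuries/external causes S, T, V–Y, congenital Q by
default), and each patient becomes one *transaction*: the set of retained
categories across their admissions.

**Association rules.** Frequent itemsets are mined with a from-scratch
level-wise Apriori (candidate generation by prefix join, pruning by downward
closure), then every bipartition X → Y of each frequent itemset is scored
with the five standard metrics:

- support `s = P(X ∪ Y)`
- confidence `c = s / s_X`
- lift `L = s / (s_X · s_Y)` (1 = independence, > 1 = positive association)
- leverage `s − s_X · s_Y`
- conviction `(1 − s_Y) / (1 − c)` (∞ for perfect implication)

Default thresholds: support ≥ 0.20, confidence ≥ 0.20, lift ≥ 1.0, itemsets
of at most 4 diseases.

**Temporal comparison.** Patients are stratified into admission periods
(2019–2020, 2021–2022, 2023–2024 by default), rules are mined per period,
X → Y and Y → X are merged into one orientation-free pattern, and period
pairs are compared by the Jaccard similarity `|A ∩ B| / |A ∪ B|` of their
top-20 support-ranked pattern sets.

**Networks.** Diseases are nodes; an edge's weight is the number of patients
in whom both diseases co-occur. The overall network adds ranked edges until
it holds 24–34 nodes; period networks keep the top-20 edges by weight. Node
metrics are degree, weighted degree and normalized betweenness centrality;
network metrics are density, average weighted degree and mean local
clustering. Networks export to Gephi-compatible GEXF, GraphML, or CSV.

**Statistics.** Comorbidity counts are summarized as median (P25, P75);
binary subgroups are compared with Mann–Whitney U, multi-group comparisons
use Kruskal–Wallis H with ε² = H/(N−1) effect size and Dunn's post-hoc z
tests under Holm adjustment.

**Synthetic cohorts.** A noisy-OR latent-block generator: patient joins
block *b* with probability π_b, and category *i* is then present with
probability `1 − (1−p_i) · Π_{b active} (1−q_{b,i})`. One- and two-item
supports have exact closed forms, so planted associations are recoverable
targets, not guesses.

## Worked example

```python
from comorbnet import (
    study_spec, generate_cohort, build_transactions, mine_rules,
    rank_rules, summarize_distribution, cooccurrence_edges, build_network,
    EdgeSelectionPolicy,
)

spec = study_spec(n_patients=3000, seed=7)
records = generate_cohort(spec)
dist = summarize_distribution([len(r.categories) for r in records])
print(f"median comorbidities: {dist.median:.0f} (IQR {dist.p25:.0f}-{dist.p75:.0f})")

transactions = build_transactions(records)
rules = mine_rules(transactions)
print(f"{len(rules.rules)} association rules pass the thresholds")
for r in rank_rules(rules, key="lift", k=3):
    print(f"  {'+'.join(r.antecedent)} -> {'+'.join(r.consequent)}: "
          f"support={r.support:.2f} confidence={r.confidence:.2f} lift={r.lift:.2f}")

net = build_network(cooccurrence_edges(transactions), EdgeSelectionPolicy(mode="node_budget"))
top = net.nodes.iloc[0]
print(f"network: {net.summary.n_nodes} nodes, density {net.summary.density:.2f}; "
      f"hub {top.category} (weighted degree {top.weighted_degree:.0f})")
```

prints

```
median comorbidities: 9 (IQR 7-12)
66 association rules pass the thresholds
  B20 -> B99: support=0.25 confidence=0.42 lift=1.25
  B99 -> B20: support=0.25 confidence=0.74 lift=1.25
  B37 -> B99: support=0.24 confidence=0.42 lift=1.25
network: 24 nodes, density 0.30; hub E87 (weighted degree 14775)
```

The synthetic cohort's severely immunosuppressed block makes HIV-related
infections (B20), candidiasis (B37) and bacterial infection (B99) co-occur
beyond independence — the miner surfaces exactly those rules with lift > 1
— and electrolyte disorders (E87), the most prevalent category, sits at the
hub of the co-occurrence network.

The same analysis runs from the shell:

```
comorbnet simulate --n 3000 --seed 7 --out cohort.csv
comorbnet run --config pipeline.yaml
comorbnet mine --transactions txns.csv --min-support 0.2
```

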