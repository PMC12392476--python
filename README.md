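# symmine

Association-rule mining of clinical symptom cohorts: which symptoms,
*in combination*, mark patients who carry a binary outcome such as
early-stage diabetes?

Single-symptom screens miss combination effects: a symptom that is
unremarkable alone (low prevalence, or a non-significant chi-square
against the outcome) can be strongly informative when it co-occurs with
others. `symmine` treats each patient as a *transaction* — the set of
their present symptom indicators — and mines outcome-targeted
association rules `A → B` with a from-scratch Apriori, scored by the
three classical metrics:

- **support**(A → B) = |transactions ⊇ A ∪ {B}| / N — how common the
  combination is;
- **confidence**(A → B) = support(A ∪ {B}) / support(A) — the outcome
  frequency among patients showing the antecedent;
- **lift**(A → B) = confidence(A → B) / support({B}) — the multiplier
  over the outcome base rate (>1 positive association, =1 independence,
  <1 negative association).

Rules are filtered on support and confidence (defaults 3% / 60%); lift
is reported but never thresholded. Around the miner sits a full
pipeline: CSV ingestion of Yes/No-style cohort files, strict-boundary
dichotomization of continuous covariates (age), pre-mining screens
(frequency descriptives, 2×2 chi-square without continuity correction,
rank-based ROC cutoff selection by Youden's J, pooled-variance group
means), order-stratified rule tables, and a synthetic-cohort generator
with a deterministic 520-patient reference fixture whose sixteen
symptom × outcome contingency tables match a published early-diabetes
screen cell for cell.

## Worked example

Write the reference fixture and run the full pipeline on it:

```sh
symmine fixture --out fixture.csv
symmine run fixture.csv --out-dir out --max-order 2
```

`out/rules_order2.tsv` then begins:

```
LHS	RHS	supp	conf	lift
Polyuria=1	Diabetes=1	0.47	0.94	1.53
Polydipsia=1	Diabetes=1	0.43	0.97	1.57
weakness=1	Diabetes=1	0.42	0.71	1.16
partial.paresis=1	Diabetes=1	0.37	0.86	1.39
Polyphagia=1	Diabetes=1	0.36	0.80	1.30
```

Read the top row as: 47% of all 520 patients show both polyuria and a
positive outcome; 94% of polyuria-positive patients are outcome
positive; and polyuria raises the outcome probability 1.53-fold over
the 61.5% base rate. Alopecia yields no rule at all — its 44%
confidence sits below the 60% floor — while itching is kept at lift
0.99, i.e. essentially independent of the outcome despite passing both
thresholds. A rule with confidence 1.00 against this base rate attains
the ceiling lift of 1/(320/520) = 1.625 → 1.63.

`out/frequency.tsv` and `out/screen.tsv` carry the descriptives and the
per-symptom 2×2 chi-square screen; `out/manifest.json` records the
configuration, input checksum and library versions of the run. The same
stages are available as library functions (`read_cohort`,
`frequency_table`, `screen_table`, `mine_rules`, `stratify_rules`, …)
and as the `screen`, `mine`, `simulate` and `fixture` subcommands.

Only the fixture's *pairwise* (symptom, outcome) tables are faithful to
the published screen; joint distributions of three or more symptoms are
construction artifacts — see `docs/methods.md`.

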