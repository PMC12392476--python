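# Methods

## Data model

A cohort is a patient × variable table of binary indicators with one
designated outcome column; continuous covariates (age in years) ride
alongside until dichotomized. String-token files in the common survey
dialect (Yes/No, Male/Female, Positive/Negative) are mapped to {0, 1}
on read — women code as 1, being the outcome-enriched stratum — and
the canonical on-disk form is 0/1 CSV. Missing cells and unmapped
tokens are hard errors: the ingestion layer never imputes, because the
downstream counting statistics have no principled way to absorb silent
imputation.

For mining, each patient becomes the set of `"<Variable>=1"` tokens for
their present indicators. Only presence tokens are emitted by default:
outcome-targeted rules are built from present symptoms, and absence
items would double the item universe while contributing nothing to
that question. They remain available behind `include_absence` for
exploratory use. All-zero rows become empty transactions but still
count toward N, since support is a fraction of all patients.

## Pre-mining screens

**Frequency table.** Count, percent of cohort, and percent within
outcome-positives for every indicator, half-up rounded to one decimal
for display.

**2×2 chi-square.** Pearson's X² on each symptom × outcome table with
df = 1 and *no* Yates continuity correction. The uncorrected statistic
is the one that reproduces the reference screen's printed p-values from
its printed counts (genital thrush 0.012, obesity 0.1); a regression
test pins this choice. A zero margin raises rather than returning a
conventional value. No multiple-testing adjustment is applied across
the sixteen screens — the screen is descriptive, not confirmatory.

**ROC cutoff.** The AUC is the Mann–Whitney probability
P(score⁺ > score⁻) with ties counted ½; its p-value (AUC = 0.5) comes
from the tie-corrected normal approximation to the rank statistic,
without continuity correction. The cutoff is the midpoint between
adjacent distinct score values maximizing Youden's J = sensitivity +
specificity − 1, ties resolving to the smallest candidate so output is
deterministic; positive classification means score > cutoff.

**Age boundary.** Dichotomization is strict (`value > cutoff`), and the
pipeline's default age cutoff is 46.5, so 47-year-olds code positive.
The reference analysis reports an ROC cutpoint of 47.5 yet labels its
positive stratum "47+" with a 260/260 split; these two statements put
47-year-olds on opposite sides. We follow the printed group sizes (47
is positive) and flag the inconsistency here rather than resolving it.

**Group means.** Two-sample pooled-variance t-test (the reference
report shows equal SDs in both groups and names no variant); a zero
pooled SD or a group smaller than 2 raises.

## Apriori miner

Transactions are bitmask integers (bit j set when transaction j holds
the item), so itemset support is a bitwise AND plus a popcount — this
keeps even exhaustive enumeration cheap at cohort scale. Level k
candidates come from the classical prefix join of frequent (k−1)-sets
sharing their first k−2 items under canonical (sorted) order, pruned
when any (k−1)-subset is infrequent, then support-counted and filtered.
Anti-monotonicity (support never grows as items are added) guarantees
completeness and is property-tested.

Rules fix the consequent to one configured target item (the
outcome-positive token); a general any-consequent mode exists behind
`target=None`. Rule support is the support of the *union*
antecedent ∪ consequent, which is what the reference tables' `supp`
column contains (verifiable arithmetically from their 2×2 counts), not
the antecedent-only support. Metrics are computed from integer counts
(lift as `count(A∪B)·N / (count(A)·count(B))`) so algebraically exact
values such as 1.625 stay exact in floating point. Thresholds: support
≥ min_support and confidence ≥ min_confidence, defaults 0.03 and 0.60 —
the reference operating point. Lift is reported, never filtered: a
lift-0.99 rule that passes both thresholds is kept, and its
near-independence is part of the result.

Display values are half-up rounded to two decimals (1.125 → 1.13); raw
values drive all filtering and sorting. Two cells of the reference
order-2 table (weakness confidence, obesity lift) differ from the
values their own printed counts give by exactly one double-rounding
step; this package reports the single-rounded values.

A brute-force enumerator over the full power set (≤ 15 items) computes
every candidate rule directly from transaction counts and serves as
the independent oracle: the test suite asserts rule-for-rule equality
with the Apriori path on 200 seeded random transaction sets and on an
8-symptom restriction of the fixture.

## Rule tables

Rules are stratified by order (|LHS| + 1: 2 = "binary", 3 = "triple",
…) and sorted within each table by raw support descending, then raw
confidence, then raw lift, then lexicographic antecedent — a stable
total order chosen to match the visible ordering of the reference
tables, which name no explicit key. Rounding never feeds back into
sorting; a dedicated test constructs rules whose rounded keys tie but
raw keys differ.

## Synthetic cohorts

`generate_cohort` draws from a conditional-independence model: outcome
~ Bernoulli(prevalence), then each symptom independently given the
outcome with its own conditional probability pair. A pairwise screen
constrains only (symptom, outcome) margins, so independence-given-
outcome is the maximum-entropy completion; higher-order structure is
injected solely via explicit *implications* — itemsets that force the
outcome positive wherever all members are present, creating
confidence-1 rules whose lift is exactly the reciprocal of the
post-planting outcome support. The default `study_spec` emulates the
reference cohort: n = 520, prevalence 320/520 ≈ 0.615, and the sixteen
conditional probability pairs implied by the published 2×2 counts.
Randomness is NumPy's PCG64 (`default_rng`) under an explicit integer
seed; seeded runs are bit-reproducible, and the run manifest records
the seed.

`table2_fixture` is the deterministic 520-row cohort embedding every
published 2×2 table exactly: rows 0–319 outcome-positive, each
symptom's published positive-block and negative-block counts of 1s
placed in the first rows of the respective block. No seed is involved
and the CSV diffs cleanly. **Limitation:** because placement maximally
overlaps symptoms, only the fixture's order-2 quantities are faithful;
joint distributions of three or more symptoms are construction
artifacts (e.g. the fixture's polyuria∧polydipsia support is 0.43 where
the study observed 0.37). Higher-order results from the study are
therefore covered by property tests (anti-monotone support;
confidence 1 ⇒ lift = 1/support(B)) rather than value reproduction,
and passing tests on the fixture say nothing about real higher-order
symptom structure.

## Problem sizes and numerical choices

The test suite mines the 520 × 17 fixture (order ≤ 2 where values are
asserted), 200 random transaction sets of ≤ 12 items × ≤ 200
transactions for oracle equivalence, and synthetic cohorts of n =
2,000–20,000 for parameter recovery (3-standard-error bounds, seeded,
so the checks are deterministic). The acceptance script mines a
520-row planted cohort. The whole suite runs in a few seconds.

Tie-breaks are deterministic everywhere: canonical item order in
candidate generation, smallest-cutoff on Youden ties, stable sorts in
rule tables. Degenerate inputs (empty transaction sets, single-class
outcomes, constant scores, zero margins, zero pooled SD) raise typed
errors rather than returning conventional values.

## Known limitations

- Multi-level categorical variables (> 2 levels) are out of scope; the
  encoder handles binary indicators plus continuous columns only.
- The miner implements Apriori only (no FP-Growth/Eclat) and the three
  classical metrics (no conviction or leverage).
- The conditional-independence generator cannot emulate higher-order
  dependence except through planted implications, which create only
  the extreme confidence-1 kind.
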