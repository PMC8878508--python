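# Methods

## Problem and pipeline

The package converts per-participant Likert questionnaire data into market
baskets and mines association rules, so that behavioural patterns ("students
who never use positive reappraisal tend to report strong discriminatory
impact") can be read off as antecedent ⟶ consequent rules with quantified
support, confidence and lift, separately for two student cohorts.

Stages: score → recode → encode → mine → generate rules → compare cohorts.
Each stage is a standalone module with a matching CLI subcommand.

## Scoring model

A domain score is the arithmetic mean of its items after reversing any
reverse-keyed item (`x ↦ k + 1 − x` on a `k`-point scale — the standard
Likert reversal; it is an involution and preserves the scale range), recoded
to an integer with fixed bins.

The 5-point bins are `[1, 1.80] → 1, (1.80, 2.60] → 2, (2.60, 3.40] → 3,
(3.40, 4.20] → 4, (4.20, 5] → 5`. The published bin edges are printed as
two-decimal truncations with apparent gaps (e.g. 1.80 vs 1.81); we close the
gaps with `≤ upper-bound` breakpoints, which reproduces every printed
boundary exactly. The 4-point coping domains have no published bins, so we
use the minimal consistent extension: equal-width bins
`[1, 1.75], (1.75, 2.50], (2.50, 3.25], (3.25, 4]`.

Missing item responses are an error, never imputed — the pipeline is
complete-case throughout. Precomputed integer domain scores can be supplied
directly (a `participant_id, cohort, C1..C6, W1..W3` CSV), bypassing
item-level scoring. Cronbach's alpha (`k/(k−1)·(1 − Σ item variances /
total-score variance)`, sample variances) is included so synthetic cohorts
can be sanity-checked for internal consistency; it plays no role in mining.

The default instrument has six COVID adjustment domains (5-point:
Emotionality C1, Social Support C2, Academic Adjustment C3, Discriminatory
Adjustment C4, Regulation Reaction Specific C5 and General C6) and three
Ways-of-Coping domains (4-point: Escape Avoidance W1, Planful Problem
Solving W2, Positive Reappraisal W3). The coping instrument's item-level
content is not modelled; generic item ids with the correct subscale sizes
(8/6/7 items) stand in, and arbitrary instruments can be configured via a
YAML subscale file.

## Basket encoding

Item tokens concatenate domain code and score (`"C4-5"`); the domain code is
everything before the final hyphen. Cohort membership is encoded as a bare
tag item inside the transaction (`10` undergraduate, `20` graduate) rather
than as an external stratum, because the mined rules of interest carry the
tag in their antecedent. The mapping is configurable. A full default
vocabulary holds 6·5 + 3·4 + 2 = 44 tokens; every transaction from a fully
scored participant has exactly 10 items.

## Mining

`mine_frequent` is a from-scratch FP-growth: scan 1 counts item frequencies
and discards items below minsup; scan 2 inserts each transaction's surviving
items, ordered by global support descending with lexicographic tie-break,
into a prefix tree with per-item node links; mining recurses over
conditional pattern bases per item in reverse canonical order, with the
standard single-path shortcut (direct subset enumeration). The canonical
order makes output deterministic and invariant to transaction order.

Numerical choices: supports are integer counts; the frequency test is
inclusive (`count ≥ minsup·N`) with an absolute slack of 1e−12 so a
fractional product like `0.15·1000 = 150.00000000000003` cannot misclassify
a boundary itemset. Itemset size is uncapped by default (`max_len`
available). `apriori_oracle` is an independent brute-force level-wise miner
(prefix join, subset pruning, per-level full scans) with the identical
contract, used to verify FP-growth exactly on hundreds of randomized small
databases.

## Rules

From each frequent itemset of size ≥ 2, all single-item-consequent splits
are enumerated by default (every published rule of this kind has a one-item
consequent; `consequent_size="any"` enumerates all non-empty proper splits).
A rule is kept when confidence ≥ minconf and lift strictly > minlift;
support filtering already happened at mining time. Defaults are
minsup 0.20, minconf 0.70, minlift 1.20 (a stricter 0.2/0.6/1.3 variant used
in some reported rule tables is reachable via `MinerConfig`). Output is
sorted by (support, confidence, lift) descending, then canonical itemset
order; rule identity for deduplication is the (antecedent, consequent) pair.

## Cohort attribution

Default *combined* mode mines the whole database with tags as items and
assigns a rule to the cohort whose tag is in its antecedent, stripping the
tag for display; support is therefore computed over the full database.
Tag-free rules (and rules with a tag only in the consequent, which predict
membership rather than describe a within-cohort pattern) are reported under
"both". *Stratified* mode mines each cohort's transactions separately with
tags removed. Both modes share all downstream code; which one a given
published analysis used is generally ambiguous, so both are first-class.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: two cohorts
(defaults 242 undergraduates, 275 graduates, N = 517), per-domain score
marginals, and planted rules. Default marginals are mid-scale-skewed —
(0.1, 0.2, 0.4, 0.2, 0.1) on 5-point and (0.15, 0.35, 0.35, 0.15) on
4-point domains — the typical single-peaked shape of Likert responses;
uniform or any other marginal is configurable.

Planting is overwrite-then-conditional-draw: with probability
`antecedent_prevalence` (per applicable participant) the antecedent domains
are overwritten to the rule's scores; given planting, the consequent domain
is set to its score with probability `target_confidence`, otherwise redrawn
from its marginal with that score excluded (renormalised). This yields exact
closed-form expectations — with planting probability p, target confidence c,
chance antecedent probability q_A (product of antecedent-score marginals)
and consequent marginal m_B, within the scoped population:

    P(A)     = p + (1−p)·q_A
    P(A∧B)   = p·c + (1−p)·q_A·m_B
    P(B)     = p·c + (1−p)·m_B
    conf     = P(A∧B) / P(A)

For a cohort-scoped rule the mined antecedent carries the cohort tag;
support over the full database scales by the cohort fraction f and the
consequent's full-database support is f·P(B) + (1−f)·m_B. The closed form is
exact when planted rules touch pairwise disjoint domain sets; configs with
conflicting overlapping antecedents are rejected. A single shared numpy
`Generator` (from `config.seed`) drives all draws in a fixed order
(domain marginals in registry order, then rules in config order), so cohorts
are byte-identical across runs; generation is vectorised over participants.

What the generator does *not* emulate: item-level factor structure (scores
are drawn at the domain level), realistic inter-domain covariance beyond the
planted dependencies, and any demographic covariates. Passing recovery tests
therefore shows the pipeline's correctness on data with known structure, not
that real survey data would yield any particular rules.

## Test problem sizes

The test suite exercises: the 1000-transaction commuting/arrival worked
example (exact fractions); FP-growth vs. Apriori equivalence on 200 random
databases of ≤ 30 transactions over ≤ 8 items at minsup 0.1–0.5;
planted-rule recovery on a 5000-participant cohort (prevalence 0.4,
confidence 0.9, mined at 0.2/0.7/1.2, asserted within 3 binomial standard
errors of the closed form); a null-model check that the fraction of chance
item pairs passing lift > 1.2 shrinks over n ∈ {500, 5000, 50000}; and a
full default-configuration run on a 242/275 cohort whose every emitted rule
is re-audited against the configured thresholds. These sizes keep the whole
suite under a minute while leaving binomial error well below the asserted
tolerances.

## Limitations

- Counts of rules found in any real cohort depend on that cohort's joint
  score distribution; synthetic runs make no claim about them.
- Only support/confidence/lift are implemented; other interestingness
  measures (conviction, leverage, χ²) are out of scope, as are closed or
  maximal itemset condensation and weighted/quantitative items.
- The Apriori oracle is intentionally naive (full scans per level) and is
  meant for verification-scale instances, not production mining.
- Statistical significance of rule-count differences between cohorts is not
  assessed; the comparison is descriptive.
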