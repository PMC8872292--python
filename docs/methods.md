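# Methods

## Problem and scope

`fedfpm` mines multimorbidity patterns — non-random combinations of
chronic conditions — from patient-level binary transaction tables held at
several sites (*agents*), under the constraint that no patient-level data
may leave its site. The method is association-rule mining with FP-Growth,
run as a federated protocol in which a central *manager* sees only
itemset→count aggregates. Because the real multi-site cohorts this kind
of study uses are not publicly available, the package includes a
first-class synthetic cohort generator whose planted associations have
closed-form statistics, so the whole pipeline can be validated
quantitatively.

## Rule statistics

For antecedent itemset A and consequent itemset C over N pooled patients:

- support(S) = count(S)/N — for a single disease item, its prevalence;
- confidence(A ⇒ C) = count(A∪C)/count(A) — the estimate of P(C | A);
- lift(A ⇒ C) = confidence/(count(C)/N) — association strength; lift > 1
  means A raises the probability of C. In parts of the epidemiological
  literature lift is loosely called "correlation"; it is not a Pearson
  coefficient, and reports carry a glossary note.

All three are stored as exact rationals (`fractions.Fraction`) computed
from integer counts; rounding happens only at rendering. Threshold
comparisons are therefore exact, with inclusive (≥) semantics for both
minimum support and minimum confidence: an itemset or rule sitting
exactly at a threshold survives. Float thresholds in configs are
interpreted through their decimal literal (0.3 means 3/10, not the
nearest binary double), so `count/N = 3/10` passes `min_support = 0.3`.

## Local mining: FP-Growth

Each agent mines its own data with the classic FP-tree scheme: items are
support-filtered, ordered by descending local frequency (lexicographic
tie-break), and inserted into a prefix tree whose header table chains
same-item nodes. Mining recurses over conditional pattern bases
(prefix paths of each item, weighted by its node counts) projected into
conditional FP-trees. The implementation favors verifiability: no
pruning beyond the support threshold, plain integer counts, and a
deliberately naive powerset-enumeration oracle (`fedfpm.oracle`, capped
at 16 items, no shared code) that the FP-Growth route must match exactly
in tests. "Frequent" additionally requires count ≥ 1, so a support
threshold of 0 never declares a never-observed itemset frequent.

## Federated protocol

Two aggregation rounds, simulated in-process through an audited channel:

1. **Item frequencies.** Every agent reports single-item counts over its
   full catalog plus its size n_local. The manager sums counts, pools
   N = Σ n_local over all participating agents, and retains items with
   global support ≥ min_support.
2. **Rules.** The manager broadcasts the retained items. Each agent
   restricts its transactions to them and mines locally frequent
   itemsets at the local threshold ⌈min_support · n_local⌉, reporting
   their counts. The manager merges the candidate itemsets, broadcasts
   the union, and each agent returns its exact count for every candidate
   in its schema (a bitmask scan). The manager then re-applies the
   support threshold to the exact global counts, forms every
   (A, C) split with a single-item consequent (configurable), computes
   global confidence and lift, and retains rules with confidence ≥
   min_confidence.

The intermediate candidate exchange is the package's answer to a real
design problem: without it, an itemset frequent globally but not at some
agent would be undercounted, and federated results would drift from the
centralized answer. With it the protocol is *exactly transparent*: a
globally frequent itemset has global support equal to a size-weighted
average of local supports, hence is locally frequent at ≥ 1 agent and
enters the candidate union; the final counting pass makes every global
count exact. Tests assert exact equality of rules, counts, supports,
confidences and lifts against the naive centralized oracle over
randomized partitions into 1–5 agents. The cost is that at
min_support → 0 the candidate set approaches all observed itemsets;
the protocol is intended for the study's regime (support ≥ 0.2).

**Privacy contract.** The only object crossing the agent→manager
boundary is `AgentMessage(agent_id, n_local, itemset_counts)`; its
constructor rejects any payload that is not a canonical-itemset→integer
map, so no field can carry a transaction or patient record. Every
message of a run is recorded in an audit log (JSON-lines) for
inspection. This is a structural contract, not cryptography: counts are
visible to the manager, and no differential-privacy noise is added.

**Heterogeneous schemas.** N pools all participating agents; an agent
whose schema lacks an item contributes no count for itemsets involving
it. The survey-schema cohort shares no disease item with the EHR
cohorts, so the study layout runs it as its own single-agent model.
With `outcome_item` set (the mortality model), the pool is restricted to
agents whose schema records the outcome and only outcome-consequent
rules are kept; `exclude_items` conversely removes the outcome from the
multimorbidity models so that death is analyzed only in its own run.

## Synthetic cohorts

The generator emulates five cohorts of patients ≥ 65 years with ≥ 2
chronic conditions: sizes 244, 331, 861, 3786 and 5812 (pooled 11,034),
cohort mean ages 81.8–95.5 and women 47.1–71.6%, matching the study's
descriptives table; 47 chronic-condition items (the 11 conditions named
in the study's result tables padded with generic chronic-disease
labels); polypharmacy; gender and age-band categorical items; a
six-month mortality item at the two largest sites only; and one
survey-schema site with a disjoint catalog (memory complaints,
vision/hearing difficulties, mood items, polymedication).

Per patient: independent Bernoulli memberships in latent clusters
(cardiometabolic ~0.5, cardiovascular ~0.5, mental 0.28 in the EHR
cohorts; frailty 0.55 in the survey cohort, with mild site-to-site
variation); each condition present independently with probability
clamp(baseline × ∏ cluster lift factors); one item per exclusive
categorical group; mortality Bernoulli with logit = intercept + Σ
coefficients over present items (coefficients on heart failure, chronic
kidney disease, chronic anemia, coronary heart disease and diabetes).
Seeds are explicit and required; the same profile + seed reproduces the
dataset byte-for-byte.

Conditional independence given membership keeps every itemset
probability computable exactly by enumerating the latent space
(2^clusters × categorical assignments, plus the ≤ 2^5 presence patterns
of the mortality coefficients' items, since the sigmoid does not
factorize). `planted_rules()` scans candidate antecedents over the
cardiovascular block (plus hypertension/polypharmacy) — or the survey
items, or mortality consequents — and returns those whose analytic
confidence ≥ 0.6, lift ≥ 1.3 and support clears the mining threshold by
a 0.02 margin (several sampling standard errors at n ≈ 10⁴, so recovery
is not a coin flip at the boundary). By construction the cardiovascular
block yields at least one rule with confidence > 0.8 and lift > 1.5.

Two generator properties deserve honesty. First, prevalences are high
(heart failure ≈ 0.5 pooled, hypertension ≈ 0.76, polypharmacy ≈ 0.65):
this is the density required for multi-item itemsets to clear support
0.2, the regime the study's parameter choices imply, and it should be
read as "very multimorbid elderly", not population prevalence. Second,
the six-month mortality frequency is ≈ 0.48 — higher than the ≈ 0.30
the study's printed confidence/lift ratio implies — because a mortality
model run at (support 0.2, confidence 0.8) can only emit rules when the
joint support of antecedent and death reaches 0.2 at confidence 0.8,
which forces a high outcome frequency; the study's own table prints rules
with confidence 0.55–0.58 under a stated 0.8 minimum, an inconsistency
we resolve in favor of the printed parameters. What passing tests show
is that the pipeline recovers planted structure at study scale; they do
not show that any specific printed rule value is reproduced, since the
real cohorts are unavailable.

Continuous age is simulated (normal per cohort) only for descriptive
reporting; mining sees age as categorical band items.

## Reporting

Descriptives follow the study-table convention: per-cohort n, share,
mean age, % women, and a pooled row with size-weighted mean age and %
women (the printed pooled values 82.1 years and 50.8% are reproduced
exactly from the printed per-cohort rows). Rules render in the
"Antecedent ≥ Consequent" format, sorted by descending lift, then
confidence, then lexicographically; CSV output uses `=>`-free ASCII
columns (antecedent, consequent, confidence, lift) with the `≥` glyph
kept in pretty-printed text. Display precision defaults to 3 decimals;
stored values stay exact.

## Numerical and degenerate-input choices

- Ties in item ordering break lexicographically everywhere, so runs are
  deterministic; report row order is a total order.
- min_count = 0 at tree level behaves as 1 (an itemset must occur).
- A candidate antecedent with global count 0 is silently dropped (it
  cannot support a frequent rule).
- Empty agents (n = 0) are legal; they report zero counts and shift no
  aggregate.
- Exact-count scans use ≤ 63-bit numpy masks when possible, with an
  arbitrary-width Python-int fallback.

## Problem sizes used in validation

Federated/centralized equivalence runs on randomized datasets of ≤ 8
items and ≤ 200 transactions over 1–5 agents (200 trials); FP-Growth vs
powerset enumeration on 500 datasets of ≤ 8 items and ≤ 30 transactions;
planted-rule recovery on the full synthetic study (pooled n = 11,034).
These sizes make the oracle enumeration exact and keep the whole suite
in the order of seconds.

## Limitations

- The privacy property is structural (count-only messages), not
  cryptographic; collusion or count-based reconstruction attacks are out
  of scope.
- The generator's conditional-independence-given-cluster structure does
  not emulate real EHR features such as coding noise, site-specific
  under-recording, age-dependent prevalence gradients, or longitudinal
  accrual; passing recovery tests therefore validates the mining
  machinery, not clinical conclusions.
- Low support thresholds (≪ 0.1) on dense data explode the candidate
  space combinatorially; the implementation does not attempt the
  engineering needed to push past that regime.
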