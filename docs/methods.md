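# Methods

`comorbnet` implements a two-arm workflow for discovering and validating
disease comorbidities of opioid use disorder (OUD). The discovery arm mines
co-occurrence structure from spontaneous adverse-event case reports
(FAERS-style quarterly tables); the validation arm estimates adjusted odds
ratios from population-level EHR cohort counts. Because the real discovery
corpus is a multi-gigabyte public bulk download and the validation platform
is proprietary, the package ships a synthetic-data generator whose planted
ground truth makes every stage testable end to end.

## Preprocessing

Raw tables (demographics, drug, indication, reaction) are linked by case ID.
A case resubmitted in a later quarter supersedes its earlier versions;
"latest" is the lexicographic maximum of the `(quarter, version)` key taken
from the demographics table, and all tables are filtered to each case's
maximal version. Raw strings are normalized through user-supplied
raw→canonical mapping tables (the stand-in for ontology normalization, which
is out of scope); unmapped strings are dropped, never passed through, and
per-table mapping coverage (mapped / total unique raw strings) is reported.
Matching is exact after case-folding and whitespace trimming — no fuzzy
matching.

The OUD cohort is flagged heuristically: a case receives the OUD indication
label iff it has at least one opioid drug *and* at least one
drug-use-disorder term among its indications or reactions. Cases already
carrying a literal OUD indication keep it (union with the heuristic cohort).
Flagging is monotone: adding an opioid drug or disorder term can only add
the flag. Each case's final indication set becomes one mining transaction;
cases with no indications are dropped.

## Association-rule mining

Frequent itemsets are mined with FP-growth: transactions are inserted into a
prefix tree in descending global item frequency (ties broken
lexicographically for determinism), and itemsets are enumerated by recursive
conditional-pattern-base projection. Output supports are exact counts / n.
Defaults follow the intended full-corpus regime: minimum support 2×10⁻⁶,
maximum pattern size |X∪Y| = 3, minimum lift 1. On corpora where
`min_support · n` would round to a single transaction, an explicit
`min_support_count` override is available (the orchestrated pipeline uses 5
by default); otherwise the absolute threshold is `max(1, ceil(min_support · n))`.

Rules are every ordered partition of a frequent itemset into non-empty
disjoint antecedent/consequent (2ᵏ − 2 per itemset of size k), scored by

    lift(X→Y) = support(X∪Y) / (support(X) · support(Y)),

and filtered by lift ≥ 1 only; confidence is computed and reported but never
used for filtering. Rule direction encodes nothing beyond co-occurrence and
is ignored downstream; rule counts are reported both as ordered partitions
and as unordered {X, Y} pairs.

## Comorbidity network and ranking

Each rule's disease set is clique-expanded: all C(k, 2) unordered pairs
become edges of an undirected, unweighted graph, with duplicates across
rules merged (rule multiplicity retained as diagnostic edge metadata only).

Ranking uses a random walk with restart from the OUD seed on the seed's
connected component:

    P_{k+1} = (1 − c) · W · P_k + c · P_0

with restart probability c = 0.15, W the column-stochastic adjacency
operator (column j divided by deg j), and P_0 the seed indicator. Because
the update is a convex combination of probability vectors, every iterate
sums to 1; restricting to the seed component keeps the normalization exact,
since unreachable nodes would carry zero stationary mass anyway. Iteration
stops when the L1 change drops below 10⁻⁶ (the norm is a configuration
choice; L1 is scale-free on the simplex), with a 10,000-iteration safety
cap that raises, carrying the last residual. The fixed point equals the
direct solve P* = c (I − (1−c) W)⁻¹ P_0, which the test suite verifies on
random graphs. A subtlety worth recording: with a column-normalized M the
frequently written form "Mᵀ P" denotes the row-stochastic operator on
irregular graphs and does not conserve probability mass; this package
deliberately applies the column-stochastic operator, which is the only
reading consistent with simplex conservation.

The seed is excluded from the ranked list; ties break lexicographically and
are logged. Decile evaluation splits the ranking into 10 contiguous bins
with cumulative boundaries ceil(i·n/10) (bin sizes differ by at most one)
and counts gold-standard members per bin. The headline "first-decile
precision" follows the field's reporting convention — gold hits in bin 1
divided by the gold-list size, e.g. 43/55 = 78.2% — although that quantity
is recall-shaped; the conventional hits-per-bin-size fraction is reported
alongside. The gold list is always an input file, never hard-coded.

## Case-control arm

Population-level platforms expose stratified cohort counts, not
patient-level records, so confounding is handled by stratifying the 2×2
exposure/outcome table on adjustment variables (age, sex, race, risk-factor
status) and pooling with the Cochran–Mantel–Haenszel common odds ratio

    OR_MH = Σᵢ (aᵢdᵢ/nᵢ) / Σᵢ (bᵢcᵢ/nᵢ).

The 95% CI uses the Robins–Breslow–Greenland variance of log OR_MH (the
standard sparse-data-robust choice); the two-sided p-value comes from the
Mantel–Haenszel chi-square statistic (1 df), without continuity correction
by default (flag available). Single-stratum input reduces exactly to the
crude OR; swapping the exposure rows inverts the estimate exactly and
negates the log CI. Strata with n = 0 are skipped and counted.

De-identification masking (cells below 10 suppressed, remainder rounded to
tens) is resolved by an explicit policy before analysis: `midpoint`
(suppressed cell := 5, the centre of the suppressed range — default),
`drop`, `zero`, or a user constant; the policy is recorded in the result's
provenance. Demographic summaries report per-cohort category counts with
column percentages rounded half-up to the nearest integer; categories may
sum above the cohort total because one patient can report several values of
a demographic.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the package's acceptance checks.

**Case reports.** Per-case background item counts follow zero-truncated
Poisson (ZTP) laws — the simplest one-parameter family guaranteeing at
least one item per record — whose means are calibrated so the *total*
expected diseases, drugs and reactions per case equal the configured means,
default 1.37 / 2.91 / 3.00 (the real corpus's averages). Calibration is
analytic: the ZTP mean is the configured mean minus the structural
contribution (seed prevalence p_s + n_comorbid · comorbid marginal p_c for
diseases; the injected trigger term, p_s, for drugs and reactions), and the
ZTP rate is solved by bisection. Background items are drawn *distinct* via
Gumbel-top-k weighted sampling from a Zipf-ranked marginal (exponent 1 by
default) — heavy-tailed like real indication frequencies, though the Zipf
form is a modeling convenience, not an empirical fit.

The seed condition (OUD) is latent in the written files: seed cases
(probability p_s = 0.05) carry one opioid drug and one drug-use-disorder
reaction, so cohort flagging reconstructs the seed set exactly — the
returned in-memory reports carry the label explicitly, giving the tests an
exact round-trip target. Each planted comorbid has overall marginal
p_c = 0.02 and conditional inclusion probability q₁ = lift·p_c given the
seed and q₀ = p_c(1 − p_s·lift)/(1 − p_s) otherwise, making the population
lift of every (seed, comorbid) pair exactly `planted_lift` (default 4).
Infeasible targets (q₁ > 1 or q₀ < 0, i.e. lift > 1/p_s) are rejected with
an explicit message, never clipped. p_s and p_c were fixed once as a
prevalent-exposure / common-comorbidity regime that keeps lift 4 feasible.
A configurable fraction of cases (default 10%) additionally emits a stale
earlier version differing in version key and one dropped reaction,
exercising de-duplication with a detectable difference. All randomness
comes from one explicitly seeded NumPy generator; a fixed seed yields
byte-identical files.

What the generator does *not* emulate: real reporting-field inventory
(outcome codes, route, dose), real ontology coding, temporal reporting
dynamics, reporter biases, or free-text noise beyond a trivial
upper-casing of raw strings. Passing recovery tests therefore demonstrate
algorithmic correctness under the planted model, not performance on real
pharmacovigilance data.

**Stratified cohorts.** Per stratum, outcome counts among exposed/unexposed
are binomial with odds w·OR and w respectively, so the conditional odds
ratio is the spec'd common OR in every stratum. Optional masking applies
the platform-style suppression above. The CMH estimator recovers the
planted OR within 5% at large counts and its 95% CI covers the truth in
93–97% of 500 seeded replicates at moderate counts.

## Numerical choices and degenerate inputs

- Supports are exact rational counts divided by n; mining output is
  bit-reproducible and, on any corpus small enough to enumerate, identical
  to the brute-force oracle.
- Crude OR with a zero cell raises unless the Haldane–Anscombe continuity
  correction (+0.5 to every cell) is enabled.
- Strata with n = 1 contribute zero MH chi-square variance; all-degenerate
  inputs raise rather than return NaN.
- Rules with fewer than two distinct diseases are skipped with a warning
  during network construction; a missing seed raises an error naming it.
- Percent rounding is half-up (floor(x + 0.5)), matching the published
  tables' convention.

## Problem sizes

The shipped suites use: a 3,000-case corpus for round-trip tests; 50,000
cases for mean calibration (3-SE bands); 100,000 cases, 200 diseases, 10
planted comorbids at lift 4 for end-to-end recovery (all planted pairs
passing the support threshold must appear as network edges and ≥90% of the
planted set must occupy the first decile); 100 random corpora (≤2,000
transactions, ≤60 items) for mining-oracle equivalence; 50 random graphs
(≤200 nodes) for walk-oracle equivalence; and 500 replicates per odds ratio
∈ {1, 1.45, 3.3} for CI calibration. The full suite runs in well under a
minute on one CPU.

## Known limitations

- The mined "OUD comorbidities" inherit the flagging heuristic's false
  positives (e.g. pain indications of opioid therapy); the package measures
  recovery of planted structure, not clinical validity.
- Decile "precision" is recall-shaped by convention; both metrics are
  reported to avoid ambiguity.
- The CMH arm assumes a homogeneous common OR across strata; no
  heterogeneity test is included.
- No edge weighting by lift/support, no temporal networks, no multi-seed
  walks, and no individual-level regression — all deliberately out of
  scope.
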