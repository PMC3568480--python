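# Methods

## Data model and counting semantics

A spontaneous report is a demographic tuple plus a non-empty drug set and a
non-empty symptom set; the exchange format is a de-normalized delimited
table with one row per (report, drug, symptom) combination. Readers group
rows by report id and reconstruct the sets as *distinct* values, so both the
full m×k cross product and partial row sets load identically. Every count in
the package — cube cells, margins, contingency cells, item supports — is a
distinct-report count, never a row count: because the report↔drug and
report↔symptom relations are many-to-many, row-level aggregation would
double-count multi-drug/multi-symptom reports, and distinct-report counting
is also what makes `*`-marginalization exactly consistent
(count(…,*,…) = Σ over reports, not Σ over rows).

Missing demographic values are mapped to a reserved token, counted as an
ordinary category, and excluded from rule antecedents unless
`include_missing=True`. Continuous attributes (age, weight) are binned by
user-supplied half-open interval edges with labels `~e0`, `e0~e1`, `ek~`;
out-of-range values fall into the open boundary bins. Time filtering keeps
reports whose event date lies in the union of the requested inclusive
intervals (discontinuous histories are allowed); dateless reports are kept
only when no time filter is active.

## Contingency extraction

For constraint P, exposure D (a drug or drug set) and symptom s:

    a = count(P, D, s)        b = count(P, D) − a
    c = count(P, s) − a       d = count(P) − a − b − c

using positive-item counts only, so cells are non-negative by construction
and a+b+c+d equals the constrained report total. Single-drug counts come
from the cube (margins are materialized lazily per marginalization pattern
and cached — repeated candidate queries become dictionary lookups);
drug-*set* exposure ("report contains all drugs of D") is counted by a
direct report scan, since per-drug cube cells cannot be joined into set
counts without re-touching the reports anyway.

## Measures and signal criteria

Implemented from their defining formulas: PRR, ROR, the maximum-likelihood
information component (no Bayesian shrinkage — deliberately out of scope),
Yates-corrected χ², leverage, and the MHRA composite
(PRR ≥ 2 ∧ a ≥ 3 ∧ χ² ≥ 4). All signal criteria are additionally gated by
`min_count` (default a ≥ 3), the frequency floor conventional in
spontaneous-report mining. Defaults live in
`adrmine.measures.DEFAULT_THRESHOLDS`.

Numerical choices:

- **PRR zero-cell policy** (configurable): the default `"background"` rule
  replaces the background rate c/(c+d) by 0.5/(c+d+0.5) only when c = 0,
  which keeps the exposed rate untouched; `"haldane"` adds 0.5 to all four
  cells; `"strict"` reports infinity. ROR always uses Haldane–Anscombe +0.5
  on any zero cell.
- **CI criterion scale**: "PRR − 1.96δ > 1" is evaluated on the log scale,
  exp(ln PRR − 1.96·SE_lnPRR) > 1, the standard pharmacovigilance
  convention (SE_lnPRR = √(1/a − 1/(a+b) + 1/c − 1/(c+d)), SE_lnROR =
  √(1/a + 1/b + 1/c + 1/d), both on corrected cells); a literal
  natural-scale variant is available via `ci_scale="natural"`.
- **Divergent tables**: when the *uncorrected* ratio diverges (PRR with
  c = 0, ROR with b·c = 0, each with a > 0) the criterion is considered
  met. A Wald interval computed on continuity-corrected cells is not a
  meaningful test of the uncorrected null in that regime — the correction
  exists to report a finite point value, and the observed disproportion is
  the largest the table can express. Without this convention a rule whose
  symptom is *never* reported off-drug could be rejected while a weaker
  rule with one background report is accepted.
- **Yates χ²**: the continuity term |ad − bc| − N/2 is floored at 0 so the
  statistic cannot go negative near independence (this matches
  `scipy.stats.chi2_contingency(correction=True)`, which the tests use as
  an independent oracle). A zero margin is reported as 0 with a degenerate
  flag.
- Candidates whose measure value is non-finite (possible only under the
  strict policy) are dropped and logged, not errored.

## The cube miner (single drug)

Phases: (1) time-filter and build the cube over the selected attributes +
Drug + PT; (2) one candidate per concrete cell — every *selected* attribute
must be instantiated in the rule (cells marginalizing a selected attribute
are not enumerated as coarser rules), drug and symptom concrete, a ≥
min_count, optional fixed drug/symptom focus; (3) contingency + measure +
criterion; (4) sort by measure value descending and truncate to top-k. Ties
are broken by larger antecedent, then larger a, then lexicographically —
the ordering is total, so output is deterministic and independent of report
order.

## The interaction miner (CR-tree)

Offline: items are (attribute, value) pairs for demographics and drugs;
items and symptoms with report support < min_count are eliminated (every
component of a reportable signal must itself be frequent), transactions with
no frequent symptom label are dropped, and surviving items are sorted by
decreasing support. Equal-support ties follow schema attribute precedence
(Year, Age, Gender, Weight, Country, then drugs), then value — a fixed,
documented rule so the cache and the tree are reproducible. The reduced
transactions serialize to a delimited cache (`write_transactions`) for the
offline/online split.

Online: demographic items outside the queried attributes are removed; a
transaction is eliminated when a drug focus is set and it lacks that drug
(co-prescribed drugs are retained — removing them would make fixed-drug
interaction rules unminable), when attribute selection is non-empty and it
retains no selected-attribute item, or when no label remains. Transactions
are inserted into a prefix tree whose node counts accumulate along the
ordered item path and whose per-symptom counts attach at the path end.
Pattern growth processes suffix items least-frequent-first; each item's
conditional pattern base carries the per-symptom counts of its subtrees
(symptom leaves of eliminated items merge upward), conditional items whose
total weight falls below min_count are pruned (safe: any per-symptom count
is bounded by the total), and the recursion reproduces exactly the
brute-force set {(I, s, n): n = #transactions ⊇ I with label s ≥ min_count}
— property-verified against exhaustive subset enumeration. A report with
several frequent symptoms forms one transaction whose pattern counts
increment once per (transaction, label).

Scoring: patterns must instantiate every selected attribute and contain at
least `min_drugs` drugs (default 2 in drug-interaction mode, 1 otherwise;
bare-demographic patterns are never emitted as rules). The contingency is
computed over the **full** time-filtered warehouse, stratified by the
pattern's demographic items — not over the reduced transactions, whose
dropped infrequent-label reports still belong in the background cells (on
the built-in toy warehouse this is what yields d = 1 rather than 0).
Ranking adds antecedent size as the secondary key, preferring more specific
rules at equal strength.

## Synthetic generator

`generate_reports` emulates the content of an AERS-style star schema —
independent categorical demographics, a bounded number (default 1–4) of
distinct drugs drawn by Plackett–Luce weighted sampling (Gumbel top-k) from
a mildly skewed background, and per-symptom Bernoulli inclusion at
configurable background rates (default 30 symptoms at 0.02). An injected
association multiplies the symptom's probability by ρ in reports whose drug
sets contain the association's drugs (and match its optional demographic
stratum), capped at 1, so the implied report-level relative rate is ~ρ and
analytically checkable. Reports are forced to carry ≥ 1 symptom by
resampling, which inflates all symptom marginals by the same factor
1/P(≥1 symptom) and leaves relative rates essentially untouched; the
calibration tests assert the exact conditional marginal. All randomness
flows through one seeded `numpy` generator; identical configs produce
identical warehouses.

Deliberately *not* modelled: reporting biases (stimulated reporting,
duplicates, under-reporting), missingness, dose/latency, correlated drug
co-prescription beyond the sampling-without-replacement coupling, and
MedDRA term hierarchy. Passing recovery tests therefore show the miners
detect disproportionality under clean conditions; they say nothing about
robustness to real-world reporting artefacts.

## Problem sizes used in the test suite

The worked-example checks run on the six-report built-in warehouse; oracle
equivalence uses 50 random warehouses of 20–200 reports (small enough for
exhaustive enumeration to stay exact); generator calibration and recovery
use 20,000-report warehouses, with recovery measured over 100 seeded
replicates of a single ρ = 5 association over 20 background drugs. These
sizes make every expected value computable by an independent brute-force
or closed-form oracle while exercising the vectorized counting paths.

## Known limitations

- No multiple-testing adjustment across the emitted signal list (none of
  the implemented criteria prescribes one).
- The count cube materializes margins for the queried dimensions only;
  it is a desk-scale in-memory structure, not an OLAP server.
- Drug-set exposure counting is linear in the number of constrained
  reports per pattern.
- IC is the raw information component; shrinkage-based early-warning
  variants are out of scope.
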