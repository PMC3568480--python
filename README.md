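# adrmine

Signal detection for spontaneous adverse-drug-reaction (ADR) reports.

Post-marketing drug safety surveillance relies on spontaneous reporting
systems (SRS) such as the FDA's AERS/FAERS: voluntary reports, each carrying
patient demographics, a set of suspected drugs and a set of symptoms coded
as MedDRA Preferred Terms (PT). `adrmine` is a library plus a thin CLI for
pharmacovigilance analysts and methods researchers who want to mine such
data for *disproportionality signals* — drug–symptom (and drug-pair–symptom)
combinations reported together more often than the background would predict
— interactively, stratified by any combination of demographic attributes.

## The statistics

Every measure is computed from the 2×2 report-level contingency table of a
(constraint, exposure, symptom) triple:

|                | target symptom | other symptoms |
|----------------|----------------|----------------|
| suspected drug | a              | b              |
| other drugs    | c              | d              |

- **PRR** (proportional reporting ratio) = (a/(a+b)) / (c/(c+d)); signal
  when the 95% CI lower bound exceeds 1.
- **ROR** (reporting odds ratio) = ad/bc, Haldane–Anscombe corrected on zero
  cells; same CI criterion.
- **IC** (information component) = log₂(p(x,y)/(p(x)p(y))), the
  maximum-likelihood form; signal when above a threshold (default 0).
- **MHRA** composite: PRR ≥ 2 ∧ a ≥ 3 ∧ Yates χ² ≥ 4.
- **Leverage** = p(x,y) − p(x)p(y).

All criteria are gated by a minimum co-occurrence count (default a ≥ 3).

## The two miners

**Cube miner (single drug).** Counts are served from an OLAP-style count
cube over the selected demographic attributes plus Drug and PT; each cell is
a distinct-report count and `*` marginalizes a position. The four
contingency cells come from positive-item counts only
(`a = count(P, d, s)`, `b = count(P, d) − a`, `c = count(P, s) − a`,
`d = count(P) − a − b − c`), so no negative-item aggregation is ever needed.
Four phases: cube extraction → candidate generation (one candidate per
concrete cell with a ≥ min count) → measure calculation → ranking/top-k.

**CR-tree miner (drug interaction).** Cubes are awkward for drug *sets*, so
multidrug rules are mined from itemized reports: an offline,
query-independent stage removes infrequent items, orders the rest by
decreasing report support and stores transactions labelled with their
frequent symptoms; online, transactions are pruned to the queried
attributes, inserted into a class-labelled prefix tree (a CR-tree) and all
frequent (itemset, symptom) patterns are enumerated FP-growth style. Each
surviving pattern is scored on a contingency table taken over the full
warehouse, stratified by the pattern's demographic items.

A seeded synthetic-report generator (`SimConfig`/`generate_reports`) emits
the same de-normalized dialect with injectable drug→symptom associations of
known strength, so recovery can be tested end to end without external data.

## Worked example

The built-in six-report warehouse (`adrmine.example_warehouse()`) is small
enough to verify every count by hand:

```python
import adrmine as am

reports = am.example_warehouse()
query = am.QuerySpec(mode="single-drug", attributes=("Age",),
                     measure="PRR", min_count=3)
print(am.rules_to_frame(am.run_cbm_ss(reports, query)).to_string(index=False))
```

```
 rank antecedent drugs symptom  a  b  c  d measure  value  lower_bound  is_signal
    1     Age=a2    d1      s1  3  0  0  1     PRR    3.0     0.312047       True
    2     Age=a2    d3      s1  3  0  0  1     PRR    3.0     0.312047       True
```

Among the four Age=a2 reports, the three mentioning d1 all mention symptom
s1 and no other a2 report does, so a=3, b=c=0, d=1. With the default
zero-background correction (rate 0.5/(c+d+0.5) when c=0) the PRR is 3. The
interaction miner on the same data emits exactly one multidrug rule,
`Age=a2, {d1, d3} → s1`, with the same cells. The same runs from the shell:

```sh
adrmine single-drug      --input toy.csv --attrs Age --measure PRR --min-count 3 --out signals.tsv
adrmine drug-interaction --input toy.csv --attrs Age --measure PRR --min-count 3 --out interactions.tsv
```

Each run writes a tab-delimited rule table plus a JSON run record (resolved
query, input digest, version, timing). See `examples/` for narrative
scripts, including ground-truth recovery from 20,000 synthetic reports.

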