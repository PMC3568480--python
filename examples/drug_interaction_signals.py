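"""Mine multidrug -> symptom interaction signals with the CR-tree miner.

The pipeline first reduces the six toy reports to frequency-ordered
transactions (the offline stage), prunes them to the queried Age attribute,
mines every frequent (itemset, symptom) pattern from the class-labelled
prefix tree, and finally scores patterns with at least two drugs against the
full warehouse.  Exactly one interaction rule survives: Age=a2 with drugs
{d1, d3} -> s1, supported by 3 reports and PRR = 3.
"""

import adrmine as am

reports = am.example_warehouse()

# offline, query-independent stage (cacheable via write_transactions)
transactions = am.build_transactions(reports, min_count=3)
print("reduced transactions:")
for t in transactions:
    items = ", ".join(f"{a}={v}" if a != "Drug" else v for a, v in t.items)
    print(f"  tid {t.tid}: [{items}] labels={sorted(t.labels)}")

query = am.QuerySpec(
    mode="drug-interaction", attributes=("Age",), measure="PRR", min_count=3
)
pruned = am.prune_transactions(transactions, query)
patterns = am.mine_patterns(am.build_cr_tree(pruned), min_count=3)
print(f"\n{len(patterns)} frequent patterns mined from {len(pruned)} transactions")

rules = am.run_acm_ms(reports, query, transactions=transactions)
print(f"{len(rules)} interaction signal(s):")
for r in rules:
    print(
        f"  {r.describe()}  cells={r.contingency.cells}  "
        f"PRR={r.measure_result.value:g}"
    )
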