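"""Mine single-drug -> symptom signals from the built-in toy warehouse.

The warehouse holds six spontaneous reports over drugs d1-d3 and symptoms
s1-s3.  Stratifying by Age and asking for PRR signals with co-occurrence
count >= 3 yields two rules, both with contingency cells (3, 0, 0, 1): among
the four Age=a2 reports, all three that mention the drug also mention s1 and
no other report mentions s1, so the drug's s1 reporting rate is three times
the zero-corrected background rate (PRR = 3).
"""

import adrmine as am

reports = am.example_warehouse()
query = am.QuerySpec(
    mode="single-drug", attributes=("Age",), measure="PRR", min_count=3
)
rules = am.run_cbm_ss(reports, query)

print(am.rules_to_frame(rules).to_string(index=False))
print()
for r in rules:
    print(
        f"rank {r.rank}: {r.describe()}  cells={r.contingency.cells}  "
        f"PRR={r.measure_result.value:g}"
    )
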