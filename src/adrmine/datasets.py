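"""Tiny built-in warehouses used in documentation, examples and tests."""

from __future__ import annotations

import io

from .warehouse import DEFAULT_SCHEMA, ReportSet, read_denormalized

# Six-report toy warehouse in the de-normalized dialect: one row per
# (report, drug, symptom) combination, report 1 carrying three drugs and one
# symptom, report 3 two drugs and two symptoms, etc.  Small enough to check
# every count by hand, yet it exercises grouping, margins, transaction
# reduction and the interaction miner end to end.
_TOY_CSV = """\
Demo_key,Year,Age,Gender,Weight,Country,Drug,PT
1,y3,a2,g1,w2,c3,d1,s1
1,y3,a2,g1,w2,c3,d2,s1
1,y3,a2,g1,w2,c3,d3,s1
2,y1,a1,g2,w2,c1,d2,s2
2,y1,a1,g2,w2,c1,d3,s2
3,y2,a2,g2,w2,c2,d1,s1
3,y2,a2,g2,w2,c2,d3,s1
3,y2,a2,g2,w2,c2,d1,s2
3,y2,a2,g2,w2,c2,d3,s2
4,y1,a2,g1,w1,c3,d1,s1
4,y1,a2,g1,w1,c3,d3,s1
5,y1,a1,g2,w1,c2,d2,s1
6,y3,a2,g1,w2,c1,d2,s3
"""


def example_warehouse() -> ReportSet:
    """The six-report toy warehouse (three drugs d1-d3, symptoms s1-s3)."""
    return read_denormalized(io.StringIO(_TOY_CSV), DEFAULT_SCHEMA)


def example_warehouse_csv() -> str:
    """The toy warehouse as de-normalized CSV text."""
    return _TOY_CSV
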