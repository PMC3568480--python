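"""Shared fixtures: the six-report toy warehouse and small random warehouses.

The random-warehouse helper is intentionally independent of
``adrmine.synthetic`` so that oracle-equivalence tests do not share code with
the generator under test.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

import adrmine as am
from adrmine.warehouse import Report, ReportSet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy() -> am.ReportSet:
    """Six-report worked-example warehouse (drugs d1-d3, symptoms s1-s3)."""
    return am.example_warehouse()


def random_warehouse(
    rng: random.Random,
    n_reports: int = 60,
    n_attrs: int = 2,
    n_values: int = 3,
    n_drugs: int = 4,
    n_symptoms: int = 3,
) -> ReportSet:
    """A small random warehouse built with plain ``random`` (no numpy)."""
    schema = tuple(f"A{i}" for i in range(n_attrs))
    reports = []
    for i in range(n_reports):
        demo = {a: f"{a.lower()}v{rng.randrange(n_values)}" for a in schema}
        drugs = frozenset(
            rng.sample(
                [f"d{j}" for j in range(n_drugs)], rng.randint(1, min(3, n_drugs))
            )
        )
        symptoms = frozenset(
            rng.sample(
                [f"s{j}" for j in range(n_symptoms)],
                rng.randint(1, min(2, n_symptoms)),
            )
        )
        reports.append(Report(str(i + 1), demo, drugs, symptoms))
    return ReportSet(schema, reports)


# ---------------------------------------------------------------------------
# brute-force oracles (straight re-statements of the definitions)


def brute_count(reports: ReportSet, dims, coords) -> int:
    """Count distinct reports matching the concrete coordinates."""
    n = 0
    for r in reports:
        ok = True
        for d, c in zip(dims, coords):
            if c == "*":
                continue
            if d == "Drug":
                ok = c in r.drugs
            elif d == "PT":
                ok = c in r.symptoms
            else:
                ok = r.demographics[d] == c
            if not ok:
                break
        n += ok
    return n


def brute_contingency(reports: ReportSet, constraint: dict, drugs, symptom):
    """Four-way partition of the constrained reports."""
    drugs = frozenset([drugs] if isinstance(drugs, str) else drugs)
    a = b = c = d = 0
    for r in reports:
        if any(r.demographics.get(k) != v for k, v in constraint.items()):
            continue
        has_d = drugs <= r.drugs
        has_s = symptom in r.symptoms
        if has_d and has_s:
            a += 1
        elif has_d:
            b += 1
        elif has_s:
            c += 1
        else:
            d += 1
    return a, b, c, d
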