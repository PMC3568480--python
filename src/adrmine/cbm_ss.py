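"""Cube-based mining of single-drug -> single-symptom signals.

The miner runs in four phases:

1. *Cube extraction* — time-filter the warehouse and build the count cube
   over the selected demographic attributes plus Drug and PT.
2. *Candidate generation* — one candidate per concrete cube cell
   (every selected attribute instantiated, drug and symptom concrete) whose
   co-occurrence count a reaches the minimum count.
3. *Measure calculation* — extract the 2x2 contingency from the cube and
   compute the chosen disproportionality measure.
4. *Ranking and output* — keep candidates satisfying the measure's signal
   criterion, sort by measure value (descending) and truncate to top-k.
"""

from __future__ import annotations

import logging
import math

from .cube import CountCube, build_cube
from .errors import QueryError
from .measures import compute_measure, evaluate_criterion
from .query import SINGLE_DRUG, QuerySpec, SignalRule, rank_rules
from .warehouse import (
    DRUG_COLUMN,
    MISSING_TOKEN,
    SYMPTOM_COLUMN,
    ReportSet,
    filter_reports,
)

logger = logging.getLogger(__name__)

Candidate = tuple[tuple[tuple[str, str], ...], str, str]


def generate_candidates(cube: CountCube, query: QuerySpec) -> list[Candidate]:
    """Enumerate (constraint, drug, symptom) candidates from concrete cells.

    Every selected attribute must take a concrete value (cells marginalizing
    a selected attribute are not candidates); attributes that are cube
    dimensions but not selected are marginalized away.  Candidates must reach
    ``a >= min_count`` and respect any fixed drug/symptom focus.
    """
    for attr in query.attributes:
        if attr not in cube.dims:
            raise QueryError(f"query attribute {attr!r} is not a cube dimension")
    sel = [cube.dims.index(a) for a in query.attributes]
    i_drug = cube.dims.index(DRUG_COLUMN)
    i_sym = cube.dims.index(SYMPTOM_COLUMN)

    # marginalize non-selected demographic dims: count distinct reports per
    # (selected attrs, drug, symptom)
    concrete_positions = tuple(sorted([*sel, i_drug, i_sym]))
    table = cube.margin_counts(concrete_positions)

    pos_of = {p: i for i, p in enumerate(concrete_positions)}
    out: list[Candidate] = []
    for key, count in table.items():
        if count < query.min_count:
            continue
        drug = key[pos_of[i_drug]]
        sym = key[pos_of[i_sym]]
        if query.fixed_drug is not None and drug != query.fixed_drug:
            continue
        if query.fixed_symptom is not None and sym != query.fixed_symptom:
            continue
        constraint = tuple(
            (cube.dims[p], key[pos_of[p]]) for p in sorted(sel)
        )
        if not query.include_missing and any(
            v == MISSING_TOKEN for _, v in constraint
        ):
            continue
        out.append((constraint, drug, sym))
    out.sort()
    return out


def run_cbm_ss(reports: ReportSet, query: QuerySpec) -> list[SignalRule]:
    """Execute the four-phase cube miner and return ranked signal rules."""
    if query.mode != SINGLE_DRUG:
        raise QueryError("run_cbm_ss requires a single-drug query")
    query.validate_against(reports)

    # phase 1: cube extraction
    data = filter_reports(reports, query.time_intervals)
    if not len(data):
        return []
    dims = [*query.attributes, DRUG_COLUMN, SYMPTOM_COLUMN]
    cube = build_cube(data, dims)
    logger.info("cube extraction: %d reports, dims %s", len(data), dims)

    # phase 2: candidate rule generation
    candidates = generate_candidates(cube, query)
    logger.info("rule generation: %d candidates", len(candidates))

    # phase 3: measure calculation
    th = query.resolved_thresholds()
    rules: list[SignalRule] = []
    for constraint, drug, sym in candidates:
        t = cube.contingency(dict(constraint), drug, sym)
        res = compute_measure(
            t, query.measure, zero_policy=query.zero_policy, thresholds=th
        )
        if not math.isfinite(res.value):
            logger.info("dropping degenerate candidate %s, %s -> %s", constraint, drug, sym)
            continue
        if not evaluate_criterion(
            t, query.measure, th, zero_policy=query.zero_policy
        ):
            continue
        rules.append(SignalRule(constraint, frozenset([drug]), sym, t, res, 0))
    logger.info("measure calculation: %d signals", len(rules))

    # phase 4: ranking and output
    ranked = rank_rules(rules)
    if query.top_k is not None:
        ranked = ranked[: query.top_k]
    return ranked
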