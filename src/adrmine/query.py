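"""Query specification and signal-rule output shared by both miners."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cube import ContingencyTable
from .errors import QueryError
from .measures import CRITERIA, DEFAULT_THRESHOLDS, MeasureResult, ZERO_POLICIES
from .warehouse import ReportSet, TimeInterval

SINGLE_DRUG = "single-drug"
DRUG_INTERACTION = "drug-interaction"


@dataclass(frozen=True)
class QuerySpec:
    """A signal-detection query.

    Parameters
    ----------
    mode
        ``"single-drug"`` (one drug per rule) or ``"drug-interaction"``
        (drug sets, mined from the CR-tree).
    attributes
        Demographic attributes that must appear, instantiated, in every rule
        antecedent.  Empty means rules condition on drugs alone.
    time_intervals
        Union of inclusive date windows restricting the input reports;
        empty disables time filtering.
    fixed_drug, fixed_symptom
        Optional focus: restrict rules to this drug / symptom.
    measure
        One of PRR, ROR, IC, CHI2_YATES, LEVERAGE or the composite MHRA.
    thresholds
        Overrides of :data:`adrmine.measures.DEFAULT_THRESHOLDS`.
    min_count
        Minimum a-cell (report co-occurrence count) for a candidate, and the
        frequency floor of the transaction-reduction stage.
    top_k
        Truncate the ranked output; ``None`` returns all signals.
    zero_policy
        PRR zero-cell policy ("background", "haldane" or "strict").
    min_drugs
        Minimum drugs per rule in the interaction miner; defaults to 2 in
        drug-interaction mode and 1 otherwise.
    include_missing
        Whether the reserved missing-value token may appear in antecedents.
    """

    mode: str = SINGLE_DRUG
    attributes: tuple[str, ...] = ()
    time_intervals: tuple[TimeInterval, ...] = ()
    fixed_drug: str | None = None
    fixed_symptom: str | None = None
    measure: str = "PRR"
    thresholds: Mapping[str, float] = field(default_factory=dict)
    min_count: int = 3
    top_k: int | None = None
    zero_policy: str = "background"
    min_drugs: int | None = None
    include_missing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "time_intervals", tuple(self.time_intervals))
        object.__setattr__(self, "thresholds", dict(self.thresholds))
        if self.mode not in (SINGLE_DRUG, DRUG_INTERACTION):
            raise QueryError(f"unknown mode {self.mode!r}")
        if self.measure.upper() not in CRITERIA:
            raise QueryError(f"unknown measure {self.measure!r}")
        if self.zero_policy not in ZERO_POLICIES:
            raise QueryError(f"unknown zero policy {self.zero_policy!r}")
        if self.min_count < 1:
            raise QueryError("min_count must be >= 1")
        if self.top_k is not None and self.top_k < 1:
            raise QueryError("top_k must be >= 1 when given")
        object.__setattr__(self, "measure", self.measure.upper())

    @property
    def effective_min_drugs(self) -> int:
        if self.min_drugs is not None:
            return self.min_drugs
        return 2 if self.mode == DRUG_INTERACTION else 1

    def resolved_thresholds(self) -> dict[str, float]:
        th = {**DEFAULT_THRESHOLDS, **self.thresholds}
        th["min_count"] = self.min_count
        return th

    def validate_against(self, reports: ReportSet) -> None:
        unknown = [a for a in self.attributes if a not in reports.schema]
        if unknown:
            raise QueryError(f"query attribute(s) not in schema: {unknown}")


@dataclass(frozen=True)
class SignalRule:
    """One ranked output rule: demographic antecedent + drug set -> symptom."""

    antecedent: tuple[tuple[str, str], ...]
    drugs: frozenset[str]
    symptom: str
    contingency: ContingencyTable
    measure_result: MeasureResult
    rank: int

    @property
    def antecedent_size(self) -> int:
        return len(self.antecedent) + len(self.drugs)

    def describe(self) -> str:
        parts = [f"{a}={v}" for a, v in self.antecedent]
        parts += [f"Drug={d}" for d in sorted(self.drugs)]
        return ", ".join(parts) + f" -> PT={self.symptom}"


def rank_rules(rules: list[SignalRule]) -> list[SignalRule]:
    """Sort by measure value desc, antecedent size desc, a desc, then the
    lexicographic antecedent/drugs/symptom — a total, deterministic order."""
    keyed = sorted(
        rules,
        key=lambda r: (
            -r.measure_result.value,
            -r.antecedent_size,
            -r.contingency.a,
            r.antecedent,
            tuple(sorted(r.drugs)),
            r.symptom,
        ),
    )
    return [
        SignalRule(r.antecedent, r.drugs, r.symptom, r.contingency, r.measure_result, i + 1)
        for i, r in enumerate(keyed)
    ]


def rules_to_frame(rules: Sequence[SignalRule]) -> pd.DataFrame:
    """Tabular view of a ranked signal list (one row per rule)."""
    rows = []
    for r in rules:
        rows.append(
            {
                "rank": r.rank,
                "antecedent": ";".join(f"{a}={v}" for a, v in r.antecedent),
                "drugs": ";".join(sorted(r.drugs)),
                "symptom": r.symptom,
                "a": r.contingency.a,
                "b": r.contingency.b,
                "c": r.contingency.c,
                "d": r.contingency.d,
                "measure": r.measure_result.name,
                "value": r.measure_result.value,
                "lower_bound": r.measure_result.lower_bound,
                "is_signal": r.measure_result.is_signal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "antecedent",
            "drugs",
            "symptom",
            "a",
            "b",
            "c",
            "d",
            "measure",
            "value",
            "lower_bound",
            "is_signal",
        ],
    )
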