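"""Data model for spontaneous adverse-event reports.

A spontaneous reporting system (SRS) such as the FDA's AERS/FAERS collects one
*report* per suspected adverse event.  Each report carries demographic
attributes (year, age, gender, weight, country, ...), a non-empty set of
suspected drugs and a non-empty set of symptoms coded as MedDRA Preferred
Terms (PT).  Because the report-to-drug and report-to-symptom relations are
many-to-many, the de-normalized exchange format used here has one row per
(report, drug, symptom) combination; a report with m drugs and k symptoms may
appear as up to m*k rows.  All counting downstream of this module is at the
level of *distinct reports*, never rows.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, IntegrityError, ParseError, QueryError, SchemaError

#: Demographic attributes used when none are specified explicitly.
DEFAULT_SCHEMA: tuple[str, ...] = ("Year", "Age", "Gender", "Weight", "Country")

#: Reserved token for a missing demographic value.  Treated as an ordinary
#: category when counting but excluded from candidate rule antecedents by
#: default.
MISSING_TOKEN = "<NA>"

#: Default column names of the de-normalized dialect.
REPORT_ID_COLUMN = "Demo_key"
DRUG_COLUMN = "Drug"
SYMPTOM_COLUMN = "PT"
DATE_COLUMN = "Event_Time"


@dataclass(frozen=True)
class Report:
    """One spontaneous report.

    Parameters
    ----------
    report_id
        Opaque identifier, unique within a :class:`ReportSet`.
    demographics
        Mapping attribute name -> categorical value.  Every attribute of the
        owning set's schema must be present; missing values carry
        :data:`MISSING_TOKEN`.
    drugs
        Non-empty set of drug identifiers.
    symptoms
        Non-empty set of symptom identifiers (PT terms).
    event_date
        Optional calendar date of the adverse event.
    """

    report_id: str
    demographics: Mapping[str, str]
    drugs: frozenset[str]
    symptoms: frozenset[str]
    event_date: _dt.date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))
        object.__setattr__(self, "demographics", dict(self.demographics))
        if not self.drugs:
            raise IntegrityError(f"report {self.report_id!r} has no drugs")
        if not self.symptoms:
            raise IntegrityError(f"report {self.report_id!r} has no symptoms")


@dataclass
class ReportSet:
    """An ordered collection of reports sharing one demographic schema."""

    schema: tuple[str, ...]
    reports: list[Report] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise IntegrityError(f"duplicate report id {r.report_id!r}")
            seen.add(r.report_id)
            missing = [a for a in self.schema if a not in r.demographics]
            if missing:
                raise SchemaError(
                    f"report {r.report_id!r} lacks demographic attributes {missing}"
                )

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self.schema == other.schema and sorted(
            self.reports, key=lambda r: str(r.report_id)
        ) == sorted(other.reports, key=lambda r: str(r.report_id))

    def drug_vocabulary(self) -> set[str]:
        return set().union(*(r.drugs for r in self.reports)) if self.reports else set()

    def symptom_vocabulary(self) -> set[str]:
        return (
            set().union(*(r.symptoms for r in self.reports)) if self.reports else set()
        )


@dataclass(frozen=True)
class TimeInterval:
    """Inclusive calendar interval ``[start, end]``."""

    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise QueryError(f"interval start {self.start} after end {self.end}")

    def __contains__(self, day: _dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass(frozen=True)
class BinningConfig:
    """Half-open interval bins for continuous demographic attributes.

    ``edges[attr] = [e0, e1, ..., ek]`` (strictly increasing) partitions the
    real line into ``(-inf, e0)``, ``[e0, e1)``, ..., ``[ek, inf)``, labelled
    ``"~e0"``, ``"e0~e1"``, ..., ``"ek~"``.  Values outside every finite
    interval fall into the open-ended boundary bins by construction.
    """

    edges: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        for attr, es in self.edges.items():
            es = list(es)
            if any(b <= a for a, b in zip(es, es[1:])):
                raise ConfigError(
                    f"bin edges for {attr!r} must be strictly increasing: {es}"
                )

    def labels(self, attr: str) -> list[str]:
        es = [_fmt_edge(e) for e in self.edges[attr]]
        return [f"~{es[0]}"] + [f"{a}~{b}" for a, b in zip(es, es[1:])] + [f"{es[-1]}~"]

    def label_for(self, attr: str, value: float) -> str:
        es = list(self.edges[attr])
        fmt = [_fmt_edge(e) for e in es]
        if value < es[0]:
            return f"~{fmt[0]}"
        for lo, hi, flo, fhi in zip(es, es[1:], fmt, fmt[1:]):
            if lo <= value < hi:
                return f"{flo}~{fhi}"
        return f"{fmt[-1]}~"


def _fmt_edge(e: float) -> str:
    f = float(e)
    return str(int(f)) if f.is_integer() and not isinstance(e, float) else str(f)


def read_denormalized(
    source,
    schema: Sequence[str] = DEFAULT_SCHEMA,
    *,
    report_id_column: str = REPORT_ID_COLUMN,
    drug_column: str = DRUG_COLUMN,
    symptom_column: str = SYMPTOM_COLUMN,
    date_column: str = DATE_COLUMN,
    sep: str | None = None,
) -> ReportSet:
    """Read a de-normalized report table into a :class:`ReportSet`.

    ``source`` is a path or text stream of a delimited table with a header
    naming the report-id column, the demographic attributes, the drug and the
    symptom column.  Rows sharing a report id are grouped into one report; its
    drug and symptom sets are the distinct values over those rows and its
    demographics come from the first row of the group.  The reader therefore
    accepts both the full m*k drug-symptom cross product and partial row sets.

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        If rows of one report id disagree on a demographic value.
    """
    if sep is None:
        sep = _sniff_sep(source)
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    if df.empty and not len(df.columns):
        return ReportSet(tuple(schema), [])
    required = [report_id_column, *schema, drug_column, symptom_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"input lacks required column(s) {missing}")
    has_date = date_column in df.columns
    df = df.replace("", MISSING_TOKEN)

    reports: list[Report] = []
    for rid, grp in df.groupby(report_id_column, sort=False):
        demo: dict[str, str] = {}
        for attr in schema:
            vals = grp[attr].unique()
            if len(vals) > 1:
                raise IntegrityError(
                    f"report {rid!r} carries conflicting values for {attr!r}: "
                    f"{sorted(vals)}"
                )
            demo[attr] = vals[0]
        date = None
        if has_date:
            dvals = {v for v in grp[date_column] if v != MISSING_TOKEN}
            if len(dvals) > 1:
                raise IntegrityError(f"report {rid!r} carries conflicting event dates")
            if dvals:
                date = _dt.date.fromisoformat(dvals.pop())
        reports.append(
            Report(
                report_id=str(rid),
                demographics=demo,
                drugs=frozenset(grp[drug_column]),
                symptoms=frozenset(grp[symptom_column]),
                event_date=date,
            )
        )
    return ReportSet(tuple(schema), reports)


def _sniff_sep(source) -> str:
    """Choose between comma and tab from the header line."""
    if hasattr(source, "read"):
        pos = source.tell()
        head = source.readline()
        source.seek(pos)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def write_denormalized(
    reports: ReportSet,
    target,
    *,
    report_id_column: str = REPORT_ID_COLUMN,
    drug_column: str = DRUG_COLUMN,
    symptom_column: str = SYMPTOM_COLUMN,
    date_column: str = DATE_COLUMN,
    sep: str = ",",
) -> None:
    """Write the full drug x symptom cross-product rows of every report."""
    any_date = any(r.event_date is not None for r in reports)
    rows = []
    for r in reports:
        for d in sorted(r.drugs):
            for s in sorted(r.symptoms):
                row = {report_id_column: r.report_id}
                row.update({a: r.demographics[a] for a in reports.schema})
                row[drug_column] = d
                row[symptom_column] = s
                if any_date:
                    row[date_column] = (
                        r.event_date.isoformat() if r.event_date else ""
                    )
                rows.append(row)
    cols = [report_id_column, *reports.schema, drug_column, symptom_column]
    if any_date:
        cols.append(date_column)
    pd.DataFrame(rows, columns=cols).to_csv(target, sep=sep, index=False)


def bin_continuous(reports: ReportSet, config: BinningConfig) -> ReportSet:
    """Replace numeric values of configured attributes by interval labels.

    Values already equal to one of the configured labels pass through
    unchanged; anything neither numeric nor a known label raises
    :class:`ParseError`.  The missing token passes through.
    """
    out: list[Report] = []
    label_cache = {a: set(config.labels(a)) for a in config.edges}
    for r in reports:
        demo = dict(r.demographics)
        for attr in config.edges:
            if attr not in demo:
                continue
            v = demo[attr]
            if v == MISSING_TOKEN or v in label_cache[attr]:
                continue
            try:
                num = float(v)
            except ValueError as exc:
                raise ParseError(
                    f"value {v!r} of {attr!r} is neither numeric nor a bin label"
                ) from exc
            demo[attr] = config.label_for(attr, num)
        out.append(replace(r, demographics=demo))
    return ReportSet(reports.schema, out)


def filter_reports(
    reports: ReportSet,
    intervals: Iterable[TimeInterval] = (),
    constraints: Mapping[str, str] | None = None,
) -> ReportSet:
    """Select reports by time window union and demographic equality.

    A report is kept when its event date falls in *any* of ``intervals``
    (supporting discontinuous history windows; an empty list disables the time
    filter — reports without a date are dropped only when a time filter is
    active) and it satisfies *all* ``constraints``.
    """
    intervals = list(intervals)
    constraints = dict(constraints or {})
    unknown = [a for a in constraints if a not in reports.schema]
    if unknown:
        raise QueryError(f"unknown demographic attribute(s) in constraint: {unknown}")

    def keep(r: Report) -> bool:
        if intervals:
            if r.event_date is None or not any(r.event_date in iv for iv in intervals):
                return False
        return all(r.demographics[a] == v for a, v in constraints.items())

    return ReportSet(reports.schema, [r for r in reports if keep(r)])
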