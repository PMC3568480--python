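"""Report-level count cubes and 2x2 contingency extraction.

The disproportionality measures used in pharmacovigilance are all computed
from a 2x2 contingency table

    ==============  =============  ===============
    .               target symptom  all other symptoms
    suspected drug  a               b
    other drugs     c               d
    ==============  =============  ===============

optionally conditioned on a demographic predicate (e.g. ``Age=20~60``).
Rather than re-partitioning the warehouse for every rule, the counts are
served from an OLAP-style count cube over user-selected dimensions, whose
last two dimensions are Drug and PT.  Every cell holds the number of
*distinct reports* matching its concrete coordinates; the reserved token
``"*"`` marginalizes a position.  Because report-drug and report-symptom
relations are many-to-many, naive row aggregation would double count; all
cells here are distinct-report counts, which makes marginalization consistent
by construction.

The four contingency cells are recovered from positive-item counts only:

    a = count(constraint, drug, symptom)
    b = count(constraint, drug) - a
    c = count(constraint, symptom) - a
    d = count(constraint) - a - b - c
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import QueryError
from .warehouse import DRUG_COLUMN, SYMPTOM_COLUMN, Report, ReportSet

#: Reserved marginalization token.
ANY = "*"

_RID = "_rid"


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 cells of a (constraint, exposure, symptom) triple.

    ``a + b + c + d`` equals the number of reports satisfying the demographic
    constraint; all cells are non-negative report counts.
    """

    a: int
    b: int
    c: int
    d: int
    constraint: tuple[tuple[str, str], ...] = ()
    exposure: frozenset[str] = frozenset()
    symptom: str | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency cell in {self.cells}")
        object.__setattr__(self, "constraint", tuple(self.constraint))
        object.__setattr__(self, "exposure", frozenset(self.exposure))

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class CountCube:
    """Distinct-report counts over chosen dimensions with ``"*"`` margins.

    Counts are materialized lazily per marginalization pattern (the subset of
    positions held concrete) and cached, so repeated queries — as issued in
    bulk during candidate generation — are dictionary lookups.
    """

    def __init__(self, reports: ReportSet, dims: Sequence[str]):
        unknown = [
            d for d in dims if d not in (*reports.schema, DRUG_COLUMN, SYMPTOM_COLUMN)
        ]
        if unknown:
            raise QueryError(f"unknown cube dimension(s): {unknown}")
        self.dims: tuple[str, ...] = tuple(dims)
        self._reports = reports
        self._n = len(reports)
        self._rows = _exploded_frame(reports, self.dims)
        self._margin_cache: dict[tuple[int, ...], dict[tuple[str, ...], int]] = {}
        # per-report structures for multi-drug exposure counting
        self._drug_sets = {r.report_id: r.drugs for r in reports}
        self._symptom_sets = {r.report_id: r.symptoms for r in reports}
        self._demo = {r.report_id: r.demographics for r in reports}

    @property
    def n_reports(self) -> int:
        return self._n

    def count(self, coords: Sequence[str]) -> int:
        """Number of distinct reports matching ``coords`` (``"*"`` = any)."""
        coords = tuple(coords)
        if len(coords) != len(self.dims):
            raise QueryError(
                f"expected {len(self.dims)} coordinates for dims {self.dims}, "
                f"got {len(coords)}"
            )
        concrete = tuple(i for i, c in enumerate(coords) if c != ANY)
        table = self._margin(concrete)
        return table.get(tuple(coords[i] for i in concrete), 0)

    # the cube is also indexable: cube[("a2", "*", "s1")]
    __getitem__ = count

    def _margin(self, concrete: tuple[int, ...]) -> dict[tuple[str, ...], int]:
        if concrete not in self._margin_cache:
            if not concrete:
                self._margin_cache[concrete] = {(): self._n}
            else:
                cols = [self.dims[i] for i in concrete]
                counts = self._rows.groupby(cols, sort=False)[_RID].nunique()
                self._margin_cache[concrete] = {
                    (k if isinstance(k, tuple) else (k,)): int(v)
                    for k, v in counts.items()
                }
        return self._margin_cache[concrete]

    def margin_counts(
        self, concrete_positions: Sequence[int]
    ) -> dict[tuple[str, ...], int]:
        """Non-zero counts of the margin keeping ``concrete_positions``.

        Keys are value tuples over the kept positions in ascending position
        order; every other position is marginalized to ``"*"``.
        """
        return dict(self._margin(tuple(sorted(concrete_positions))))

    def concrete_cells(self) -> dict[tuple[str, ...], int]:
        """All fully concrete cells with a non-zero count."""
        return dict(self._margin(tuple(range(len(self.dims)))))

    def contingency(
        self,
        constraint: Mapping[str, str],
        drugs: str | Iterable[str],
        symptom: str,
    ) -> ContingencyTable:
        """Extract the 2x2 table for ``constraint`` and an exposure.

        For a single drug the four positive-item counts come straight from
        the cube.  For a drug *set*, exposure means a report containing every
        drug of the set; those counts are taken by a direct report scan (cube
        cells are per single drug, and joining them is both slow and lossy).
        """
        drugset = frozenset([drugs] if isinstance(drugs, str) else drugs)
        if not drugset:
            raise QueryError("exposure drug set must be non-empty")
        if ANY in drugset or symptom == ANY:
            raise QueryError("drug and symptom must be concrete in contingency extraction")
        constraint = dict(constraint)
        unknown = [a for a in constraint if a not in self.dims]
        if unknown:
            raise QueryError(f"constraint attribute(s) not cube dims: {unknown}")

        if len(drugset) == 1 and set(constraint) <= set(self.dims):
            (drug,) = drugset
            coords = {**constraint, DRUG_COLUMN: drug, SYMPTOM_COLUMN: symptom}
            a = self.count(self._coords(coords))
            nd = self.count(self._coords({**constraint, DRUG_COLUMN: drug}))
            ns = self.count(self._coords({**constraint, SYMPTOM_COLUMN: symptom}))
            nc = self.count(self._coords(constraint))
        else:
            a, nd, ns, nc = self._scan_counts(constraint, drugset, symptom)
        return ContingencyTable(
            a=a,
            b=nd - a,
            c=ns - a,
            d=nc - nd - ns + a,
            constraint=tuple(sorted(constraint.items())),
            exposure=drugset,
            symptom=symptom,
        )

    def _coords(self, concrete: Mapping[str, str]) -> tuple[str, ...]:
        return tuple(concrete.get(d, ANY) for d in self.dims)

    def _scan_counts(
        self, constraint: Mapping[str, str], drugset: frozenset[str], symptom: str
    ) -> tuple[int, int, int, int]:
        a = nd = ns = nc = 0
        for rid, demo in self._demo.items():
            if any(demo.get(k) != v for k, v in constraint.items()):
                continue
            nc += 1
            has_d = drugset <= self._drug_sets[rid]
            has_s = symptom in self._symptom_sets[rid]
            nd += has_d
            ns += has_s
            a += has_d and has_s
        return a, nd, ns, nc

    def to_frame(self) -> pd.DataFrame:
        """Long-format export of all non-zero concrete cells."""
        cells = self.concrete_cells()
        rows = [(*k, v) for k, v in sorted(cells.items())]
        return pd.DataFrame(rows, columns=[*self.dims, "count"])


def build_cube(reports: ReportSet, dims: Sequence[str]) -> CountCube:
    """Build a distinct-report :class:`CountCube` over ``dims``.

    ``dims`` must be drawn from the report schema plus Drug and PT; by
    convention Drug and PT come last.
    """
    return CountCube(reports, dims)


def contingency_from_cube(
    cube: CountCube,
    constraint: Mapping[str, str],
    drugs: str | Iterable[str],
    symptom: str,
) -> ContingencyTable:
    """Functional alias for :meth:`CountCube.contingency`."""
    return cube.contingency(constraint, drugs, symptom)


def read_cube_frame(df: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Parse a long-format cube export back into a cell mapping."""
    dims = [c for c in df.columns if c != "count"]
    return {
        tuple(str(row[d]) for d in dims): int(row["count"])
        for _, row in df.iterrows()
    }


def _exploded_frame(reports: ReportSet, dims: Sequence[str]) -> pd.DataFrame:
    """One row per (report, drug, symptom); restricted to ``dims`` + id."""
    want_drug = DRUG_COLUMN in dims
    want_sym = SYMPTOM_COLUMN in dims
    demo_dims = [d for d in dims if d not in (DRUG_COLUMN, SYMPTOM_COLUMN)]
    rows: list[tuple] = []
    for r in reports:
        base = tuple(r.demographics[d] for d in demo_dims)
        drugs = sorted(r.drugs) if want_drug else [None]
        syms = sorted(r.symptoms) if want_sym else [None]
        for d in drugs:
            for s in syms:
                row = (r.report_id, *base)
                if want_drug:
                    row += (d,)
                if want_sym:
                    row += (s,)
                rows.append(row)
    cols = [_RID, *demo_dims]
    if want_drug:
        cols.append(DRUG_COLUMN)
    if want_sym:
        cols.append(SYMPTOM_COLUMN)
    return pd.DataFrame(rows, columns=cols)
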