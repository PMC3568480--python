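"""Disproportionality measures over 2x2 report contingency tables.

Given cells (a, b, c, d) — a = reports with the suspected drug(s) *and* the
target symptom, b = drug without symptom, c = symptom without drug,
d = neither — the module computes the standard pharmacovigilance statistics:

PRR
    Proportional reporting ratio ``(a/(a+b)) / (c/(c+d))`` with the signal
    criterion ``PRR - 1.96*SE > 1`` evaluated, by convention, on the log
    scale: ``exp(ln PRR - 1.96*SE_lnPRR) > 1``.
ROR
    Reporting odds ratio ``ad/bc``, same CI-style criterion,
    ``SE_lnROR = sqrt(1/a + 1/b + 1/c + 1/d)``.
IC
    Information component ``log2(p(x,y) / (p(x)p(y)))`` — the
    maximum-likelihood form, without Bayesian shrinkage; signal when the
    value exceeds a threshold (default 0).
CHI2_YATES
    Yates-corrected chi-squared statistic of the table.
MHRA
    The composite criterion PRR >= 2 AND a >= 3 AND chi2 >= 4.
LEVERAGE
    ``p(x,y) - p(x)p(y)``; positive under positive association, zero under
    independence.

Zero cells.  Spontaneous-report tables are sparse; c = 0 makes PRR diverge
and any zero cell makes ROR diverge.  The default PRR policy replaces the
background rate ``c/(c+d)`` by the continuity rate ``0.5/(c+d+0.5)`` only
when c = 0 ("background" policy); alternatives are Haldane–Anscombe +0.5 on
all cells ("haldane") and no correction ("strict", yielding inf).  ROR always
uses Haldane–Anscombe when any cell is zero.  A table whose *uncorrected*
ratio diverges (zero denominator with a > 0) represents the strongest
observable disproportion, so the CI criterion is considered met for it; the
Wald interval on corrected cells is not meaningful there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cube import ContingencyTable
from .errors import QueryError

MEASURES = ("PRR", "ROR", "IC", "CHI2_YATES", "LEVERAGE")
CRITERIA = MEASURES + ("MHRA",)

ZERO_POLICIES = ("background", "haldane", "strict")

#: Default thresholds for :func:`evaluate_criterion`.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_count": 3,  # minimum a for any signal
    "ci_z": 1.96,
    "ic": 0.0,  # IC signal threshold
    "leverage": 0.0,
    "mhra_prr": 2.0,
    "mhra_a": 3,
    "mhra_chi2": 4.0,
}


@dataclass(frozen=True)
class MeasureResult:
    """Value of one measure on one table, with its signal verdict."""

    name: str
    value: float
    lower_bound: float | None = None
    is_signal: bool = False
    zero_corrected: bool = False
    degenerate: bool = False

    def __float__(self) -> float:
        return float(self.value)


def prr(
    t: ContingencyTable,
    *,
    zero_policy: str = "background",
    ci_scale: str = "log",
    z: float = 1.96,
) -> MeasureResult:
    """Proportional reporting ratio with CI-based signal verdict.

    ``ci_scale="log"`` (default) evaluates the criterion as
    ``exp(ln PRR - z*SE) > 1``; ``"natural"`` uses the literal
    ``PRR - z*SE > 1`` reading.
    """
    _check_policy(zero_policy)
    a, b, c, d = t.cells
    if a + b == 0:
        raise QueryError("PRR undefined: no exposed reports (a+b=0)")
    if a == 0:
        return MeasureResult("PRR", 0.0, None, False, False, True)
    exposed_rate = a / (a + b)
    diverges = c == 0
    corrected = False
    if not diverges:
        background = c / (c + d)
        cc, cd = c, d
    elif zero_policy == "strict":
        return MeasureResult("PRR", math.inf, None, True, False, True)
    elif zero_policy == "background":
        background = 0.5 / (c + d + 0.5)
        cc, cd = 0.5, d
        corrected = True
    else:  # haldane: +0.5 on all cells
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        exposed_rate = a2 / (a2 + b2)
        background = c2 / (c2 + d2)
        a, b, cc, cd = a2, b2, c2, d2
        corrected = True
    value = exposed_rate / background
    se = _safe_sqrt(1 / a - 1 / (a + b) + 1 / cc - 1 / (cc + cd))
    lower = _lower_bound(value, se, z, ci_scale)
    is_signal = diverges or (lower is not None and lower > 1)
    return MeasureResult("PRR", value, lower, is_signal, corrected, False)


def ror(
    t: ContingencyTable,
    *,
    ci_scale: str = "log",
    z: float = 1.96,
) -> MeasureResult:
    """Reporting odds ratio ad/bc, Haldane–Anscombe corrected on zero cells."""
    a, b, c, d = t.cells
    diverges = a > 0 and (b == 0 or c == 0)
    corrected = 0 in t.cells
    if corrected:
        a, b, c, d = (x + 0.5 for x in t.cells)
    value = (a * d) / (b * c)
    se = _safe_sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lower = _lower_bound(value, se, z, ci_scale)
    is_signal = diverges or (lower is not None and lower > 1)
    return MeasureResult("ROR", value, lower, is_signal, corrected, False)


def ic(t: ContingencyTable, *, threshold: float = 0.0) -> MeasureResult:
    """Maximum-likelihood information component log2(a*N / ((a+b)(a+c)))."""
    a, b, c, _ = t.cells
    n = t.n
    if n == 0:
        raise QueryError("IC undefined on an empty table")
    if a == 0:
        return MeasureResult("IC", math.nan, None, False, False, True)
    value = math.log2(a * n / ((a + b) * (a + c)))
    return MeasureResult("IC", value, None, value > threshold, False, False)


def chi2_yates(t: ContingencyTable) -> MeasureResult:
    """Yates continuity-corrected chi-squared statistic of the 2x2 table.

    The continuity term ``|ad - bc| - N/2`` is floored at zero so the
    statistic never turns negative near independence.  A zero margin makes
    the statistic undefined; it is reported as 0 with the degenerate flag.
    """
    a, b, c, d = t.cells
    n = t.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return MeasureResult("CHI2_YATES", 0.0, None, False, False, True)
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    value = n * num * num / margins
    return MeasureResult("CHI2_YATES", value, None, value >= 4.0, False, False)


def leverage(t: ContingencyTable) -> MeasureResult:
    """Dependency measure p(x,y) - p(x)p(y); zero under independence."""
    a, b, c, _ = t.cells
    n = t.n
    if n == 0:
        raise QueryError("leverage undefined on an empty table")
    value = a / n - ((a + b) / n) * ((a + c) / n)
    return MeasureResult("LEVERAGE", value, None, value > 0, False, False)


_MEASURE_FUNCS = {
    "PRR": prr,
    "ROR": ror,
    "IC": ic,
    "CHI2_YATES": chi2_yates,
    "LEVERAGE": leverage,
}


def compute_measure(
    t: ContingencyTable,
    name: str,
    *,
    zero_policy: str = "background",
    ci_scale: str = "log",
    thresholds: Mapping[str, float] | None = None,
) -> MeasureResult:
    """Compute one named measure; for MHRA the reported value is the PRR."""
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    name = name.upper()
    if name == "PRR":
        return prr(t, zero_policy=zero_policy, ci_scale=ci_scale, z=th["ci_z"])
    if name == "ROR":
        return ror(t, ci_scale=ci_scale, z=th["ci_z"])
    if name == "IC":
        return ic(t, threshold=th["ic"])
    if name == "CHI2_YATES":
        return chi2_yates(t)
    if name == "LEVERAGE":
        return leverage(t)
    if name == "MHRA":
        p = prr(t, zero_policy=zero_policy, ci_scale=ci_scale, z=th["ci_z"])
        x2 = chi2_yates(t)
        ok = (
            p.value >= th["mhra_prr"]
            and t.a >= th["mhra_a"]
            and x2.value >= th["mhra_chi2"]
        )
        return MeasureResult(
            "MHRA", p.value, p.lower_bound, ok, p.zero_corrected, p.degenerate
        )
    raise QueryError(f"unknown measure {name!r}; expected one of {CRITERIA}")


def evaluate_criterion(
    t: ContingencyTable,
    measure: str,
    thresholds: Mapping[str, float] | None = None,
    *,
    zero_policy: str = "background",
    ci_scale: str = "log",
) -> bool:
    """Signal verdict of ``measure`` on ``t``, gated by the minimum count.

    Every criterion additionally requires ``a >= min_count`` (default 3),
    the frequency floor shared by all spontaneous-reporting measures.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if t.a < th["min_count"]:
        return False
    res = compute_measure(
        t, measure, zero_policy=zero_policy, ci_scale=ci_scale, thresholds=th
    )
    if res.name == "IC" and not math.isnan(res.value):
        return res.value > th["ic"]
    if res.name == "LEVERAGE":
        return res.value > th["leverage"]
    return res.is_signal


def _check_policy(policy: str) -> None:
    if policy not in ZERO_POLICIES:
        raise QueryError(f"unknown zero-cell policy {policy!r}; use {ZERO_POLICIES}")


def _safe_sqrt(x: float) -> float | None:
    return math.sqrt(x) if x >= 0 else None


def _lower_bound(value: float, se: float | None, z: float, ci_scale: str) -> float | None:
    if se is None or value <= 0 or not math.isfinite(value):
        return None
    if ci_scale == "log":
        return math.exp(math.log(value) - z * se)
    if ci_scale == "natural":
        return value - z * se
    raise QueryError(f"unknown ci_scale {ci_scale!r}; use 'log' or 'natural'")
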