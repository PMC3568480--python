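"""Synthetic spontaneous-report generator with injectable ground truth.

The generator emulates the star-schema content of an AERS-style warehouse:
per-report categorical demographics, a many-to-many drug group and a
many-to-many symptom group.  The generative model is deliberately simple so
the disproportionality a miner should recover is analytically known:

* demographics are sampled independently per report from configured
  categorical distributions;
* the number of drugs per report is drawn from a bounded integer
  distribution and that many distinct drugs are sampled according to
  background weights;
* each symptom ``s`` enters the report independently with probability
  ``p_s * prod(rho)`` over every injected association whose drug set is a
  subset of the report's drugs (and whose demographic stratum, if any,
  matches), capped at 1; reports with no symptom are resampled so every
  report carries at least one.

With a single injected pair (D*, S*, rho) the implied report-level relative
rate Pr(S*|D*)/Pr(S*|not D*) is ~rho (the forced-symptom resampling perturbs
it only at second order for small background rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .warehouse import DEFAULT_SCHEMA, Report, ReportSet

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class Association:
    """An injected drug-set -> symptom association of strength ``rho``."""

    drugs: frozenset[str]
    symptom: str
    rho: float
    stratum: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "stratum", tuple(self.stratum))
        if self.rho <= 0:
            raise ConfigError("association risk multiplier rho must be > 0")
        if not self.drugs:
            raise ConfigError("association drug set must be non-empty")


def _default_demographics() -> dict[str, dict[str, float]]:
    return {
        "Year": {"y1": 0.4, "y2": 0.3, "y3": 0.3},
        "Age": {"a1": 0.25, "a2": 0.35, "a3": 0.25, "a4": 0.15},
        "Gender": {"g1": 0.5, "g2": 0.5},
        "Weight": {"w1": 0.3, "w2": 0.5, "w3": 0.2},
        "Country": {"c1": 0.5, "c2": 0.3, "c3": 0.2},
    }


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic warehouse.

    Defaults describe a small but realistic spontaneous-reporting snapshot:
    20 background drugs with mildly skewed prescription weights, 30 symptoms
    with background reporting probabilities of a few percent, 1-4 drugs and
    a Bernoulli symptom profile per report.
    """

    n_reports: int = 1000
    demographics: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_demographics
    )
    n_drugs: int = 20
    drug_weights: Sequence[float] | None = None  # default: Zipf-like skew
    drugs_per_report: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    n_symptoms: int = 30
    symptom_probs: Sequence[float] | None = None  # default: 0.02 each
    associations: tuple[Association, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "associations", tuple(self.associations))
        if self.n_reports < 0:
            raise ConfigError("n_reports must be >= 0")
        if self.n_drugs < 1 or self.n_symptoms < 1:
            raise ConfigError("need at least one drug and one symptom")
        for attr, dist in self.demographics.items():
            tot = sum(dist.values())
            if not dist or abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"probabilities of {attr!r} must sum to 1")
        kmax = max(self.drugs_per_report)
        if min(self.drugs_per_report) < 1 or kmax > self.n_drugs:
            raise ConfigError("drugs-per-report counts must lie in [1, n_drugs]")
        if abs(sum(self.drugs_per_report.values()) - 1.0) > 1e-9:
            raise ConfigError("drugs-per-report probabilities must sum to 1")

    def drug_names(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_drugs)]

    def symptom_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_symptoms)]

    def resolved_drug_weights(self) -> np.ndarray:
        if self.drug_weights is not None:
            w = np.asarray(self.drug_weights, dtype=float)
            if len(w) != self.n_drugs or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("drug_weights must be n_drugs non-negative values")
        else:
            w = 1.0 / np.arange(1, self.n_drugs + 1)
        return w / w.sum()

    def resolved_symptom_probs(self) -> np.ndarray:
        if self.symptom_probs is not None:
            p = np.asarray(self.symptom_probs, dtype=float)
            if len(p) != self.n_symptoms or (p < 0).any() or (p > 1).any():
                raise ConfigError("symptom_probs must be n_symptoms values in [0,1]")
        else:
            p = np.full(self.n_symptoms, 0.02)
        if p.sum() == 0:
            raise ConfigError("all symptom probabilities are zero; infeasible")
        return p


def generate_reports(config: SimConfig) -> ReportSet:
    """Sample a :class:`ReportSet` from ``config``; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    schema = tuple(config.demographics) or DEFAULT_SCHEMA
    drug_names = np.array(config.drug_names())
    sym_names = np.array(config.symptom_names())
    sym_index = {s: i for i, s in enumerate(sym_names)}
    p_base = config.resolved_symptom_probs()

    # demographics: independent categorical draws, vectorized per attribute
    demo_cols: dict[str, np.ndarray] = {}
    for attr, dist in config.demographics.items():
        vals = np.array(list(dist))
        probs = np.array(list(dist.values()), dtype=float)
        demo_cols[attr] = rng.choice(vals, size=n, p=probs)

    # drug sets: Gumbel top-k over background weights gives a weighted
    # without-replacement sample per report in one vectorized pass
    counts_vals = np.array(sorted(config.drugs_per_report), dtype=int)
    counts_probs = np.array(
        [config.drugs_per_report[int(k)] for k in counts_vals], dtype=float
    )
    m = rng.choice(counts_vals, size=n, p=counts_probs)
    w = config.resolved_drug_weights()
    keys = np.log(w)[None, :] + rng.gumbel(size=(n, config.n_drugs))
    ranked = np.argsort(-keys, axis=1)
    drug_mask = np.zeros((n, config.n_drugs), dtype=bool)
    rows = np.repeat(np.arange(n), m)
    cols = np.concatenate([ranked[i, : m[i]] for i in range(n)]) if n else np.array([], int)
    drug_mask[rows, cols] = True

    # per-report symptom probabilities with multiplicative risk boosts
    p = np.broadcast_to(p_base, (n, config.n_symptoms)).copy()
    drug_idx = {d: i for i, d in enumerate(drug_names)}
    for assoc in config.associations:
        if assoc.symptom not in sym_index:
            raise ConfigError(f"association targets unknown symptom {assoc.symptom!r}")
        try:
            didx = [drug_idx[d] for d in assoc.drugs]
        except KeyError as exc:
            raise ConfigError(f"association references unknown drug: {exc}") from exc
        mask = drug_mask[:, didx].all(axis=1)
        for attr, val in assoc.stratum:
            if attr not in demo_cols:
                raise ConfigError(f"association stratum uses unknown attribute {attr!r}")
            mask &= demo_cols[attr] == val
        p[mask, sym_index[assoc.symptom]] *= assoc.rho
    np.clip(p, 0.0, 1.0, out=p)

    sym_mask = rng.random((n, config.n_symptoms)) < p
    # every report must carry at least one symptom: resample empty rows
    empty = np.flatnonzero(~sym_mask.any(axis=1))
    tries = 0
    while empty.size:
        tries += 1
        if tries > _MAX_RESAMPLE:
            raise ConfigError(
                "could not draw a non-empty symptom set; probabilities too small"
            )
        sym_mask[empty] = rng.random((empty.size, config.n_symptoms)) < p[empty]
        empty = empty[~sym_mask[empty].any(axis=1)]

    reports = [
        Report(
            report_id=str(i + 1),
            demographics={a: str(demo_cols[a][i]) for a in schema},
            drugs=frozenset(drug_names[drug_mask[i]]),
            symptoms=frozenset(sym_names[sym_mask[i]]),
        )
        for i in range(n)
    ]
    return ReportSet(schema, reports)
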