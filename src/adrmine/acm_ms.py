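"""Associative-classification mining of multidrug -> single-symptom signals.

Count cubes make single-drug rules cheap but are awkward for drug-drug
interactions, because interaction counts would need joins across cube cells.
This miner instead itemizes reports into transactions and counts drug sets on
a class-labelled prefix tree (a CR-tree, the structure of the CMAR
classifier) with FP-growth-style recursive pattern growth.

The pipeline has an offline stage and three online phases:

1. *Data transformation* (offline, query independent) — each report becomes
   a transaction of items (demographic attribute=value items and drug
   items), infrequent items (report-level support below the minimum count)
   are removed, the remaining items are sorted by decreasing support and the
   report's frequent symptoms become class labels.  Label-less transactions
   are dropped.
2. *CR-tree construction* — items outside the queried attribute domains are
   pruned, unrelated transactions eliminated, and the survivors inserted
   into a prefix tree whose leaves accumulate per-symptom counts.
3. *Pattern generation* — FP-growth over the tree enumerates every itemset
   whose per-symptom transaction count reaches the minimum count.
4. *Signal generation and sorting* — patterns are filtered (each selected
   attribute represented; enough drug items), scored on a contingency table
   taken over the full warehouse stratified by the pattern's demographic
   items, and ranked.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

from .cube import build_cube
from .errors import IntegrityError, QueryError
from .measures import compute_measure, evaluate_criterion
from .query import QuerySpec, SignalRule, rank_rules
from .warehouse import (
    DRUG_COLUMN,
    MISSING_TOKEN,
    SYMPTOM_COLUMN,
    ReportSet,
    filter_reports,
)

logger = logging.getLogger(__name__)

#: An item is an (attribute, value) pair; drug items use the Drug attribute.
Item = tuple[str, str]


@dataclass(frozen=True)
class Transaction:
    """One itemized report: ordered frequent items plus symptom labels."""

    tid: str
    items: tuple[Item, ...]
    labels: frozenset[str]


@dataclass(frozen=True)
class ItemOrder:
    """Global item order: decreasing report-level support, ties broken by
    schema attribute precedence (drugs last), then by value."""

    items: tuple[Item, ...]
    support: Mapping[Item, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", dict(self.support))
        object.__setattr__(
            self, "_index", {it: i for i, it in enumerate(self.items)}
        )

    def index(self, item: Item) -> int:
        return self._index[item]

    def sort(self, items: Iterable[Item]) -> tuple[Item, ...]:
        return tuple(sorted(items, key=self._index.__getitem__))


@dataclass
class TransactionSet:
    """Reduced transactions plus the order and supports they conform to."""

    transactions: list[Transaction]
    order: ItemOrder
    symptom_support: Mapping[str, int]
    min_count: int

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)


def build_transactions(
    reports: ReportSet, min_count: int, *, include_missing: bool = False
) -> TransactionSet:
    """Offline transformation of a warehouse into reduced transactions.

    Items (demographic values and drugs) and symptoms with report-level
    support below ``min_count`` are eliminated; transactions retaining no
    frequent symptom label are dropped; surviving items are sorted by the
    global frequency order.
    """
    if min_count < 1:
        raise QueryError("min_count must be >= 1")
    item_support: Counter[Item] = Counter()
    symptom_support: Counter[str] = Counter()
    for r in reports:
        for a in reports.schema:
            v = r.demographics[a]
            if include_missing or v != MISSING_TOKEN:
                item_support[(a, v)] += 1
        for d in r.drugs:
            item_support[(DRUG_COLUMN, d)] += 1
        for s in r.symptoms:
            symptom_support[s] += 1

    frequent = {it: n for it, n in item_support.items() if n >= min_count}
    freq_symptoms = {s: n for s, n in symptom_support.items() if n >= min_count}
    precedence = {a: i for i, a in enumerate(reports.schema)}
    precedence[DRUG_COLUMN] = len(reports.schema)
    ordered = tuple(
        sorted(
            frequent,
            key=lambda it: (-frequent[it], precedence[it[0]], str(it[1])),
        )
    )
    order = ItemOrder(ordered, frequent)

    transactions: list[Transaction] = []
    for r in reports:
        labels = frozenset(s for s in r.symptoms if s in freq_symptoms)
        if not labels:
            continue
        items = [
            (a, r.demographics[a])
            for a in reports.schema
            if (a, r.demographics[a]) in frequent
        ]
        items += [(DRUG_COLUMN, d) for d in r.drugs if (DRUG_COLUMN, d) in frequent]
        transactions.append(Transaction(r.report_id, order.sort(items), labels))
    logger.info(
        "data transformation: %d frequent items, %d frequent symptoms, "
        "%d transactions",
        len(frequent),
        len(freq_symptoms),
        len(transactions),
    )
    return TransactionSet(transactions, order, freq_symptoms, min_count)


def prune_transactions(ts: TransactionSet, query: QuerySpec) -> TransactionSet:
    """Online pruning of the cached transactions for one query.

    Demographic items whose attribute is not selected are removed; drug
    items are kept.  When a drug (symptom) focus is set, transactions not
    containing it are eliminated and labels are restricted.  A transaction
    is also eliminated when selected attributes exist but none of its items
    belongs to any selected attribute's domain, or when no label remains.
    """
    selected = set(query.attributes)
    kept: list[Transaction] = []
    for t in ts.transactions:
        items = tuple(
            it for it in t.items if it[0] == DRUG_COLUMN or it[0] in selected
        )
        if query.fixed_drug is not None and (DRUG_COLUMN, query.fixed_drug) not in items:
            continue
        labels = t.labels
        if query.fixed_symptom is not None:
            labels = labels & {query.fixed_symptom}
        if not labels:
            continue
        if selected and not any(it[0] in selected for it in items):
            continue
        kept.append(Transaction(t.tid, items, labels))
    return TransactionSet(kept, ts.order, dict(ts.symptom_support), ts.min_count)


class _Node:
    __slots__ = ("item", "count", "parent", "children", "symptoms")

    def __init__(self, item: Item | None, parent: "_Node | None"):
        self.item = item
        self.count = 0.0
        self.parent = parent
        self.children: dict[Item, _Node] = {}
        self.symptoms: Counter[str] = Counter()


class CRTree:
    """Class-labelled prefix tree over frequency-ordered transactions.

    Each node stores an item and the number of transactions whose ordered
    prefix passes through it; the per-symptom counts of a transaction are
    attached at the node ending its item list (the "symptom leaves").
    """

    def __init__(self, order: ItemOrder):
        self.order = order
        self.root = _Node(None, None)
        self.header: dict[Item, list[_Node]] = {}

    def insert(
        self, items: Sequence[Item], labels: Mapping[str, float], weight: float
    ) -> None:
        prev = -1
        for it in items:
            idx = self.order.index(it)
            if idx <= prev:
                raise IntegrityError(
                    f"transaction items out of global frequency order: {items}"
                )
            prev = idx
        node = self.root
        node.count += weight
        for it in items:
            child = node.children.get(it)
            if child is None:
                child = _Node(it, node)
                node.children[it] = child
                self.header.setdefault(it, []).append(child)
            child.count += weight
            node = child
        for s, w in labels.items():
            node.symptoms[s] += w

    def items_present(self) -> list[Item]:
        """Items with at least one node, in global order."""
        return sorted(self.header, key=self.order.index)

    def subtree_symptoms(self, node: _Node) -> Counter:
        """Per-symptom counts of all transactions passing through ``node``."""
        total = Counter(node.symptoms)
        stack = list(node.children.values())
        while stack:
            n = stack.pop()
            total.update(n.symptoms)
            stack.extend(n.children.values())
        return total

    def prefix_path(self, node: _Node) -> tuple[Item, ...]:
        path = []
        n = node.parent
        while n is not None and n.item is not None:
            path.append(n.item)
            n = n.parent
        return tuple(reversed(path))


def build_cr_tree(ts: TransactionSet) -> CRTree:
    """Insert every transaction of ``ts`` into a fresh CR-tree."""
    tree = CRTree(ts.order)
    for t in ts.transactions:
        tree.insert(t.items, {s: 1 for s in t.labels}, 1.0)
    return tree


@dataclass(frozen=True)
class FrequentPattern:
    """A non-empty itemset co-occurring with a symptom in >= min_count
    transactions."""

    itemset: frozenset[Item]
    symptom: str
    count: int

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(v for a, v in self.itemset if a == DRUG_COLUMN)

    @property
    def demographics(self) -> dict[str, str]:
        return {a: v for a, v in self.itemset if a != DRUG_COLUMN}


def mine_patterns(tree: CRTree, min_count: int) -> set[FrequentPattern]:
    """Enumerate all frequent (itemset, symptom) patterns by pattern growth.

    Suffix items are processed least-frequent-first; each item's conditional
    pattern base carries the per-symptom counts of its subtrees (symptom
    leaves below the eliminated item are merged upward), and a conditional
    CR-tree is mined recursively.  The result equals, by construction, the
    brute-force set {(I, s, n) : n = #transactions containing I labelled s,
    n >= min_count, I non-empty}.
    """
    out: set[FrequentPattern] = set()
    _grow(tree, (), min_count, out)
    return out


def _grow(
    tree: CRTree,
    suffix: tuple[Item, ...],
    min_count: int,
    out: set[FrequentPattern],
) -> None:
    for item in reversed(tree.items_present()):
        nodes = tree.header[item]
        base: list[tuple[tuple[Item, ...], Counter]] = []
        totals: Counter[str] = Counter()
        for n in nodes:
            syms = tree.subtree_symptoms(n)
            if not syms:
                continue
            base.append((tree.prefix_path(n), syms))
            totals.update(syms)
        itemset = frozenset((item, *suffix))
        for s, cnt in totals.items():
            c = int(round(cnt))
            if c >= min_count:
                out.add(FrequentPattern(itemset, s, c))
        # conditional tree on the prefix paths of this item
        if not base:
            continue
        cond_support: Counter[Item] = Counter()
        for path, syms in base:
            w = sum(syms.values())
            for it in path:
                cond_support[it] += w
        keep = {it for it, w in cond_support.items() if w >= min_count}
        if not keep:
            continue
        cond = CRTree(tree.order)
        for path, syms in base:
            kept = tuple(it for it in path if it in keep)
            cond.insert(kept, syms, float(sum(syms.values())))
        _grow(cond, (item, *suffix), min_count, out)


def run_acm_ms(
    reports: ReportSet,
    query: QuerySpec,
    *,
    transactions: TransactionSet | None = None,
) -> list[SignalRule]:
    """Execute the interaction miner and return ranked signal rules.

    ``transactions`` may supply the cached offline stage (it must have been
    built with the same ``min_count``); otherwise it is computed here.  The
    final contingency of each pattern is computed over the *full*
    (time-filtered) warehouse, stratified on the pattern's demographic items
    — reduction drops infrequent-label reports, which still belong in the
    background cells.
    """
    query.validate_against(reports)
    data = filter_reports(reports, query.time_intervals)
    if not len(data):
        return []

    # offline stage (phase 1)
    if transactions is None:
        transactions = build_transactions(
            data, query.min_count, include_missing=query.include_missing
        )
    elif transactions.min_count != query.min_count:
        raise QueryError(
            f"cached transactions were reduced at min_count="
            f"{transactions.min_count}, query asks {query.min_count}"
        )

    # phase 2: prune and build the CR-tree
    pruned = prune_transactions(transactions, query)
    logger.info("CR-tree construction: %d transactions", len(pruned))
    if not len(pruned):
        return []
    tree = build_cr_tree(pruned)

    # phase 3: pattern generation
    patterns = mine_patterns(tree, query.min_count)
    logger.info("pattern generation: %d frequent patterns", len(patterns))

    # phase 4: signal generation and sorting
    selected = set(query.attributes)
    min_drugs = query.effective_min_drugs
    cube = build_cube(data, [*query.attributes, DRUG_COLUMN, SYMPTOM_COLUMN])
    th = query.resolved_thresholds()
    rules: list[SignalRule] = []
    for p in patterns:
        demo = p.demographics
        if selected and set(demo) != selected:
            continue
        drugs = p.drugs
        if len(drugs) < min_drugs:
            continue
        if query.fixed_drug is not None and query.fixed_drug not in drugs:
            continue
        if query.fixed_symptom is not None and p.symptom != query.fixed_symptom:
            continue
        t = cube.contingency(demo, drugs, p.symptom)
        res = compute_measure(
            t, query.measure, zero_policy=query.zero_policy, thresholds=th
        )
        if not math.isfinite(res.value):
            logger.info("dropping degenerate pattern %s", p)
            continue
        if not evaluate_criterion(t, query.measure, th, zero_policy=query.zero_policy):
            continue
        rules.append(
            SignalRule(tuple(sorted(demo.items())), drugs, p.symptom, t, res, 0)
        )
    logger.info("signal generation: %d signals", len(rules))
    ranked = rank_rules(rules)
    if query.top_k is not None:
        ranked = ranked[: query.top_k]
    return ranked


def write_transactions(ts: TransactionSet, target: TextIO | str) -> None:
    """Serialize the reduced-transaction cache as a tab-delimited file.

    Layout: a header section of ``#item`` / ``#symptom`` support lines (in
    global order), then one ``tid<TAB>items<TAB>labels`` row per transaction
    with ``;``-joined ``attr=value`` tokens.
    """
    own = isinstance(target, str)
    fh = open(target, "w", encoding="utf-8") if own else target
    try:
        fh.write(f"#min_count\t{ts.min_count}\n")
        for it in ts.order.items:
            fh.write(f"#item\t{it[0]}={it[1]}\t{ts.order.support[it]}\n")
        for s in sorted(ts.symptom_support):
            fh.write(f"#symptom\t{s}\t{ts.symptom_support[s]}\n")
        fh.write("tid\titems\tlabels\n")
        for t in ts.transactions:
            items = ";".join(f"{a}={v}" for a, v in t.items)
            labels = ";".join(sorted(t.labels))
            fh.write(f"{t.tid}\t{items}\t{labels}\n")
    finally:
        if own:
            fh.close()


def read_transactions(source: TextIO | str) -> TransactionSet:
    """Inverse of :func:`write_transactions`."""
    own = isinstance(source, str)
    fh = open(source, "r", encoding="utf-8") if own else source
    try:
        min_count = 1
        items: list[Item] = []
        support: dict[Item, int] = {}
        symptom_support: dict[str, int] = {}
        transactions: list[Transaction] = []
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                tag, *rest = line[1:].split("\t")
                if tag == "min_count":
                    min_count = int(rest[0])
                elif tag == "item":
                    a, v = rest[0].split("=", 1)
                    items.append((a, v))
                    support[(a, v)] = int(rest[1])
                elif tag == "symptom":
                    symptom_support[rest[0]] = int(rest[1])
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            tid, item_s, label_s = line.split("\t")
            t_items = tuple(
                tuple(tok.split("=", 1)) for tok in item_s.split(";") if tok
            )
            labels = frozenset(x for x in label_s.split(";") if x)
            transactions.append(Transaction(tid, t_items, labels))
        order = ItemOrder(tuple(items), support)
        return TransactionSet(transactions, order, symptom_support, min_count)
    finally:
        if own:
            fh.close()
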