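"""Association rule mining: level-wise APRIORI, rule generation, filtering.

Supports are kept as exact transaction counts internally; fractions are only
materialized when a metric is read or serialized.  Rule heads are restricted
to single items, matching the intended use where the head names one trait
level of interest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .traits import ItemizedDataset

__all__ = [
    "FrequentItemsets",
    "AssociationRule",
    "RuleConstraint",
    "apriori",
    "generate_rules",
    "filter_rules",
    "write_rules",
    "read_rules",
]


@dataclass
class FrequentItemsets:
    """Itemsets with support >= the mining threshold, keyed by frozenset.

    ``counts`` maps each frequent itemset to its absolute transaction count;
    ``n`` is the database size, so support(S) = counts[S] / n exactly.
    """

    counts: dict[frozenset[str], int]
    n: int

    def support(self, items: frozenset[str]) -> float:
        return self.counts[items] / self.n

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, items) -> bool:
        return frozenset(items) in self.counts


@dataclass(frozen=True)
class AssociationRule:
    """Rule body -> head with support, confidence and lift.

    Body and head are disjoint; ``support`` is s(body ∪ {head}),
    ``confidence`` is s(body ∪ {head}) / s(body) and ``lift`` is
    confidence / s(head).
    """

    body: frozenset[str]
    head: str
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.head in self.body:
            raise ValueError("rule body and head must be disjoint")
        if not self.body:
            raise ValueError("rule body must be non-empty")

    @property
    def items(self) -> frozenset[str]:
        return self.body | {self.head}

    def sort_key(self):
        return (tuple(sorted(self.body)), self.head)


@dataclass
class RuleConstraint:
    """Conjunction of clauses a rule must satisfy to be retained.

    ``item``/``side`` require a named item to appear in the body, the head,
    or either; the threshold clauses bound the rule metrics from below and
    ``max_body_size`` from above.  An empty constraint keeps everything.
    """

    item: str | None = None
    side: str = "either"  # body | head | either
    min_sup: float = 0.0
    min_conf: float = 0.0
    min_lift: float = 0.0
    max_body_size: int | None = None

    def __post_init__(self) -> None:
        if self.side not in ("body", "head", "either"):
            raise ValueError(f"side must be body|head|either, got {self.side!r}")
        for name in ("min_sup", "min_conf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")

    def accepts(self, rule: AssociationRule) -> bool:
        if self.item is not None:
            in_body = self.item in rule.body
            in_head = self.item == rule.head
            if self.side == "body" and not in_body:
                return False
            if self.side == "head" and not in_head:
                return False
            if self.side == "either" and not (in_body or in_head):
                return False
        if rule.support < self.min_sup:
            return False
        if rule.confidence < self.min_conf:
            return False
        if rule.lift < self.min_lift:
            return False
        if self.max_body_size is not None and len(rule.body) > self.max_body_size:
            return False
        return True


def apriori(
    data: ItemizedDataset, min_sup: float = 0.01, max_len: int = 5
) -> FrequentItemsets:
    """Level-wise frequent itemset mining.

    Returns every itemset with support >= ``min_sup`` and at most ``max_len``
    items.  Candidate k-sets are produced by joining (k-1)-sets sharing a
    (k-2)-prefix and pruned by downward closure before counting.
    """
    if not 0 < min_sup <= 1:
        raise ValueError("min_sup must be in (0, 1]")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    transactions = data.transactions
    n = len(transactions)
    if n == 0:
        raise ValueError("empty transaction database")

    counts: dict[frozenset[str], int] = {}

    item_counts: dict[str, int] = {}
    for txn in transactions:
        for it in txn:
            item_counts[it] = item_counts.get(it, 0) + 1
    frequent_prev = []
    for it, c in item_counts.items():
        if c / n >= min_sup:
            fs = frozenset((it,))
            counts[fs] = c
            frequent_prev.append((it,))
    frequent_prev.sort()

    k = 2
    while frequent_prev and k <= max_len:
        prev_set = {frozenset(t) for t in frequent_prev}
        candidates: list[tuple[str, ...]] = []
        for i, a in enumerate(frequent_prev):
            for b in frequent_prev[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted: once prefixes diverge no later b matches
                cand = a + (b[-1],)
                cand_fs = frozenset(cand)
                # downward closure: every (k-1)-subset must be frequent
                if all(cand_fs - {x} in prev_set for x in cand):
                    candidates.append(cand)
        if not candidates:
            break
        cand_counts = {c: 0 for c in candidates}
        cand_fs = {c: frozenset(c) for c in candidates}
        for txn in transactions:
            if len(txn) < k:
                continue
            for c in candidates:
                if cand_fs[c] <= txn:
                    cand_counts[c] += 1
        frequent_prev = []
        for c, cnt in cand_counts.items():
            if cnt / n >= min_sup:
                counts[cand_fs[c]] = cnt
                frequent_prev.append(c)
        frequent_prev.sort()
        k += 1

    return FrequentItemsets(counts=counts, n=n)


def generate_rules(
    frequent: FrequentItemsets,
    min_conf: float = 0.10,
    heads: Iterable[str] | None = None,
) -> list[AssociationRule]:
    """Emit single-head rules Z∖{y} -> y from every frequent Z, |Z| >= 2.

    Metrics come from the stored supports only; a missing subset support
    signals a corrupt frequent set and raises.  ``heads`` optionally
    restricts which items may appear as a rule head.
    """
    head_whitelist = set(heads) if heads is not None else None
    n = frequent.n
    rules: list[AssociationRule] = []
    for itemset, count in frequent.counts.items():
        if len(itemset) < 2:
            continue
        sup_xy = count / n
        for y in itemset:
            if head_whitelist is not None and y not in head_whitelist:
                continue
            body = itemset - {y}
            try:
                body_count = frequent.counts[body]
                head_count = frequent.counts[frozenset((y,))]
            except KeyError as e:
                raise ValueError(
                    f"frequent set not closed under subsets: missing {set(e.args[0])}"
                ) from None
            conf = count / body_count
            if conf < min_conf:
                continue
            lift = conf / (head_count / n)
            rules.append(
                AssociationRule(body=body, head=y, support=sup_xy, confidence=conf, lift=lift)
            )
    rules.sort(key=AssociationRule.sort_key)
    return rules


def filter_rules(
    rules: Iterable[AssociationRule], constraint: RuleConstraint
) -> list[AssociationRule]:
    """Keep rules satisfying every clause of the constraint (pure filter)."""
    return [r for r in rules if constraint.accepts(r)]


_COLUMNS = ["rule_id", "body", "head", "support", "confidence", "lift"]


def write_rules(rules: Sequence[AssociationRule], path, header: str | None = None) -> None:
    """CSV with body items semicolon-joined; floats use shortest round-trip repr."""
    with open(path, "w", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for i, r in enumerate(rules):
            w.writerow(
                [i, ";".join(sorted(r.body)), r.head, repr(r.support), repr(r.confidence), repr(r.lift)]
            )


def read_rules(path) -> list[AssociationRule]:
    rules = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty rule file") from None
    if header != _COLUMNS:
        raise ValueError(f"unexpected rule CSV header: {header}")
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(_COLUMNS):
            raise ValueError(f"malformed rule row at line {lineno}: {row}")
        try:
            rules.append(
                AssociationRule(
                    body=frozenset(row[1].split(";")),
                    head=row[2],
                    support=float(row[3]),
                    confidence=float(row[4]),
                    lift=float(row[5]),
                )
            )
        except (ValueError, IndexError) as e:
            raise ValueError(f"malformed rule row at line {lineno}: {e}") from None
    return rules
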