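"""FP-growth frequent-itemset mining and lift-filtered association rules.

Transactions are per-case disease sets.  Mining uses an FP-tree (prefix
tree ordered by descending global item frequency) with recursive
conditional-pattern-base projection, which avoids Apriori-style candidate
generation.  Rules {X -> Y} are scored by support and lift,

    lift(X -> Y) = support(X u Y) / (support(X) * support(Y)),

the ratio of the observed support to the support expected were X and Y
independent; only support and lift are used for filtering.  Rule direction
is retained in the output but expresses co-occurrence, not causation, and
is ignored by every downstream consumer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

__all__ = [
    "MiningParams",
    "AssociationRule",
    "mine_frequent_itemsets",
    "itemsets_to_rules",
    "oud_comorbidities_from_rules",
    "precision_recall",
    "effective_min_count",
    "write_rules",
    "read_rules",
]


@dataclass(frozen=True)
class MiningParams:
    """Thresholds for mining.

    ``min_support`` is a fraction of transactions (default 2e-6, tuned for
    corpora of ~1e7 reports); ``min_support_count`` overrides the implied
    absolute count, which matters on small synthetic corpora where
    ``min_support * n`` would round up to a single transaction.
    ``max_pattern_size`` caps |X u Y|.
    """

    min_support: float = 0.000002
    max_pattern_size: int = 3
    min_lift: float = 1.0
    min_support_count: Optional[int] = None

    def __post_init__(self):
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError("min_support must lie in (0, 1]")
        if self.max_pattern_size < 2:
            raise ValueError("max_pattern_size must be >= 2")
        if self.min_lift <= 0:
            raise ValueError("min_lift must be positive")
        if self.min_support_count is not None and self.min_support_count < 1:
            raise ValueError("min_support_count must be >= 1")


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    def __post_init__(self):
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> frozenset:
        return self.antecedent | self.consequent


def effective_min_count(params: MiningParams, n_transactions: int) -> int:
    if params.min_support_count is not None:
        return params.min_support_count
    return max(1, math.ceil(params.min_support * n_transactions))


def _item_sets(transactions: Iterable) -> list[frozenset]:
    """Accept bare item sets or (case_id, items) pairs."""
    out = []
    for t in transactions:
        if isinstance(t, tuple) and len(t) == 2 and not isinstance(t[1], str):
            t = t[1]
        out.append(frozenset(t))
    return out


# ---------------------------------------------------------------------------
# FP-tree

class _Node:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, count, parent):
        self.item = item
        self.count = count
        self.parent = parent
        self.children = {}


class _FPTree:
    """Prefix tree over frequency-ordered transactions with a header table."""

    def __init__(self, weighted_transactions, min_count):
        weighted_transactions = list(weighted_transactions)
        counts = {}
        for items, w in weighted_transactions:
            for it in items:
                counts[it] = counts.get(it, 0) + w
        self.item_counts = {it: c for it, c in counts.items() if c >= min_count}
        # descending frequency, ties broken lexicographically for determinism
        self.order = sorted(self.item_counts, key=lambda it: (-self.item_counts[it], it))
        rank = {it: i for i, it in enumerate(self.order)}
        self.root = _Node(None, 0, None)
        self.header: dict = {it: [] for it in self.order}
        for items, w in weighted_transactions:
            path = sorted((it for it in items if it in rank), key=rank.__getitem__)
            node = self.root
            for it in path:
                child = node.children.get(it)
                if child is None:
                    child = _Node(it, 0, node)
                    node.children[it] = child
                    self.header[it].append(child)
                child.count += w
                node = child

    def prefix_paths(self, item):
        """Conditional pattern base: (path items above node, node count)."""
        paths = []
        for node in self.header[item]:
            path = []
            up = node.parent
            while up.item is not None:
                path.append(up.item)
                up = up.parent
            if path:
                paths.append((path, node.count))
        return paths


def _mine(tree: _FPTree, suffix: frozenset, min_count: int, max_size: int, out: dict):
    # items visited in ascending frequency (classic FP-growth order)
    for item in reversed(tree.order):
        support = tree.item_counts[item]
        itemset = suffix | {item}
        out[itemset] = support
        if len(itemset) < max_size:
            base = tree.prefix_paths(item)
            if base:
                cond = _FPTree(base, min_count)
                if cond.order:
                    _mine(cond, itemset, min_count, max_size, out)


def mine_frequent_itemsets(
    transactions: Iterable, params: MiningParams
) -> dict[frozenset, float]:
    """All itemsets of size 1..max_pattern_size meeting the support threshold.

    Returns a map itemset -> support fraction (exact count / n).  Raises on
    an empty transaction collection.
    """
    sets = _item_sets(transactions)
    if not sets:
        raise ValueError("transaction collection is empty")
    n = len(sets)
    min_count = effective_min_count(params, n)
    tree = _FPTree(((s, 1) for s in sets), min_count)
    counts: dict[frozenset, int] = {}
    _mine(tree, frozenset(), min_count, params.max_pattern_size, counts)
    return {itemset: c / n for itemset, c in counts.items()}


# ---------------------------------------------------------------------------
# rules

def itemsets_to_rules(
    itemsets: dict[frozenset, float], params: MiningParams
) -> list[AssociationRule]:
    """Emit every ordered partition {X -> Y} of each frequent itemset.

    For an itemset of size k this yields 2^k - 2 rules (all non-empty
    disjoint ordered splits).  Rules with lift below ``min_lift`` are
    dropped.  Requires subset supports to be present (guaranteed by
    anti-monotonicity when ``itemsets`` comes from the miner).
    """
    rules = []
    for itemset, support in sorted(
        itemsets.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                X = frozenset(ante)
                Y = itemset - X
                try:
                    s_x = itemsets[X]
                    s_y = itemsets[Y]
                except KeyError as exc:
                    raise ValueError(
                        f"missing subset support for {set(exc.args[0]) if isinstance(exc.args[0], frozenset) else exc.args[0]}"
                    ) from exc
                lift = support / (s_x * s_y)
                if lift >= params.min_lift:
                    rules.append(
                        AssociationRule(
                            antecedent=X,
                            consequent=Y,
                            support=support,
                            confidence=support / s_x,
                            lift=lift,
                        )
                    )
    return rules


def oud_comorbidities_from_rules(
    rules: Iterable[AssociationRule], oud_label: str
) -> set:
    """All diseases presenting together with the OUD label in any rule."""
    out: set = set()
    for rule in rules:
        items = rule.items
        if oud_label in items:
            out |= items - {oud_label}
    return out


def precision_recall(predicted: set, gold: set) -> tuple[float, float]:
    """Set-overlap precision and recall of predicted comorbidities."""
    if not gold:
        raise ValueError("gold-standard set must be non-empty")
    hits = len(set(predicted) & set(gold))
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(gold)
    return precision, recall


def rule_counts(rules: Sequence[AssociationRule]) -> dict:
    """Rule tallies, both as ordered partitions and as unordered {X, Y} pairs."""
    unordered = {
        (rule.items, frozenset((rule.antecedent, rule.consequent)))
        for rule in rules
    }
    return {"ordered": len(rules), "unordered_pairs": len(unordered)}


# ---------------------------------------------------------------------------
# TSV round-trip

def write_rules(rules: Sequence[AssociationRule], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("antecedent\tconsequent\tsupport\tconfidence\tlift\n")
        for r in rules:
            fh.write(
                f"{';'.join(sorted(r.antecedent))}\t{';'.join(sorted(r.consequent))}"
                f"\t{r.support!r}\t{r.confidence!r}\t{r.lift!r}\n"
            )


def read_rules(path) -> list[AssociationRule]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("antecedent"):
            raise ValueError(f"unexpected rules header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ante, cons, support, confidence, lift = line.split("\t")
            out.append(
                AssociationRule(
                    antecedent=frozenset(ante.split(";")),
                    consequent=frozenset(cons.split(";")),
                    support=float(support),
                    confidence=float(confidence),
                    lift=float(lift),
                )
            )
    return out
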