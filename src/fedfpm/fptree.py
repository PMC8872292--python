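"""FP-tree construction and frequent-itemset mining (FP-Growth).

The FP-tree is a prefix tree over support-filtered transactions: items in
each transaction are sorted by a fixed total order and inserted root-down,
so transactions sharing a prefix share nodes whose counts accumulate. A
header table chains all nodes carrying the same item, which makes the
item's prefix paths (its *conditional pattern base*) cheap to collect.
Mining recurses: for each item, project the conditional pattern base into
a conditional FP-tree and mine that, growing the suffix.

This implementation favors verifiability over raw speed: counts are plain
integers, recursion follows the textbook pattern-base scheme, and there is
no pruning beyond the support threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .rulestats import Itemset, canonical

Transaction = Iterable[str]
#: (itemset, weight) pairs — conditional pattern bases carry node counts.
WeightedTransaction = tuple[Itemset, int]


class FPNode:
    """One node of an FP-tree: an item with the count of transactions whose
    sorted prefix passes through it."""

    __slots__ = ("item", "count", "parent", "children", "node_link")

    def __init__(self, item: str | None, count: int = 0, parent: "FPNode | None" = None):
        self.item = item          # None marks the root
        self.count = count
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.node_link: FPNode | None = None

    def prefix_path(self) -> Itemset:
        """Items on the path from this node's parent up to (not incl.) root."""
        path = []
        node = self.parent
        while node is not None and node.item is not None:
            path.append(node.item)
            node = node.parent
        return tuple(reversed(path))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"FPNode({self.item!r}, count={self.count})"


class _HeaderEntry:
    __slots__ = ("count", "head", "tail")

    def __init__(self):
        self.count = 0
        self.head: FPNode | None = None
        self.tail: FPNode | None = None

    def append(self, node: FPNode) -> None:
        if self.head is None:
            self.head = self.tail = node
        else:
            self.tail.node_link = node
            self.tail = node

    def chain(self):
        node = self.head
        while node is not None:
            yield node
            node = node.node_link


class FPTree:
    """Prefix tree plus header table; also represents conditional trees."""

    def __init__(self, min_count: int, item_order: Sequence[str]):
        if min_count < 0:
            raise ValueError("min_count must be non-negative")
        self.root = FPNode(None)
        self.min_count = min_count
        #: rank of each insertable item; lower rank = closer to the root
        self.item_rank: dict[str, int] = {it: i for i, it in enumerate(item_order)}
        self.header: dict[str, _HeaderEntry] = {}

    @property
    def items(self) -> list[str]:
        """Header items in insertion (item_order) rank."""
        return sorted(self.header, key=self.item_rank.__getitem__)

    def header_counts(self) -> dict[str, int]:
        return {item: entry.count for item, entry in self.header.items()}

    def insert(self, items: Sequence[str], weight: int = 1) -> None:
        """Insert an already filtered+ordered transaction with a weight."""
        node = self.root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, 0, parent=node)
                node.children[item] = child
                entry = self.header.setdefault(item, _HeaderEntry())
                entry.append(child)
            child.count += weight
            self.header[item].count += weight
            node = child

    def is_empty(self) -> bool:
        return not self.header

    def to_text(self) -> str:
        """Indented debug dump, deterministic (children in item-rank order)."""
        lines: list[str] = []

        def walk(node: FPNode, depth: int) -> None:
            for item in sorted(node.children, key=self.item_rank.__getitem__):
                child = node.children[item]
                lines.append(f"{'  ' * depth}{item} ({child.count})")
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def item_frequencies(
    transactions: Iterable[Transaction], weights: Sequence[int] | None = None
) -> Counter:
    """Weighted per-item occurrence counts (each item once per transaction)."""
    counts: Counter = Counter()
    if weights is None:
        for t in transactions:
            counts.update(set(t))
    else:
        for t, w in zip(transactions, weights):
            for item in set(t):
                counts[item] += w
    return counts


def frequency_order(counts: Mapping[str, int]) -> list[str]:
    """Canonical FP-Growth insertion order: descending frequency,
    lexicographic tie-break."""
    return sorted(counts, key=lambda item: (-counts[item], item))


def build_tree(
    transactions: Iterable[Transaction],
    min_count: int,
    item_order: Sequence[str] | None = None,
    weights: Sequence[int] | None = None,
) -> FPTree:
    """Build an FP-tree from (optionally weighted) transactions.

    Items whose total count falls below ``min_count`` are dropped before
    insertion; the survivors of each transaction are inserted root-down in
    ``item_order`` (default: descending global frequency, lexicographic
    tie-break).
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    transactions = [canonical(t) for t in transactions]
    if weights is not None and len(weights) != len(transactions):
        raise ValueError("weights must align with transactions")
    counts = item_frequencies(transactions, weights)
    surviving = {item: c for item, c in counts.items() if c >= min_count}
    if item_order is None:
        order = frequency_order(surviving)
    else:
        order = [it for it in item_order if it in surviving]
        missing = set(surviving) - set(order)
        if missing:
            raise ValueError(f"item_order does not cover items {sorted(missing)}")
    tree = FPTree(min_count, order)
    rank = tree.item_rank
    for i, t in enumerate(transactions):
        kept = sorted((it for it in t if it in surviving), key=rank.__getitem__)
        if kept:
            tree.insert(kept, 1 if weights is None else weights[i])
    return tree


def conditional_pattern_base(tree: FPTree, item: str) -> list[WeightedTransaction]:
    """Prefix paths of ``item``, each weighted by the item node's count."""
    if item not in tree.header:
        raise KeyError(f"item {item!r} not in tree header")
    base: list[WeightedTransaction] = []
    for node in tree.header[item].chain():
        path = node.prefix_path()
        if path:
            base.append((path, node.count))
    return base


def conditional_tree(tree: FPTree, item: str, min_count: int | None = None) -> FPTree:
    """FP-tree of ``item``'s conditional pattern base.

    Its transactions are the co-occurrence contexts of ``item``; counts are
    propagated from the item's nodes. ``min_count`` defaults to the parent
    tree's threshold.
    """
    base = conditional_pattern_base(tree, item)
    eff = tree.min_count if min_count is None else min_count
    return build_tree(
        [p for p, _ in base], eff, weights=[w for _, w in base]
    )


@dataclass(frozen=True)
class FrequentItemset:
    """A non-empty itemset with its exact supporting-transaction count."""

    items: Itemset
    count: int

    def __post_init__(self):
        if not self.items:
            raise ValueError("frequent itemset must be non-empty")
        if self.items != canonical(self.items):
            raise ValueError("items not in canonical form")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def mine_itemsets(
    transactions: Iterable[Transaction], min_count: int
) -> list[FrequentItemset]:
    """All itemsets with support count >= min_count, with exact counts.

    A zero ``min_count`` behaves as 1: an itemset must occur in the data to
    be reported. Output is sorted by itemset size, then lexicographically.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    eff = max(1, min_count)
    out: list[FrequentItemset] = []
    tree = build_tree(transactions, eff)
    _mine_tree(tree, (), eff, out)
    out.sort(key=lambda f: (len(f.items), f.items))
    return out


def _mine_tree(tree: FPTree, suffix: Itemset, eff: int, out: list[FrequentItemset]) -> None:
    # least-frequent header item first: its conditional base is smallest
    for item in reversed(tree.items):
        count = tree.header[item].count
        new_suffix = canonical(suffix + (item,))
        out.append(FrequentItemset(new_suffix, count))
        ctree = conditional_tree(tree, item, min_count=eff)
        if not ctree.is_empty():
            _mine_tree(ctree, new_suffix, eff, out)
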