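"""From-scratch FP-growth frequent-itemset mining.

FP-growth compresses the transaction database into a prefix tree
(FP-tree) in two database scans — one to count item frequencies, one to
insert each transaction's frequent items in a canonical order — then
mines frequent itemsets recursively over conditional pattern bases,
avoiding Apriori's repeated full scans.  An Apriori-style brute-force
miner with the identical contract is provided as an independent oracle
for equivalence testing on small instances.

Canonical item order is global support descending with lexicographic
tie-break, which makes tree construction and mining output fully
deterministic.  Support comparisons are inclusive (count >= minsup * N)
and performed on integer counts with a tiny absolute tolerance so a
fractional threshold never misclassifies at a float boundary.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .basket_encoder import TransactionDB
from .survey_model import ValidationError

__all__ = [
    "FrequentItemset",
    "FPTree",
    "FPNode",
    "build_fptree",
    "mine_frequent",
    "apriori_oracle",
    "canonical_order",
]

# Absolute slack applied when comparing an integer count with minsup * N,
# so e.g. count 150 passes a threshold stored as 150.00000000000003.
_TOL = 1e-12


def _check_minsup(minsup: float) -> None:
    if not 0.0 < minsup <= 1.0:
        raise ValidationError(f"minsup must be in (0, 1], got {minsup}")


def canonical_order(counts: dict[str, int]) -> list[str]:
    """Items sorted by global support descending, ties lexicographic."""
    return sorted(counts, key=lambda i: (-counts[i], i))


@dataclass(frozen=True)
class FrequentItemset:
    """A mined itemset with its exact support count and fraction."""

    items: frozenset[str]
    count: int
    support: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))


class FPNode:
    """One FP-tree node: an item with a prefix-path count."""

    __slots__ = ("item", "count", "parent", "children", "link")

    def __init__(self, item: str | None, parent: "FPNode | None") -> None:
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.link: FPNode | None = None


class FPTree:
    """Prefix tree over frequency-ordered transactions with node links.

    The header table maps each frequent item to the head of its
    node-link chain and its total supporting count.
    """

    def __init__(self, rank: dict[str, int]) -> None:
        self.root = FPNode(None, None)
        self.rank = rank  # item -> canonical position (0 = most frequent)
        self.header: dict[str, FPNode] = {}
        self.counts: dict[str, int] = defaultdict(int)
        self._tails: dict[str, FPNode] = {}

    def insert(self, items: Sequence[str], count: int = 1) -> None:
        """Insert one transaction's frequent items, already rank-sorted."""
        node = self.root
        for item in items:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                if item in self._tails:
                    self._tails[item].link = child
                else:
                    self.header[item] = child
                self._tails[item] = child
            child.count += count
            self.counts[item] += count
            node = child

    def node_links(self, item: str) -> Iterable[FPNode]:
        node = self.header.get(item)
        while node is not None:
            yield node
            node = node.link

    def prefix_paths(self, item: str) -> list[tuple[tuple[str, ...], int]]:
        """Conditional pattern base: prefix path + count per node of item."""
        paths = []
        for node in self.node_links(item):
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                paths.append((tuple(reversed(path)), node.count))
        return paths

    def single_path(self) -> list[tuple[str, int]] | None:
        """Return the (item, count) chain if the tree is one path, else None."""
        chain = []
        node = self.root
        while node.children:
            if len(node.children) > 1:
                return None
            (node,) = node.children.values()
            chain.append((node.item, node.count))
        return chain


def _build_tree(
    weighted: Iterable[tuple[Iterable[str], int]],
    item_counts: dict[str, int],
    threshold: float,
) -> FPTree:
    frequent = {i: c for i, c in item_counts.items() if c >= threshold - _TOL}
    rank = {item: pos for pos, item in enumerate(canonical_order(frequent))}
    tree = FPTree(rank)
    for items, count in weighted:
        kept = sorted((i for i in items if i in rank), key=rank.__getitem__)
        if kept:
            tree.insert(kept, count)
    return tree


def build_fptree(db: TransactionDB, minsup: float) -> FPTree:
    """Two-scan FP-tree construction over a transaction database.

    Scan 1 counts item frequencies and prunes items with support below
    ``minsup``; scan 2 inserts each transaction's surviving items in
    canonical (frequency-descending) order.
    """
    _check_minsup(minsup)
    counts: Counter[str] = Counter()
    for items in db.itemsets():
        counts.update(items)
    return _build_tree(
        ((items, 1) for items in db.itemsets()), dict(counts), minsup * db.n
    )


def _mine_tree(
    tree: FPTree,
    suffix: frozenset[str],
    threshold: float,
    out: dict[frozenset[str], int],
    max_len: int | None,
) -> None:
    path = tree.single_path()
    if path is not None:
        # Single-path shortcut: every combination of path items extends the
        # suffix, with count = min count along the chosen items.
        for r in range(1, len(path) + 1):
            if max_len is not None and len(suffix) + r > max_len:
                break
            for combo in combinations(path, r):
                itemset = suffix | frozenset(i for i, _ in combo)
                out[itemset] = min(c for _, c in combo)
        return
    # Process items least-frequent first (reverse canonical order).
    for item in sorted(tree.header, key=tree.rank.__getitem__, reverse=True):
        count = tree.counts[item]
        itemset = suffix | {item}
        out[itemset] = count
        if max_len is not None and len(itemset) >= max_len:
            continue
        base = tree.prefix_paths(item)
        if not base:
            continue
        cond_counts: dict[str, int] = defaultdict(int)
        for path_items, c in base:
            for i in path_items:
                cond_counts[i] += c
        cond_tree = _build_tree(base, dict(cond_counts), threshold)
        if cond_tree.header:
            _mine_tree(cond_tree, itemset, threshold, out, max_len)


def mine_frequent(
    db: TransactionDB,
    minsup: float,
    max_len: int | None = None,
) -> set[FrequentItemset]:
    """All itemsets with support >= minsup, with exact supports.

    Recursive divide and conquer over conditional FP-trees; optional
    ``max_len`` caps the itemset size (no cap by default).
    """
    _check_minsup(minsup)
    tree = build_fptree(db, minsup)
    threshold = minsup * db.n
    found: dict[frozenset[str], int] = {}
    _mine_tree(tree, frozenset(), threshold, found, max_len)
    return {
        FrequentItemset(items, count, count / db.n)
        for items, count in found.items()
    }


def apriori_oracle(
    db: TransactionDB,
    minsup: float,
    max_len: int | None = None,
) -> set[FrequentItemset]:
    """Brute-force level-wise miner with the same contract as mine_frequent.

    Candidate generation joins frequent (k-1)-itemsets sharing a prefix
    and prunes candidates with any infrequent subset; supports come from
    a full database scan per level.  Intended for small instances.
    """
    _check_minsup(minsup)
    itemsets = db.itemsets()
    n = db.n
    threshold = minsup * n - _TOL

    def count(cand: frozenset[str]) -> int:
        return sum(1 for t in itemsets if cand <= t)

    singles = sorted({i for t in itemsets for i in t})
    level = {}
    for i in singles:
        c = count(frozenset([i]))
        if c >= threshold:
            level[frozenset([i])] = c
    result = dict(level)
    k = 2
    while level and (max_len is None or k <= max_len):
        frequent_prev = set(level)
        ordered = sorted(level, key=lambda s: tuple(sorted(s)))
        candidates = set()
        for a, b in combinations(ordered, 2):
            union = a | b
            if len(union) != k:
                continue
            if all(frozenset(sub) in frequent_prev for sub in combinations(union, k - 1)):
                candidates.add(union)
        level = {}
        for cand in candidates:
            c = count(cand)
            if c >= threshold:
                level[cand] = c
        result.update(level)
        k += 1
    return {
        FrequentItemset(items, c, c / n) for items, c in result.items()
    }
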