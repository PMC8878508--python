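"""Association-rule generation and support/confidence/lift filtering.

A rule r: X1 -> X2 relates two disjoint itemsets.  Support is the
fraction of transactions containing X1 and X2 together; confidence is
s(X1 u X2) / s(X1), the conditional frequency of the consequent among
antecedent transactions; lift is confidence / s(X2), equal to 1 under
independence.  Rules are kept when confidence >= minconf and
lift > minlift (the lift filter is strict); support filtering happens
upstream at mining time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .basket_encoder import TransactionDB
from .fpgrowth import FrequentItemset
from .survey_model import ValidationError

__all__ = [
    "AssociationRule",
    "MinerConfig",
    "support_of",
    "count_of",
    "confidence_of",
    "lift_of",
    "generate_rules",
]

_TOL = 1e-12


@dataclass(frozen=True)
class AssociationRule:
    """An antecedent -> consequent rule with its three quality metrics."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", frozenset(self.antecedent))
        object.__setattr__(self, "consequent", frozenset(self.consequent))
        if not self.antecedent or not self.consequent:
            raise ValidationError("rule sides must be non-empty")
        if self.antecedent & self.consequent:
            raise ValidationError("antecedent and consequent must be disjoint")

    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Identity for deduplication: the (antecedent, consequent) pair."""
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))


@dataclass(frozen=True)
class MinerConfig:
    """Mining thresholds and rule-shape options.

    Defaults: minsup 0.20, minconf 0.70, lift > 1.20, single-item
    consequents.
    """

    minsup: float = 0.20
    minconf: float = 0.70
    minlift: float = 1.20
    consequent_size: str = "single"

    def __post_init__(self) -> None:
        if not 0.0 < self.minsup <= 1.0:
            raise ValidationError(f"minsup must be in (0, 1], got {self.minsup}")
        if not 0.0 <= self.minconf <= 1.0:
            raise ValidationError(f"minconf must be in [0, 1], got {self.minconf}")
        if self.consequent_size not in ("single", "any"):
            raise ValidationError(
                f"consequent_size must be 'single' or 'any', got {self.consequent_size!r}"
            )


def count_of(itemset: Iterable[str], db: TransactionDB) -> int:
    """Number of transactions containing every item of the itemset."""
    items = frozenset(itemset)
    if not items:
        raise ValidationError("support of the empty itemset is undefined here")
    return sum(1 for t in db.itemsets() if items <= t)


def support_of(itemset: Iterable[str], db: TransactionDB) -> float:
    """Fraction of transactions containing the itemset."""
    return count_of(itemset, db) / db.n


def confidence_of(
    antecedent: Iterable[str],
    consequent: Iterable[str],
    db: TransactionDB,
) -> float:
    """s(X1 u X2) / s(X1) for the rule X1 -> X2."""
    x1 = frozenset(antecedent)
    x2 = frozenset(consequent)
    c1 = count_of(x1, db)
    if c1 == 0:
        raise ValidationError("confidence undefined: antecedent support is zero")
    return count_of(x1 | x2, db) / c1


def lift_of(
    antecedent: Iterable[str],
    consequent: Iterable[str],
    db: TransactionDB,
) -> float:
    """confidence / s(X2); 1 under independence."""
    x2 = frozenset(consequent)
    s2 = support_of(x2, db)
    if s2 == 0:
        raise ValidationError("lift undefined: consequent support is zero")
    return confidence_of(antecedent, x2, db) / s2


def _splits(items: frozenset[str], consequent_size: str):
    ordered = sorted(items)
    if consequent_size == "single":
        sizes = [1]
    else:
        sizes = range(1, len(ordered))
    for k in sizes:
        for cons in combinations(ordered, k):
            consequent = frozenset(cons)
            antecedent = items - consequent
            if antecedent:
                yield antecedent, consequent


def generate_rules(
    frequents: Iterable[FrequentItemset],
    db: TransactionDB,
    config: MinerConfig = MinerConfig(),
) -> list[AssociationRule]:
    """Enumerate rule splits of each frequent itemset and filter.

    ``frequents`` must have been mined from ``db`` at ``config.minsup``
    (so every subset of a kept itemset is present with its exact count,
    by antimonotonicity).  Keeps rules with confidence >= minconf and
    lift strictly above minlift; output sorted by (support, confidence,
    lift) descending, then canonical itemset order.
    """
    counts: dict[frozenset[str], int] = {f.items: f.count for f in frequents}
    n = db.n
    rules: list[AssociationRule] = []
    seen: set[tuple] = set()
    for itemset, joint in counts.items():
        if len(itemset) < 2:
            continue
        for antecedent, consequent in _splits(itemset, config.consequent_size):
            if antecedent not in counts or consequent not in counts:
                raise ValidationError(
                    "frequent set is not subset-closed; was it mined from this "
                    "db at config.minsup?"
                )
            confidence = joint / counts[antecedent]
            if confidence < config.minconf - _TOL:
                continue
            lift = confidence * n / counts[consequent]
            if lift - config.minlift <= _TOL:
                continue
            rule = AssociationRule(
                antecedent, consequent, joint / n, confidence, lift
            )
            if rule.key() in seen:
                continue
            seen.add(rule.key())
            rules.append(rule)
    rules.sort(
        key=lambda r: (-r.support, -r.confidence, -r.lift, r.key())
    )
    return rules
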