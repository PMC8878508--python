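"""Market-basket encoding of domain-score vectors.

Each participant becomes one transaction whose items are domain-score
tokens of the form ``"<domain_code>-<score>"`` ("C1-3", "W2-1") plus a
bare cohort-tag item ("10" for undergraduates, "20" for graduates), so
that cohort membership participates in mining like any other item.
With six 5-point domains, three 4-point domains and two tags the full
vocabulary holds at most 6*5 + 3*4 + 2 = 44 tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .survey_model import (
    DEFAULT_SUBSCALES,
    DomainScoreVector,
    SubscaleDefinition,
    ValidationError,
)

__all__ = [
    "EncodingError",
    "ParseError",
    "DEFAULT_TAGS",
    "Transaction",
    "TransactionDB",
    "domain_registry",
    "encode_item",
    "decode_item",
    "cohort_tag",
    "decode_cohort_tag",
    "is_cohort_tag",
    "full_vocabulary",
    "encode_cohort",
    "read_baskets",
    "write_baskets",
]

logger = logging.getLogger(__name__)

# Tag mapping per the published rule tables; configurable because the
# source material is internally inconsistent about which tag is which.
DEFAULT_TAGS: Mapping[str, str] = {"undergraduate": "10", "graduate": "20"}


class EncodingError(ValidationError):
    pass


class ParseError(ValidationError):
    pass


def domain_registry(
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> dict[str, int]:
    """Map domain_code -> scale_points for the configured domains."""
    return {d.domain_code: d.scale_points for d in subscales}


def encode_item(
    domain_code: str,
    score: int,
    domains: Mapping[str, int] | None = None,
) -> str:
    """Concatenate domain code and score into one basket item token."""
    domains = domain_registry() if domains is None else domains
    if domain_code not in domains:
        raise EncodingError(f"unknown domain {domain_code!r}")
    if not 1 <= score <= domains[domain_code]:
        raise EncodingError(
            f"score {score} outside 1..{domains[domain_code]} for {domain_code}"
        )
    return f"{domain_code}-{score}"


def decode_item(
    token: str,
    domains: Mapping[str, int] | None = None,
) -> tuple[str, int]:
    """Split a token back into (domain_code, score).

    The domain code is everything before the final hyphen; the trailing
    digit is the score.
    """
    domains = domain_registry() if domains is None else domains
    code, sep, digit = token.rpartition("-")
    if not sep or not digit.isdigit():
        raise ParseError(f"malformed item token {token!r}")
    score = int(digit)
    if code not in domains:
        raise ParseError(f"unknown domain in token {token!r}")
    if not 1 <= score <= domains[code]:
        raise ParseError(f"score out of range in token {token!r}")
    return code, score


def cohort_tag(cohort: str, tags: Mapping[str, str] = DEFAULT_TAGS) -> str:
    if cohort not in tags:
        raise EncodingError(f"unknown cohort {cohort!r}")
    return tags[cohort]


def decode_cohort_tag(token: str, tags: Mapping[str, str] = DEFAULT_TAGS) -> str:
    for cohort, tag in tags.items():
        if tag == token:
            return cohort
    raise ParseError(f"token {token!r} is not a cohort tag")


def is_cohort_tag(token: str, tags: Mapping[str, str] = DEFAULT_TAGS) -> bool:
    return token in set(tags.values())


def full_vocabulary(
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> frozenset[str]:
    """All tokens the configured instrument can produce (44 by default)."""
    vocab = {
        encode_item(d.domain_code, s, domain_registry(subscales))
        for d in subscales
        for s in range(1, d.scale_points + 1)
    }
    vocab |= set(tags.values())
    return frozenset(vocab)


@dataclass(frozen=True)
class Transaction:
    """The set of items 'purchased' by one participant."""

    participant_id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))


@dataclass
class TransactionDB:
    """Ordered collection of transactions plus its item vocabulary."""

    transactions: list[Transaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transactions:
            raise ValidationError("TransactionDB requires at least one transaction")

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for t in self.transactions:
            vocab |= t.items
        return frozenset(vocab)

    def itemsets(self) -> list[frozenset[str]]:
        return [t.items for t in self.transactions]

    @classmethod
    def from_itemsets(cls, itemsets: Iterable[Iterable[str]]) -> "TransactionDB":
        """Build a DB from bare item collections (ids are positional)."""
        return cls(
            [Transaction(f"t{i + 1}", frozenset(s)) for i, s in enumerate(itemsets)]
        )


def encode_cohort(
    scores: Sequence[DomainScoreVector],
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> TransactionDB:
    """Encode scored participants into one transaction each, in input order.

    Participants missing any configured domain score are excluded with a
    logged warning (complete-case encoding).
    """
    domains = domain_registry(subscales)
    seen: set[str] = set()
    transactions: list[Transaction] = []
    for v in scores:
        if v.participant_id in seen:
            raise EncodingError(f"duplicate participant_id {v.participant_id!r}")
        seen.add(v.participant_id)
        missing = [c for c in domains if c not in v.scores]
        if missing:
            logger.warning(
                "participant %s missing domains %s; excluded from encoding",
                v.participant_id, missing,
            )
            continue
        items = {encode_item(c, v.scores[c], domains) for c in domains}
        items.add(cohort_tag(v.cohort, tags))
        transactions.append(Transaction(v.participant_id, frozenset(items)))
    if not transactions:
        raise EncodingError("no encodable participants (empty input?)")
    return TransactionDB(transactions)


def _canonical_line(items: frozenset[str]) -> str:
    return " ".join(sorted(items))


def write_baskets(db: TransactionDB, path: str | Path) -> None:
    """Write one transaction per line, tokens lexicographically sorted."""
    path = Path(path)
    with path.open("w") as fh:
        for t in db.transactions:
            fh.write(_canonical_line(t.items) + "\n")


def read_baskets(
    path: str | Path,
    subscales: Sequence[SubscaleDefinition] | None = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> TransactionDB:
    """Parse a basket text file (one transaction per line).

    Tokens are validated against the configured vocabulary; pass
    ``subscales=None`` to accept arbitrary tokens.
    """
    path = Path(path)
    domains = domain_registry(subscales) if subscales is not None else None
    transactions: list[Transaction] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if domains is not None:
                for tok in tokens:
                    if is_cohort_tag(tok, tags):
                        continue
                    try:
                        decode_item(tok, domains)
                    except ParseError as exc:
                        raise ParseError(f"{path}:{lineno}: {exc}") from exc
            transactions.append(Transaction(f"t{lineno}", frozenset(tokens)))
    if not transactions:
        raise ParseError(f"{path}: no transactions")
    return TransactionDB(transactions)
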