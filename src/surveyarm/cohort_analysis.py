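"""Cohort-level rule mining, decoding, and comparison.

Runs the mining pipeline over a tagged transaction database and
attributes each rule to a student cohort.  In the default *combined*
mode the whole database is mined with cohort tags as ordinary items and
a rule belongs to the cohort whose tag sits in its antecedent (the tag
is stripped for reporting); tag-free rules are cohort-independent and
reported under "both".  The alternative *stratified* mode mines each
cohort's transactions separately with tags removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .basket_encoder import (
    DEFAULT_TAGS,
    Transaction,
    TransactionDB,
    decode_cohort_tag,
    decode_item,
    domain_registry,
    is_cohort_tag,
)
from .fpgrowth import mine_frequent
from .rule_engine import AssociationRule, MinerConfig, generate_rules
from .survey_model import DEFAULT_SUBSCALES, SubscaleDefinition, ValidationError

__all__ = [
    "CohortRuleReport",
    "mine_by_cohort",
    "strip_tags",
    "decode_token",
    "decode_rule",
    "build_report",
    "compare_cohorts",
    "BOTH",
]

BOTH = "both"


def strip_tags(
    rule: AssociationRule, tags: Mapping[str, str] = DEFAULT_TAGS
) -> tuple[frozenset[str], frozenset[str]]:
    """Rule identity with cohort tags removed from both sides."""
    tagset = frozenset(tags.values())
    return (rule.antecedent - tagset, rule.consequent - tagset)


def mine_by_cohort(
    db: TransactionDB,
    config: MinerConfig = MinerConfig(),
    tags: Mapping[str, str] = DEFAULT_TAGS,
    mode: str = "combined",
) -> dict[str, list[AssociationRule]]:
    """Mine rules and attribute them to cohorts.

    combined: one mine over the full database, tags as items; a rule
    with a cohort tag in its antecedent goes to that cohort, a rule with
    no tag (or a tag only in the consequent) goes to "both".  Support is
    computed over the full database.

    stratified: per-cohort mining with tags removed from transactions.
    """
    tagset = frozenset(tags.values())
    if not any(t.items & tagset for t in db.transactions):
        raise ValidationError("database carries no cohort tags")
    if mode == "combined":
        frequents = mine_frequent(db, config.minsup)
        rules = generate_rules(frequents, db, config)
        out: dict[str, list[AssociationRule]] = {c: [] for c in tags}
        out[BOTH] = []
        for rule in rules:
            ante_tags = rule.antecedent & tagset
            if len(ante_tags) == 1:
                cohort = decode_cohort_tag(next(iter(ante_tags)), tags)
                out[cohort].append(rule)
            else:
                # no tag, both tags (impossible within one transaction at
                # minsup > 0 unless cohorts overlap), or tag in consequent
                out[BOTH].append(rule)
        return out
    if mode == "stratified":
        out = {c: [] for c in tags}
        out[BOTH] = []
        for cohort, tag in tags.items():
            kept = [
                Transaction(t.participant_id, t.items - tagset)
                for t in db.transactions
                if tag in t.items
            ]
            kept = [t for t in kept if t.items]
            if not kept:
                continue
            sub = TransactionDB(kept)
            frequents = mine_frequent(sub, config.minsup)
            out[cohort] = generate_rules(frequents, sub, config)
        return out
    raise ValidationError(f"unknown mode {mode!r}")


def _label_maps(
    subscales: Sequence[SubscaleDefinition],
) -> tuple[dict[str, str], dict[str, Mapping[int, str]]]:
    names = {d.domain_code: d.name for d in subscales}
    labels = {d.domain_code: d.score_labels for d in subscales}
    return names, labels


def decode_token(
    token: str,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> str:
    """Human-readable reading of one item token.

    ``"C1-3"`` -> ``"Neutral, Emotionality"``; a cohort tag decodes to
    e.g. ``"Graduate student"``.
    """
    if is_cohort_tag(token, tags):
        return decode_cohort_tag(token, tags).capitalize() + " student"
    names, labels = _label_maps(subscales)
    code, score = decode_item(token, domain_registry(subscales))
    return f"{labels[code][score]}, {names[code]}"


def decode_rule(
    rule: AssociationRule,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> str:
    """Render a rule as readable text, sides joined by '=>'."""
    def side(items: frozenset[str]) -> str:
        if not items:
            return "(cohort membership alone)"
        return " AND ".join(decode_token(t, subscales, tags) for t in sorted(items))

    return f"{side(rule.antecedent)} => {side(rule.consequent)}"


@dataclass
class CohortRuleReport:
    """Decoded rule list for one cohort, with provenance."""

    cohort: str
    rules: list[AssociationRule]
    config: MinerConfig
    decoded: list[str] = field(default_factory=list)
    stripped: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.rules)


def build_report(
    cohort: str,
    rules: Sequence[AssociationRule],
    config: MinerConfig,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
    provenance: dict | None = None,
) -> CohortRuleReport:
    """Assemble the per-cohort report: raw rules, tag-stripped identities,
    and decoded interpretations (tags dropped from the antecedent text,
    mirroring how published rule tables omit the shared cohort item)."""
    stripped = [
        tuple(tuple(sorted(side)) for side in strip_tags(r, tags)) for r in rules
    ]
    decoded = []
    for r in rules:
        a, c = strip_tags(r, tags)
        shown = AssociationRule(a, c, r.support, r.confidence, r.lift) if a and c else r
        decoded.append(decode_rule(shown, subscales, tags))
    return CohortRuleReport(
        cohort=cohort,
        rules=list(rules),
        config=config,
        decoded=decoded,
        stripped=stripped,
        provenance=provenance or {},
    )


def compare_cohorts(report_a: CohortRuleReport, report_b: CohortRuleReport) -> dict:
    """Compare two cohorts' rule sets mined at identical thresholds.

    Shared rules are those identical after tag stripping; the rest are
    cohort-unique.  Returns counts and the rule identities involved.
    """
    if report_a.config != report_b.config:
        raise ValidationError(
            "reports were produced with different thresholds: "
            f"{report_a.config} vs {report_b.config}"
        )
    set_a = set(report_a.stripped)
    set_b = set(report_b.stripped)
    shared = set_a & set_b
    return {
        "cohorts": (report_a.cohort, report_b.cohort),
        "n_rules": {report_a.cohort: report_a.n_rules, report_b.cohort: report_b.n_rules},
        "n_shared": len(shared),
        "n_unique": {
            report_a.cohort: len(set_a - shared),
            report_b.cohort: len(set_b - shared),
        },
        "shared": sorted(shared),
        "unique": {
            report_a.cohort: sorted(set_a - shared),
            report_b.cohort: sorted(set_b - shared),
        },
        "thresholds": report_a.config,
    }
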