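"""Synthetic survey cohorts with plantable association structure.

Emulates the structure the analysis assumes: two student cohorts
(242 undergraduates, 275 graduates by default, N = 517), six 5-point
COVID adjustment domains and three 4-point coping domains, each score
drawn from a configurable marginal distribution, plus *planted rules* —
injected antecedent -> consequent dependencies with known prevalence
and conditional probability, so mined support/confidence/lift can be
checked against closed-form expectations.

Planting is overwrite-then-conditional-draw: with probability
``antecedent_prevalence`` a participant's antecedent domains are
overwritten to the rule's scores; given that, the consequent domain is
set to the rule's score with probability ``target_confidence`` and
otherwise redrawn from its marginal with the planted score excluded.
This keeps the expected rule metrics exact in closed form (assuming
planted rules touch pairwise disjoint domains).  One shared numpy
Generator drives every draw, so a seed reproduces whole cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .basket_encoder import DEFAULT_TAGS, cohort_tag, encode_item
from .survey_model import (
    COHORTS,
    DEFAULT_SUBSCALES,
    DomainScoreVector,
    SubscaleDefinition,
    ValidationError,
)

__all__ = [
    "PlantedRule",
    "GeneratorConfig",
    "DEFAULT_MARGINAL_5PT",
    "DEFAULT_MARGINAL_4PT",
    "default_marginals",
    "generate_cohort",
    "expected_rule_metrics",
    "planted_rule_itemsets",
]

# Mid-scale-skewed Likert marginals (typical survey shape).
DEFAULT_MARGINAL_5PT = (0.1, 0.2, 0.4, 0.2, 0.1)
DEFAULT_MARGINAL_4PT = (0.15, 0.35, 0.35, 0.15)


def default_marginals(
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> dict[str, tuple[float, ...]]:
    return {
        d.domain_code: (
            DEFAULT_MARGINAL_5PT if d.scale_points == 5 else DEFAULT_MARGINAL_4PT
        )
        for d in subscales
    }


@dataclass(frozen=True)
class PlantedRule:
    """A dependency injected into generated cohorts.

    ``antecedent`` maps domain codes to the scores forced when the rule
    fires; ``consequent`` is one (domain, score) pair set with
    probability ``target_confidence`` given the antecedent was planted.
    ``scope`` restricts planting to one cohort or applies to both.
    """

    antecedent: tuple[tuple[str, int], ...]
    consequent: tuple[str, int]
    target_confidence: float
    antecedent_prevalence: float
    scope: str = "both"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "antecedent", tuple(sorted(dict(self.antecedent).items()))
        )
        ante = dict(self.antecedent)
        if not ante:
            raise ValidationError("planted rule needs a non-empty antecedent")
        if self.consequent[0] in ante:
            raise ValidationError(
                "planted antecedent and consequent domains must be disjoint"
            )
        for p, name in (
            (self.target_confidence, "target_confidence"),
            (self.antecedent_prevalence, "antecedent_prevalence"),
        ):
            if not 0.0 < p <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {p}")
        if self.scope not in (*COHORTS, "both"):
            raise ValidationError(f"scope must be one of {COHORTS} or 'both'")

    @property
    def domains(self) -> frozenset[str]:
        return frozenset(dict(self.antecedent)) | {self.consequent[0]}


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort sizes, per-domain score marginals, planted rules, seed."""

    n_undergraduate: int = 242
    n_graduate: int = 275
    marginals: Mapping[str, tuple[float, ...]] = field(default_factory=default_marginals)
    planted: tuple[PlantedRule, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", tuple(self.planted))
        if self.n_undergraduate < 0 or self.n_graduate < 0:
            raise ValidationError("cohort sizes must be >= 0")
        if self.n_undergraduate + self.n_graduate == 0:
            raise ValidationError("at least one participant required")
        for code, probs in self.marginals.items():
            p = np.asarray(probs, dtype=float)
            if p.ndim != 1 or len(p) < 2 or (p < 0).any():
                raise ValidationError(f"bad marginal for {code}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValidationError(f"marginal for {code} must sum to 1")
        self._validate_planted()

    def _validate_planted(self) -> None:
        for rule in self.planted:
            for code in rule.domains:
                if code not in self.marginals:
                    raise ValidationError(f"planted rule uses unknown domain {code}")
            ante = dict(rule.antecedent)
            for code, score in (*ante.items(), rule.consequent):
                if not 1 <= score <= len(self.marginals[code]):
                    raise ValidationError(
                        f"planted score {score} out of range for {code}"
                    )
        # Overlapping planted antecedents with conflicting scores on a
        # shared domain would make the generative process ill-defined.
        for i, a in enumerate(self.planted):
            for b in self.planted[i + 1 :]:
                if a.scope != b.scope and "both" not in (a.scope, b.scope):
                    continue
                da, db = dict(a.antecedent), dict(b.antecedent)
                for code in set(da) & set(db):
                    if da[code] != db[code]:
                        raise ValidationError(
                            f"conflicting planted antecedents on domain {code}"
                        )

    @property
    def n_total(self) -> int:
        return self.n_undergraduate + self.n_graduate

    def cohort_fraction(self, scope: str) -> float:
        if scope == "both":
            return 1.0
        n = self.n_undergraduate if scope == "undergraduate" else self.n_graduate
        return n / self.n_total


def generate_cohort(config: GeneratorConfig) -> list[DomainScoreVector]:
    """Draw one synthetic cohort; fully reproducible from config.seed.

    Undergraduates come first (ids u0001..), then graduates (g0001..).
    Draw order is fixed: per-domain marginal draws in configured domain
    order, then planted-rule overwrites in config order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    cohorts = np.array(
        ["undergraduate"] * config.n_undergraduate + ["graduate"] * config.n_graduate
    )
    codes = list(config.marginals)
    scores = {}
    for code in codes:
        probs = np.asarray(config.marginals[code], dtype=float)
        scores[code] = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)

    for rule in config.planted:
        in_scope = (
            np.ones(n, dtype=bool) if rule.scope == "both" else cohorts == rule.scope
        )
        fire = (rng.random(n) < rule.antecedent_prevalence) & in_scope
        for code, score in rule.antecedent:
            scores[code][fire] = score
        c_code, c_score = rule.consequent
        hit = rng.random(n) < rule.target_confidence
        probs = np.asarray(config.marginals[c_code], dtype=float).copy()
        probs[c_score - 1] = 0.0
        probs /= probs.sum()
        redraw = rng.choice(np.arange(1, len(probs) + 1), size=n, p=probs)
        scores[c_code] = np.where(
            fire & hit, c_score, np.where(fire & ~hit, redraw, scores[c_code])
        )

    out = []
    for i in range(n):
        pid = (
            f"u{i + 1:04d}"
            if i < config.n_undergraduate
            else f"g{i - config.n_undergraduate + 1:04d}"
        )
        out.append(
            DomainScoreVector(
                pid, str(cohorts[i]), {c: int(scores[c][i]) for c in codes}
            )
        )
    return out


def expected_rule_metrics(
    rule: PlantedRule, config: GeneratorConfig
) -> tuple[float, float, float]:
    """Closed-form (support, confidence, lift) implied by the generator.

    Within the scoped population, with planting probability p, target
    confidence c, chance antecedent probability qA (product of the
    antecedent scores' marginals) and consequent marginal mB:

        P(A)      = p + (1-p) qA
        P(A & B)  = p c + (1-p) qA mB
        P(B)      = p c + (1-p) mB

    confidence = P(A & B) / P(A).  For a scoped rule the mined antecedent
    additionally carries the cohort tag, so support over the full
    database scales by the cohort fraction f and the consequent's full
    support mixes the other cohort's marginal back in:
    s(B) = f P(B) + (1-f) mB.  lift = confidence / s(B).

    Exact when planted rules touch pairwise disjoint domain sets.
    """
    if rule not in config.planted:
        raise ValidationError("rule is not part of this config")
    p = rule.antecedent_prevalence
    c = rule.target_confidence
    q_a = 1.0
    for code, score in rule.antecedent:
        q_a *= config.marginals[code][score - 1]
    c_code, c_score = rule.consequent
    m_b = config.marginals[c_code][c_score - 1]

    p_a = p + (1 - p) * q_a
    p_ab = p * c + (1 - p) * q_a * m_b
    p_b = p * c + (1 - p) * m_b
    confidence = p_ab / p_a

    f = config.cohort_fraction(rule.scope)
    support = f * p_ab
    s_b_full = f * p_b + (1 - f) * m_b
    lift = confidence / s_b_full
    return support, confidence, lift


def planted_rule_itemsets(
    rule: PlantedRule,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
    tags: Mapping[str, str] = DEFAULT_TAGS,
) -> tuple[frozenset[str], frozenset[str]]:
    """(antecedent, consequent) token sets the planted rule should mine as.

    A cohort-scoped rule's mined antecedent includes that cohort's tag.
    """
    registry = {d.domain_code: d.scale_points for d in subscales}
    ante = {encode_item(c, s, registry) for c, s in rule.antecedent}
    if rule.scope != "both":
        ante.add(cohort_tag(rule.scope, tags))
    cons = frozenset({encode_item(*rule.consequent, registry)})
    return frozenset(ante), cons
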