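"""Synthetic cohort generator: determinism, marginals, planted rules."""

import math

import numpy as np
import pytest

from surveyarm import (
    DEFAULT_SUBSCALES,
    GeneratorConfig,
    PlantedRule,
    encode_cohort,
    expected_rule_metrics,
    generate_cohort,
)
from surveyarm.survey_model import ValidationError
from surveyarm.synthetic_data import default_marginals


def test_default_config_reproduces_cohort_sizes():
    vectors = generate_cohort(GeneratorConfig(seed=1))
    assert len(vectors) == 517
    assert sum(v.cohort == "undergraduate" for v in vectors) == 242
    assert sum(v.cohort == "graduate" for v in vectors) == 275


def test_scores_in_range_no_planting():
    cfg = GeneratorConfig(n_undergraduate=5, n_graduate=5, seed=0)
    scales = {d.domain_code: d.scale_points for d in DEFAULT_SUBSCALES}
    for v in generate_cohort(cfg):
        for code, score in v.scores.items():
            assert 1 <= score <= scales[code]


def test_seed_determinism_byte_identical():
    cfg = GeneratorConfig(n_undergraduate=50, n_graduate=50, seed=123)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert [(v.participant_id, v.cohort, dict(v.scores)) for v in a] == [
        (v.participant_id, v.cohort, dict(v.scores)) for v in b
    ]


def test_different_seeds_differ():
    a = generate_cohort(GeneratorConfig(n_undergraduate=50, n_graduate=50, seed=1))
    b = generate_cohort(GeneratorConfig(n_undergraduate=50, n_graduate=50, seed=2))
    assert [dict(v.scores) for v in a] != [dict(v.scores) for v in b]


def test_marginal_fidelity_within_3_se():
    cfg = GeneratorConfig(n_undergraduate=5000, n_graduate=5000, seed=7)
    vectors = generate_cohort(cfg)
    n = len(vectors)
    for code, probs in cfg.marginals.items():
        counts = np.bincount([v.scores[code] for v in vectors], minlength=len(probs) + 1)
        for level, p in enumerate(probs, start=1):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(counts[level] / n - p) <= 3 * se + 1e-9


def test_conflicting_planted_antecedents_rejected():
    r1 = PlantedRule((("C1", 5),), ("C4", 5), 0.9, 0.4)
    r2 = PlantedRule((("C1", 2),), ("C2", 1), 0.9, 0.4)
    with pytest.raises(ValidationError, match="conflict"):
        GeneratorConfig(planted=(r1, r2))


def test_planted_antecedent_consequent_overlap_rejected():
    with pytest.raises(ValidationError, match="disjoint"):
        PlantedRule((("C1", 5),), ("C1", 3), 0.9, 0.4)


def test_planted_rule_empirical_confidence():
    """Planted (prevalence 0.4, confidence 0.9): empirical consequent
    frequency given the antecedent lands within ~2 binomial SEs of the
    closed-form expectation (which mixes in chance antecedents)."""
    rule = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=0.9,
                       antecedent_prevalence=0.4)
    cfg = GeneratorConfig(n_undergraduate=2500, n_graduate=2500, seed=11,
                          planted=(rule,))
    vectors = generate_cohort(cfg)
    _, conf_exp, _ = expected_rule_metrics(rule, cfg)
    with_ante = [v for v in vectors if v.scores["C1"] == 5]
    hits = sum(v.scores["C4"] == 5 for v in with_ante)
    emp = hits / len(with_ante)
    assert abs(emp - conf_exp) <= 0.03


def test_expected_metrics_degenerate_prevalence_one():
    rule = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=0.8,
                       antecedent_prevalence=1.0)
    cfg = GeneratorConfig(planted=(rule,))
    support, confidence, _ = expected_rule_metrics(rule, cfg)
    assert support == pytest.approx(0.8)
    assert confidence == pytest.approx(0.8)


def test_expected_metrics_independence_gives_unit_lift():
    # target confidence equal to the consequent marginal and vanishing
    # planting leaves the pair independent: lift -> 1
    m_b = default_marginals()["C4"][4]  # P(C4 = 5)
    rule = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=m_b,
                       antecedent_prevalence=1e-9)
    cfg = GeneratorConfig(planted=(rule,))
    _, confidence, lift = expected_rule_metrics(rule, cfg)
    assert confidence == pytest.approx(m_b, rel=1e-6)
    assert lift == pytest.approx(1.0, rel=1e-6)


def test_expected_metrics_hand_algebra():
    # prevalence 0.5, confidence 1.0, consequent marginal 0.1, antecedent
    # marginal 0.1: P(A)=0.55, P(AB)=0.505, P(B)=0.55
    rule = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=1.0,
                       antecedent_prevalence=0.5)
    cfg = GeneratorConfig(planted=(rule,))
    support, confidence, lift = expected_rule_metrics(rule, cfg)
    assert support == pytest.approx(0.5 + 0.5 * 0.1 * 0.1)
    assert confidence == pytest.approx((0.5 + 0.005) / 0.55)
    assert lift == pytest.approx(confidence / (0.5 + 0.5 * 0.1))


def test_scoped_rule_metrics_scale_by_cohort_fraction():
    rule = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=0.9,
                       antecedent_prevalence=0.4, scope="graduate")
    cfg = GeneratorConfig(n_undergraduate=250, n_graduate=250, planted=(rule,))
    support, confidence, lift = expected_rule_metrics(rule, cfg)
    both = PlantedRule((("C1", 5),), ("C4", 5), target_confidence=0.9,
                       antecedent_prevalence=0.4)
    support_b, confidence_b, _ = expected_rule_metrics(
        both, GeneratorConfig(n_undergraduate=250, n_graduate=250, planted=(both,))
    )
    assert support == pytest.approx(0.5 * support_b)
    assert confidence == pytest.approx(confidence_b)
    assert lift > 1.0


def test_null_lift_fraction_shrinks_with_n():
    """With no planted rules and uniform marginals, the fraction of mined
    item pairs passing lift > 1.2 shrinks as the cohort grows (chance lift
    concentrates at 1)."""
    from surveyarm import generate_rules, mine_frequent
    from surveyarm.rule_engine import MinerConfig

    uniform = {
        d.domain_code: tuple([1 / d.scale_points] * d.scale_points)
        for d in DEFAULT_SUBSCALES
    }
    fractions = []
    for n in (500, 5000, 50000):
        cfg = GeneratorConfig(
            n_undergraduate=n // 2, n_graduate=n - n // 2,
            marginals=uniform, seed=20220219,
        )
        db = encode_cohort(generate_cohort(cfg))
        pairs = [f for f in mine_frequent(db, 0.01, max_len=2) if len(f.items) == 2]
        rules = generate_rules(
            [f for f in mine_frequent(db, 0.01, max_len=2)],
            db, MinerConfig(0.01, 0.0, 1.2, "any"),
        )
        fractions.append(len(rules) / (2 * len(pairs)))
    assert fractions[0] >= fractions[1] >= fractions[2]
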