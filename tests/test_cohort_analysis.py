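"""Per-cohort mining, rule decoding, and cohort comparison."""

import pytest

from surveyarm import (
    AssociationRule,
    GeneratorConfig,
    MinerConfig,
    PlantedRule,
    build_report,
    compare_cohorts,
    decode_rule,
    decode_token,
    encode_cohort,
    full_vocabulary,
    generate_cohort,
    mine_by_cohort,
    planted_rule_itemsets,
)
from surveyarm.basket_encoder import TransactionDB
from surveyarm.cohort_analysis import BOTH, strip_tags
from surveyarm.survey_model import ValidationError

CFG = MinerConfig(0.15, 0.6, 1.1)


def _db(n_ug=400, n_grad=400, planted=(), seed=3):
    gen = GeneratorConfig(
        n_undergraduate=n_ug, n_graduate=n_grad, planted=planted, seed=seed
    )
    return encode_cohort(generate_cohort(gen))


def test_graduate_only_pattern_assigned_to_graduates():
    rule = PlantedRule(
        antecedent=(("W2", 1),), consequent=("C1", 5),
        target_confidence=0.95, antecedent_prevalence=0.6, scope="graduate",
    )
    db = _db(planted=(rule,))
    by_cohort = mine_by_cohort(db, CFG)
    ante, cons = planted_rule_itemsets(rule)
    grad_keys = {(r.antecedent, r.consequent) for r in by_cohort["graduate"]}
    ug_keys = {(r.antecedent, r.consequent) for r in by_cohort["undergraduate"]}
    assert (ante, cons) in grad_keys
    stripped_ug = {strip_tags(r) for r in by_cohort["undergraduate"]}
    assert (ante - {"20"}, cons) not in stripped_ug or not ug_keys


def test_single_cohort_db_leaves_other_empty():
    db = _db(n_ug=0, n_grad=300)
    by_cohort = mine_by_cohort(db, MinerConfig(0.2, 0.5, 1.05))
    assert by_cohort["undergraduate"] == []


def test_cohort_independent_pattern_reported_under_both():
    rule = PlantedRule(
        antecedent=(("W3", 1),), consequent=("C4", 5),
        target_confidence=0.95, antecedent_prevalence=0.7, scope="both",
    )
    db = _db(planted=(rule,), n_ug=600, n_grad=600)
    by_cohort = mine_by_cohort(db, MinerConfig(0.3, 0.7, 1.2))
    ante, cons = planted_rule_itemsets(rule)
    both_keys = {(r.antecedent, r.consequent) for r in by_cohort[BOTH]}
    assert (ante, cons) in both_keys


def test_untagged_db_errors():
    db = TransactionDB.from_itemsets([{"C1-3", "W1-2"}])
    with pytest.raises(ValidationError, match="tag"):
        mine_by_cohort(db, CFG)


def test_stratified_mode_mines_without_tags():
    rule = PlantedRule(
        antecedent=(("W2", 1),), consequent=("C1", 5),
        target_confidence=0.95, antecedent_prevalence=0.6, scope="graduate",
    )
    db = _db(planted=(rule,))
    by_cohort = mine_by_cohort(db, MinerConfig(0.3, 0.6, 1.1), mode="stratified")
    keys = {(r.antecedent, r.consequent) for r in by_cohort["graduate"]}
    assert (frozenset({"W2-1"}), frozenset({"C1-5"})) in keys
    for rules in by_cohort.values():
        for r in rules:
            assert "10" not in r.antecedent | r.consequent
            assert "20" not in r.antecedent | r.consequent


def test_partition_no_rule_lost_or_double_assigned():
    rule = PlantedRule(
        antecedent=(("W3", 1),), consequent=("C4", 5),
        target_confidence=0.9, antecedent_prevalence=0.5,
    )
    db = _db(planted=(rule,))
    cfg = MinerConfig(0.15, 0.5, 1.05)
    by_cohort = mine_by_cohort(db, cfg)
    from surveyarm import generate_rules, mine_frequent

    all_rules = generate_rules(mine_frequent(db, cfg.minsup), db, cfg)
    assigned = sum(len(v) for v in by_cohort.values())
    assert assigned == len(all_rules)
    ids = [(r.antecedent, r.consequent) for v in by_cohort.values() for r in v]
    assert len(ids) == len(set(ids))


def test_assignment_invariant_to_tag_relabeling():
    rule = PlantedRule(
        antecedent=(("W2", 1),), consequent=("C1", 5),
        target_confidence=0.9, antecedent_prevalence=0.6, scope="graduate",
    )
    gen = GeneratorConfig(n_undergraduate=300, n_graduate=300, planted=(rule,), seed=9)
    vectors = generate_cohort(gen)
    alt_tags = {"undergraduate": "U", "graduate": "G"}
    default_db = encode_cohort(vectors)
    alt_db = encode_cohort(vectors, tags=alt_tags)
    a = mine_by_cohort(default_db, CFG)
    b = mine_by_cohort(alt_db, CFG, tags=alt_tags)
    for cohort in ("undergraduate", "graduate", BOTH):
        sa = {strip_tags(r) for r in a[cohort]}
        sb = {strip_tags(r, alt_tags) for r in b[cohort]}
        assert sa == sb


@pytest.mark.parametrize(
    "token,text",
    [
        ("C1-3", "Neutral, Emotionality"),
        ("C4-5", "Strongly Agree, Discriminatory Adjustment"),
        ("W3-1", "Never used, Positive Reappraisal"),
        ("W1-2", "Somewhat used, Escape Avoidance"),
        ("20", "Graduate student"),
        ("10", "Undergraduate student"),
    ],
)
def test_decode_token(token, text):
    assert decode_token(token) == text


def test_decode_rule_text():
    rule = AssociationRule(
        frozenset({"W3-1"}), frozenset({"C4-5"}), 0.25, 0.8, 1.5
    )
    assert decode_rule(rule) == (
        "Never used, Positive Reappraisal => Strongly Agree, Discriminatory Adjustment"
    )


def test_decode_token_bijective_over_vocabulary():
    texts = {decode_token(t) for t in full_vocabulary()}
    assert len(texts) == 44


def test_decode_unknown_token_errors():
    with pytest.raises(ValidationError):
        decode_token("C9-1")


def _report(cohort, rules):
    return build_report(cohort, rules, CFG)


def _mk_rule(a, c):
    return AssociationRule(frozenset(a), frozenset(c), 0.3, 0.8, 1.4)


def test_compare_identical_reports_all_shared():
    rules = [_mk_rule({"W3-1", "10"}, {"C4-5"})]
    cmp = compare_cohorts(_report("undergraduate", rules), _report("graduate", rules))
    assert cmp["n_shared"] == 1
    assert cmp["n_unique"] == {"undergraduate": 0, "graduate": 0}


def test_compare_disjoint_reports_nothing_shared():
    a = [_mk_rule({"W3-1"}, {"C4-5"})]
    b = [_mk_rule({"C1-5"}, {"W1-3"})]
    cmp = compare_cohorts(_report("undergraduate", a), _report("graduate", b))
    assert cmp["n_shared"] == 0
    assert cmp["n_unique"] == {"undergraduate": 1, "graduate": 1}


def test_compare_shared_after_tag_stripping():
    # same rule, but each cohort's copy carries its own tag
    a = [_mk_rule({"W3-1", "10"}, {"C4-5"}), _mk_rule({"C1-5", "10"}, {"W1-3"})]
    b = [_mk_rule({"W3-1", "20"}, {"C4-5"})]
    cmp = compare_cohorts(_report("undergraduate", a), _report("graduate", b))
    assert cmp["n_shared"] == 1
    assert cmp["n_unique"]["undergraduate"] == 1


def test_compare_threshold_mismatch_errors():
    a = build_report("undergraduate", [], MinerConfig(0.2, 0.7, 1.2))
    b = build_report("graduate", [], MinerConfig(0.2, 0.6, 1.3))
    with pytest.raises(ValidationError, match="threshold"):
        compare_cohorts(a, b)


def test_report_decoded_round_trip():
    rules = [_mk_rule({"W3-1", "10"}, {"C4-5"})]
    report = _report("undergraduate", rules)
    assert report.n_rules == 1
    assert report.decoded == [
        "Never used, Positive Reappraisal => Strongly Agree, Discriminatory Adjustment"
    ]
    assert report.stripped == [(("W3-1",), ("C4-5",))]
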