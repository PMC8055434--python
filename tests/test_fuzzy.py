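"""Trapezoid membership, the TSK engine, the rule DSL, and the
engine-vs-oracle equivalence."""

import importlib.resources

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_weighted_average, random_rulebase
from fuzzybci.engine import NoRuleFiredError, classify, firing_strength, infer_score
from fuzzybci.membership import TrapezoidMF, membership
from fuzzybci.rules import (
    Constant,
    FuzzyRule,
    Label,
    RuleBase,
    RuleParseError,
    VoteVector,
    parse_rule,
    parse_rule_file,
    rulebase_from_json,
    rulebase_to_json,
    serialize_rule,
)


class TestMembership:
    @pytest.mark.parametrize(
        "mf,x,mu",
        [
            ((0, 2, 4, 6), 3, 1.0),
            ((0, 2, 4, 6), 1, 0.5),
            ((0, 2, 4, 6), 0, 0.0),   # support-open at a < b
            ((0, 2, 4, 6), 2, 1.0),   # core-closed at b
            ((0, 2, 4, 4), 4, 1.0),   # vertical right leg, closed core side
            ((0, 2, 4, 4), 4.001, 0.0),
            ((2, 2, 4, 6), 2, 1.0),   # vertical left leg
            ((2, 2, 4, 6), 1.999, 0.0),
        ],
    )
    def test_breakpoint_conventions(self, mf, x, mu):
        assert membership(TrapezoidMF(*mf), x) == mu

    @given(x=st.floats(-10, 10))
    @settings(max_examples=100, derandomize=True)
    def test_range(self, x):
        assert 0.0 <= membership(TrapezoidMF(-1, 0, 1, 3), x) <= 1.0

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            TrapezoidMF(1, 0, 2, 3)


class TestFiringStrength:
    def test_tnorms(self, label_rulebase):
        var = label_rulebase.variables["O2_A_ERS2_250"]
        rule_min = FuzzyRule(
            antecedents=[("O2_A_ERS2_250", "ref"), ("O2_A_ERS2_250", "low")], tnorm="min",
            consequent=Label(1),
        )
        rule_prod = FuzzyRule(
            antecedents=rule_min.antecedents, tnorm="product", consequent=Label(1)
        )
        # at x=1.1 the ref and low legs give memberships 0.5 and 0.5
        inputs = {"O2_A_ERS2_250": 1.1}
        vt = {"O2_A_ERS2_250": var}
        assert firing_strength(rule_min, inputs, vt) == pytest.approx(0.5)
        assert firing_strength(rule_prod, inputs, vt) == pytest.approx(0.25)

    def test_empty_antecedents_fire_fully(self, label_rulebase):
        rule = FuzzyRule(antecedents=[], consequent=Label(1))
        assert firing_strength(rule, {}, label_rulebase.variables) == 1.0

    def test_missing_input_named(self, label_rulebase):
        with pytest.raises(KeyError, match="O2_A_ERS2_250"):
            firing_strength(label_rulebase.rules[0], {}, label_rulebase.variables)


class TestInferScore:
    def _rb(self, outputs, sets_var):
        rules = [
            FuzzyRule(antecedents=[("O2_A_ERS2_250", s)], consequent=Constant(y))
            for s, y in outputs
        ]
        return RuleBase(rules=rules, variables=sets_var)

    def test_weighted_average_hand_value(self, label_rulebase):
        # strengths (0.3, 0.7) with outputs (1, 0) -> 0.3
        variables = label_rulebase.variables
        mf = variables["O2_A_ERS2_250"].sets
        # choose x where ref leg gives 0.3: ref=(-1.2,-1,1,1.2) right leg at x=1.14
        x = 1.2 - 0.3 * 0.2
        assert membership(mf["ref"], x) == pytest.approx(0.3)
        assert membership(mf["low"], x) == pytest.approx(0.7)
        rb = RuleBase(
            rules=[
                FuzzyRule(antecedents=[("O2_A_ERS2_250", "ref")], consequent=Constant(1.0)),
                FuzzyRule(antecedents=[("O2_A_ERS2_250", "low")], consequent=Constant(0.0)),
            ],
            variables=variables,
        )
        res = infer_score(rb, {"O2_A_ERS2_250": x})
        assert res.output == pytest.approx(0.3)
        # homogeneity: scaling all strengths (same memberships) cannot change y;
        # verified by duplicating the rule list five times
        rb5 = RuleBase(rules=rb.rules * 5, variables=variables)
        assert infer_score(rb5, {"O2_A_ERS2_250": x}).output == pytest.approx(0.3)

    def test_single_rule_returns_its_output(self, label_rulebase):
        rb = RuleBase(
            rules=[FuzzyRule(antecedents=[("O2_A_ERS2_250", "ref")], consequent=Constant(4.2))],
            variables=label_rulebase.variables,
        )
        assert infer_score(rb, {"O2_A_ERS2_250": 0.0}).output == pytest.approx(4.2)

    def test_no_rule_fired_is_an_error(self, label_rulebase):
        rb = RuleBase(
            rules=[FuzzyRule(antecedents=[("O2_A_ERS2_250", "high")], consequent=Constant(1.0))],
            variables=label_rulebase.variables,
        )
        with pytest.raises(NoRuleFiredError):
            infer_score(rb, {"O2_A_ERS2_250": 0.0})

    def test_duplicating_rule_list_leaves_score_unchanged(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            rb, plain, _, inputs = random_rulebase(rng)
            try:
                y1 = infer_score(rb, inputs).output
            except NoRuleFiredError:
                continue
            rb2 = RuleBase(rules=rb.rules + rb.rules, variables=rb.variables)
            assert infer_score(rb2, inputs).output == pytest.approx(y1, abs=1e-12)


class TestOracleEquivalence:
    def test_engine_matches_direct_formula_evaluation(self):
        """Engine output equals direct weighted-average evaluation on 1000
        random small rule bases (max |delta| < 1e-12)."""
        rng = np.random.default_rng(42)
        worst = 0.0
        n_fired = 0
        for _ in range(1000):
            rb, plain, sets_flat, inputs = random_rulebase(rng)
            expected = oracle_weighted_average(plain, sets_flat, inputs)
            if expected is None:
                with pytest.raises(NoRuleFiredError):
                    infer_score(rb, inputs)
                continue
            n_fired += 1
            got = infer_score(rb, inputs).output
            worst = max(worst, abs(got - expected))
        assert n_fired > 500
        assert worst < 1e-12


class TestClassify:
    def test_label_totals(self, label_rulebase):
        res = classify(label_rulebase, {"O2_A_ERS2_250": 0.0})
        assert res.label == 1 and res.fired and not res.tie
        assert res.supports[1] == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_class(self, label_rulebase):
        rb = RuleBase(
            rules=[
                FuzzyRule(antecedents=[], consequent=Label(2)),
                FuzzyRule(antecedents=[], consequent=Label(1)),
            ],
            variables=label_rulebase.variables,
        )
        res = classify(rb, {})
        assert res.label == 1 and res.tie

    def test_vote_vector_supports(self, label_rulebase):
        rb = RuleBase(
            rules=[
                FuzzyRule(antecedents=[], consequent=VoteVector(((1, 1.0), (2, 0.0)))),
                FuzzyRule(antecedents=[], consequent=VoteVector(((1, 0.0), (2, 1.0)))),
            ],
            variables=label_rulebase.variables,
        )
        res = classify(rb, {}, mode="weighted_vote")
        assert res.supports[1] == pytest.approx(0.5)
        assert res.supports[2] == pytest.approx(0.5)
        assert res.tie and res.label == 1

    def test_no_decision_is_not_a_label(self, label_rulebase):
        rb = RuleBase(
            rules=[FuzzyRule(antecedents=[("O2_A_ERS2_250", "high")], consequent=Label(2))],
            variables=label_rulebase.variables,
        )
        res = classify(rb, {"O2_A_ERS2_250": 0.0})
        assert not res.fired and res.label is None

    def test_rule_order_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            rb, _, _, inputs = random_rulebase(rng)
            rules = [
                FuzzyRule(antecedents=r.antecedents, consequent=Label(i % 3 + 1), tnorm=r.tnorm)
                for i, r in enumerate(rb.rules)
            ]
            fwd = classify(RuleBase(rules=rules, variables=rb.variables), inputs)
            rev = classify(RuleBase(rules=rules[::-1], variables=rb.variables), inputs)
            if fwd.fired and not fwd.tie:
                assert fwd.label == rev.label


class TestRuleDSL:
    def test_two_antecedent_temporoparietal_rule(self):
        rule = parse_rule("IF P8_T_ERS2_300 is high AND T8_G_ERS2_250 is high THEN label 1")
        assert rule.antecedents == [("P8_T_ERS2_300", "high"), ("T8_G_ERS2_250", "high")]
        assert rule.consequent == Label(1)

    def test_single_antecedent_rule(self):
        rule = parse_rule("IF T7_A_ERS2_300 is high THEN label 1")
        assert len(rule.antecedents) == 1

    def test_typographic_normalization(self):
        rule = parse_rule('IF P8_T_ERS"300 is high THEN label 1')
        assert rule.antecedents[0][0] == "P8_T_ERS2_300"

    @pytest.mark.parametrize(
        "text,match",
        [
            ("IF X is wobbly THEN label 1", "variable id"),
            ("IF P8_T_ERS2_300 is wobbly THEN label 1", "unknown set"),
            ("P8_T_ERS2_300 is high label 1", "THEN"),
            ("IF P8_T_ERS2_300 is high THEN wave 1", "consequent"),
        ],
    )
    def test_parse_errors(self, text, match):
        with pytest.raises(RuleParseError, match=match):
            parse_rule(text)

    def test_serialize_parse_identity_on_shipped_rulebase(self):
        path = importlib.resources.files("fuzzybci") / "data" / "example_rules.txt"
        rules = parse_rule_file(str(path))
        assert len(rules) >= 10
        for rule in rules:
            again = parse_rule(serialize_rule(rule))
            assert again.antecedents == rule.antecedents
            assert again.consequent == rule.consequent

    def test_json_roundtrip_bit_exact(self, label_rulebase):
        doc = rulebase_to_json(label_rulebase)
        back = rulebase_from_json(doc)
        assert rulebase_to_json(back) == doc
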