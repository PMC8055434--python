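"""Shared fixtures: canonical membership sets, random rule bases, and an
independent brute-force TSK oracle."""

from __future__ import annotations

import numpy as np
import pytest

from fuzzybci.membership import LinguisticVariable, TrapezoidMF
from fuzzybci.rules import Constant, FuzzyRule, Label, RuleBase
from fuzzybci.spectral import VariableId


# --- independent oracle ----------------------------------------------------
# Direct evaluation of the weighted-average TSK model from the rule list,
# written from the defining formulas and kept separate from the engine.

def oracle_trapezoid(abcd, x):
    a, b, c, d = abcd
    if b <= x <= c:
        return 1.0
    if a < x < b:
        return (x - a) / (b - a)
    if c < x < d:
        return (d - x) / (d - c)
    return 0.0


def oracle_strength(antecedents, tnorm, sets, inputs):
    mus = [oracle_trapezoid(sets[(var, name)], inputs[var]) for var, name in antecedents]
    if not mus:
        return 1.0
    if tnorm == "min":
        return min(mus)
    out = 1.0
    for m in mus:
        out *= m
    return out


def oracle_weighted_average(rules, sets, inputs):
    """rules: list of (antecedents, tnorm, y_constant). Returns None if no rule fires."""
    num = den = 0.0
    for antecedents, tnorm, y in rules:
        mu = oracle_strength(antecedents, tnorm, sets, inputs)
        num += mu * y
        den += mu
    return None if den == 0.0 else num / den


# --- random rule-base generator -------------------------------------------

VAR_NAMES = ["P8_T_ERS2_300", "T8_G_ERS2_250", "O2_A_ERS2_250"]
SET_NAMES = ["ref", "low", "high"]


def random_rulebase(rng: np.random.Generator):
    """A small random rule base plus the plain-data mirror for the oracle."""
    variables = {}
    sets_flat = {}
    for name in VAR_NAMES:
        sets = {}
        for sname in SET_NAMES:
            pts = np.sort(rng.uniform(-3, 3, size=4))
            sets[sname] = TrapezoidMF(*pts)
            sets_flat[(name, sname)] = tuple(pts)
        variables[name] = LinguisticVariable(id=VariableId.parse(name), sets=sets)
    rules = []
    plain = []
    for _ in range(rng.integers(1, 6)):
        n_ant = int(rng.integers(0, 4))
        antecedents = [
            (VAR_NAMES[rng.integers(len(VAR_NAMES))], SET_NAMES[rng.integers(len(SET_NAMES))])
            for _ in range(n_ant)
        ]
        tnorm = "min" if rng.random() < 0.5 else "product"
        y = float(rng.uniform(-5, 5))
        rules.append(FuzzyRule(antecedents=antecedents, consequent=Constant(y), tnorm=tnorm))
        plain.append((antecedents, tnorm, y))
    rb = RuleBase(rules=rules, variables=variables)
    inputs = {name: float(rng.uniform(-4, 4)) for name in VAR_NAMES}
    return rb, plain, sets_flat, inputs


@pytest.fixture
def unit_sets():
    """Hand-substituted trapezoids for m=0, s=1, c=(1.2, 1.4, 2)."""
    return {
        "ref": TrapezoidMF(-1.2, -1.0, 1.0, 1.2),
        "low": TrapezoidMF(1.0, 1.2, 1.4, 2.0),
        "high": TrapezoidMF(1.4, 2.0, 6.0, 6.0),
        "desync": TrapezoidMF(-6.0, -6.0, -2.0, -1.0),
        "artifact": TrapezoidMF(6.0, 6.0, float("inf"), float("inf")),
    }


@pytest.fixture
def label_rulebase():
    """Two single-antecedent label rules over one calibrated variable."""
    from fuzzybci.calibration import BaselineStats, CoefficientSet, build_variable

    var = build_variable(
        "O2_A_ERS2_250", BaselineStats(0.0, 1.0, 100), CoefficientSet(1.2, 1.4, 2.0)
    )
    rules = [
        FuzzyRule(antecedents=[("O2_A_ERS2_250", "ref")], consequent=Label(1), id="ref"),
        FuzzyRule(antecedents=[("O2_A_ERS2_250", "high")], consequent=Label(2), id="high"),
    ]
    return RuleBase(rules=rules, variables={var.name: var})
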