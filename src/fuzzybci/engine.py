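"""Zero-order TSK inference: firing strengths, weighted-average
defuzzification, and single-winner / weighted-vote classification.

For a rule base with strengths ``mu_i`` and crisp outputs ``y_i`` the
score output is the strength-weighted average

    y = sum_i mu_i * y_i / sum_i mu_i,

undefined when no rule fires (``sum mu_i == 0``); that case is a
first-class outcome here, never silently mapped to 0.  Rule strength is
the t-norm (product by default, minimum optionally) over the antecedent
memberships; a rule with no antecedents fires with strength 1 (t-norm
identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .membership import LinguisticVariable
from .rules import Constant, FuzzyRule, Label, LinearForm, RuleBase, VoteVector

__all__ = [
    "NoRuleFiredError",
    "InferenceResult",
    "firing_strength",
    "infer_score",
    "classify",
]


class NoRuleFiredError(RuntimeError):
    """The weighted average is undefined: every rule had zero strength."""


@dataclass
class InferenceResult:
    """Outcome of one inference step.

    ``fired`` is False when no rule had positive strength, in which case
    ``label``/``output`` are None ("no decision", distinct from any label).
    ``tie`` marks an exact tie in class supports (broken to the lowest
    class index).
    """

    strengths: list[float]
    fired: bool
    output: float | None = None
    label: int | None = None
    supports: dict[int, float] = field(default_factory=dict)
    tie: bool = False


def firing_strength(
    rule: FuzzyRule,
    inputs: dict[str, float],
    variables: dict[str, LinguisticVariable],
) -> float:
    """T-norm over antecedent memberships; empty antecedent list -> 1."""
    strength = 1.0
    for var, set_name in rule.antecedents:
        if var not in inputs:
            raise KeyError(f"input value for variable {var!r} is missing")
        if var not in variables:
            raise KeyError(f"variable {var!r} is not in the variable table")
        mu = variables[var].membership(set_name, inputs[var])
        if rule.tnorm == "min":
            strength = min(strength, mu)
        else:
            strength *= mu
    return strength


def _strengths(rb: RuleBase, inputs: dict[str, float]) -> list[float]:
    return [firing_strength(r, inputs, rb.variables) for r in rb.rules]


def infer_score(rb: RuleBase, inputs: dict[str, float]) -> InferenceResult:
    """Crisp score by weighted-average defuzzification.

    Uses every rule with a Constant or LinearForm consequent; raises
    :class:`NoRuleFiredError` when the total strength is zero (callers
    that want a default must map it explicitly).
    """
    strengths = _strengths(rb, inputs)
    num = 0.0
    den = 0.0
    any_score_rule = False
    for rule, mu in zip(rb.rules, strengths):
        c = rule.consequent
        if isinstance(c, Constant):
            y = c.value
        elif isinstance(c, LinearForm):
            y = c.evaluate(inputs)
        else:
            continue
        any_score_rule = True
        num += mu * y
        den += mu
    if not any_score_rule:
        raise ValueError("rule base has no Constant/LinearForm consequent")
    if den == 0.0:
        raise NoRuleFiredError("no rule fired: weighted average undefined")
    return InferenceResult(strengths=strengths, fired=True, output=num / den)


def classify(
    rb: RuleBase,
    inputs: dict[str, float],
    mode: str = "single_winner",
) -> InferenceResult:
    """Classify by Label/VoteVector rules.

    ``single_winner``: the class with maximum total strength of the vote
    (Label rules contribute their full strength to their class, vote
    rules contribute ``mu * vote``).  ``weighted_vote``: per-class
    weighted-average aggregation, then argmax; the argmax coincides with
    single-winner totals but the reported supports are normalized by the
    total fired strength.  Exact ties break to the lowest class index
    with ``tie=True``.  When no rule fires the result has ``fired=False``
    and no label — an explicit "no decision".
    """
    if mode not in ("single_winner", "weighted_vote"):
        raise ValueError(f"unknown mode {mode!r}")
    strengths = _strengths(rb, inputs)
    supports: dict[int, float] = {}
    total = 0.0
    any_class_rule = False
    for rule, mu in zip(rb.rules, strengths):
        c = rule.consequent
        if isinstance(c, Label):
            any_class_rule = True
            supports[c.value] = supports.get(c.value, 0.0) + mu
            total += mu
        elif isinstance(c, VoteVector):
            any_class_rule = True
            for cls, vote in c.votes:
                supports[cls] = supports.get(cls, 0.0) + mu * vote
            total += mu
    if not any_class_rule:
        raise ValueError("rule base has no Label/VoteVector consequent")
    if total == 0.0:
        return InferenceResult(strengths=strengths, fired=False)
    if mode == "weighted_vote":
        supports = {cls: s / total for cls, s in supports.items()}
    best = max(supports.values())
    winners = sorted(cls for cls, s in supports.items() if s == best)
    return InferenceResult(
        strengths=strengths,
        fired=True,
        label=winners[0],
        supports=supports,
        tie=len(winners) > 1,
    )
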