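"""Fuzzy IF-THEN rules, the rule DSL, and rule-base serialization.

Rules follow the Takagi-Sugeno(-Kang) structure: the IF part conjoins
linguistic-variable conditions (``P8_T_ERS2_300 is high``), the THEN part
carries a crisp consequent.  Four consequent kinds are supported:

``Label``
    a nominal class label — the plain classification rule;
``VoteVector``
    per-class support constants in [0, 1] — every rule votes for all
    classes;
``Constant``
    a single crisp output (zero-order TSK), e.g. a valence score;
``LinearForm``
    ``a0 + sum(a_k * x_k)`` over the input variables (first-order TSK).

The text DSL mirrors how such rules are written by practitioners::

    IF P8_T_ERS2_300 is high AND T8_G_ERS2_250 is high THEN label 1
    IF F4_T_ERS2_300 is high THEN value 0.1
    IF T7_A_ERS2_300 is high THEN votes 1:0.8, 2:0.2

Typographic variants of variable names (primes/quotes, e.g. P8_T_ERS"300)
are normalized to ``P8_T_ERS2_300`` before parsing.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .membership import SET_VOCABULARY, LinguisticVariable, TrapezoidMF
from .spectral import VariableId

__all__ = [
    "Label",
    "Constant",
    "VoteVector",
    "LinearForm",
    "FuzzyRule",
    "RuleBase",
    "RuleParseError",
    "parse_rule",
    "serialize_rule",
    "parse_rule_file",
]


class RuleParseError(ValueError):
    """Raised with a character position when rule text cannot be parsed."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class Label:
    value: int


@dataclass(frozen=True)
class Constant:
    value: float


@dataclass(frozen=True)
class VoteVector:
    """Per-class votes in [0, 1]; classes absent from the map count as 0."""

    votes: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        for cls, v in self.votes:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"vote for class {cls} must be in [0, 1], got {v}")

    def as_dict(self) -> dict[int, float]:
        return dict(self.votes)


@dataclass(frozen=True)
class LinearForm:
    """First-order TSK consequent ``a0 + sum(coeffs[var] * x[var])``."""

    a0: float
    coeffs: tuple[tuple[str, float], ...] = ()

    def evaluate(self, inputs: dict[str, float]) -> float:
        y = self.a0
        for var, a in self.coeffs:
            if var not in inputs:
                raise KeyError(f"linear consequent needs input variable {var!r}")
            y += a * inputs[var]
        return y


Consequent = Label | Constant | VoteVector | LinearForm


@dataclass
class FuzzyRule:
    """One IF-THEN rule: antecedents, t-norm, and a crisp consequent."""

    antecedents: list[tuple[str, str]]
    consequent: Consequent
    tnorm: str = "product"
    id: str | None = None

    def __post_init__(self) -> None:
        if self.tnorm not in ("product", "min"):
            raise ValueError(f"tnorm must be 'product' or 'min', got {self.tnorm!r}")
        for var, set_name in self.antecedents:
            VariableId.parse(var)  # validates the id shape
            if set_name not in SET_VOCABULARY:
                raise ValueError(
                    f"unknown fuzzy-set name {set_name!r} in antecedent "
                    f"({var}); allowed: {sorted(SET_VOCABULARY)}"
                )


@dataclass
class RuleBase:
    """An ordered rule list plus the linguistic-variable table it refers to."""

    rules: list[FuzzyRule] = field(default_factory=list)
    variables: dict[str, LinguisticVariable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rule in self.rules:
            for var, set_name in rule.antecedents:
                if var not in self.variables:
                    raise ValueError(
                        f"rule {rule.id or '?'} references unknown variable {var!r}"
                    )
                if set_name not in self.variables[var].sets:
                    raise ValueError(
                        f"rule {rule.id or '?'}: variable {var} has no set {set_name!r}"
                    )


# --- DSL -------------------------------------------------------------------

#: Normalization of typographic variable spellings: ERS"300 / ERS”300 ->
#: ERS2_300 (the double prime marks the second difference).
_TYPO_RE = re.compile(r'ERS[”"″′″]+\s*_?(\d+)')


def normalize_variable_text(text: str) -> str:
    return _TYPO_RE.sub(r"ERS2_\1", text)


_RULE_RE = re.compile(
    r"^\s*IF\s+(?P<body>.+?)\s+THEN\s+(?P<cons>.+?)\s*$", re.IGNORECASE
)
_COND_RE = re.compile(
    r"^\s*(?P<var>\S+)\s+is\s+(?P<set>\S+)\s*$", re.IGNORECASE
)


def _parse_consequent(text: str, offset: int) -> Consequent:
    tokens = text.strip().split(None, 1)
    if not tokens:
        raise RuleParseError("empty consequent after THEN", offset)
    kind = tokens[0].lower()
    rest = tokens[1] if len(tokens) > 1 else ""
    try:
        if kind == "label":
            return Label(int(rest))
        if kind == "value":
            return Constant(float(rest))
        if kind == "votes":
            votes = []
            for part in rest.split(","):
                cls, _, v = part.partition(":")
                votes.append((int(cls.strip()), float(v.strip())))
            return VoteVector(tuple(votes))
        if kind == "linear":
            terms = [t.strip() for t in rest.split("+")]
            a0 = float(terms[0])
            coeffs = []
            for term in terms[1:]:
                coef, _, var = term.partition("*")
                VariableId.parse(var.strip())
                coeffs.append((var.strip(), float(coef.strip())))
            return LinearForm(a0, tuple(coeffs))
    except RuleParseError:
        raise
    except (ValueError, KeyError) as exc:
        raise RuleParseError(f"malformed {kind!r} consequent {rest!r}: {exc}", offset)
    raise RuleParseError(
        f"unknown consequent kind {tokens[0]!r}; expected label/value/votes/linear", offset
    )


def parse_rule(text: str, tnorm: str = "product", rule_id: str | None = None) -> FuzzyRule:
    """Parse ``IF <var> is <set> [AND <var> is <set>]* THEN <consequent>``.

    Raises :class:`RuleParseError` with the character position of the
    offending token for unknown sets, malformed variable ids, or a
    missing THEN.
    """
    text = normalize_variable_text(text)
    m = _RULE_RE.match(text)
    if m is None:
        pos = text.upper().find("THEN")
        if pos < 0:
            raise RuleParseError(f"missing THEN in rule {text.strip()!r}", None)
        raise RuleParseError(f"rule does not match IF ... THEN ...: {text.strip()!r}", 0)
    antecedents: list[tuple[str, str]] = []
    body = m["body"]
    offset = m.start("body")
    for chunk in re.split(r"\s+AND\s+", body, flags=re.IGNORECASE):
        cm = _COND_RE.match(chunk)
        pos = offset + body.find(chunk)
        if cm is None:
            raise RuleParseError(f"malformed condition {chunk.strip()!r}", pos)
        var, set_name = cm["var"].strip('"“”'), cm["set"].strip('"“”').lower()
        try:
            VariableId.parse(var)
        except Exception as exc:
            raise RuleParseError(f"malformed variable id {var!r}: {exc}", pos)
        if set_name not in SET_VOCABULARY:
            raise RuleParseError(
                f"unknown set name {set_name!r}; allowed: {sorted(SET_VOCABULARY)}", pos
            )
        antecedents.append((var, set_name))
    consequent = _parse_consequent(m["cons"], m.start("cons"))
    return FuzzyRule(antecedents=antecedents, consequent=consequent, tnorm=tnorm, id=rule_id)


def serialize_rule(rule: FuzzyRule) -> str:
    """Render a rule back to DSL text; inverse of :func:`parse_rule`."""
    conds = " AND ".join(f"{var} is {s}" for var, s in rule.antecedents)
    c = rule.consequent
    if isinstance(c, Label):
        cons = f"label {c.value}"
    elif isinstance(c, Constant):
        cons = f"value {c.value:g}"
    elif isinstance(c, VoteVector):
        cons = "votes " + ", ".join(f"{cls}:{v:g}" for cls, v in c.votes)
    else:
        terms = [f"{c.a0:g}"] + [f"{a:g}*{var}" for var, a in c.coeffs]
        cons = "linear " + " + ".join(terms)
    return f"IF {conds} THEN {cons}"


def parse_rule_file(path: str | Path, tnorm: str = "product") -> list[FuzzyRule]:
    """One DSL rule per line; blank lines and ``#`` comments are skipped."""
    rules = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rules.append(parse_rule(line, tnorm=tnorm, rule_id=f"L{lineno}"))
        except RuleParseError as exc:
            raise RuleParseError(f"line {lineno}: {exc}") from exc
    return rules


# --- JSON round-trip -------------------------------------------------------

def _consequent_to_json(c: Consequent) -> dict:
    if isinstance(c, Label):
        return {"type": "label", "value": c.value}
    if isinstance(c, Constant):
        return {"type": "constant", "value": c.value}
    if isinstance(c, VoteVector):
        return {"type": "votes", "value": {str(k): v for k, v in c.votes}}
    return {"type": "linear", "a0": c.a0, "coeffs": {v: a for v, a in c.coeffs}}


def _consequent_from_json(d: dict) -> Consequent:
    t = d["type"]
    if t == "label":
        return Label(int(d["value"]))
    if t == "constant":
        return Constant(float(d["value"]))
    if t == "votes":
        return VoteVector(tuple((int(k), float(v)) for k, v in d["value"].items()))
    if t == "linear":
        return LinearForm(float(d["a0"]), tuple((v, float(a)) for v, a in d["coeffs"].items()))
    raise ValueError(f"unknown consequent type {t!r}")


def rulebase_to_json(rb: RuleBase) -> dict:
    return {
        "variables": [
            {
                "id": lv.name,
                "artifact_threshold": lv.artifact_threshold,
                "sets": {name: mf.as_list() for name, mf in lv.sets.items()},
            }
            for lv in rb.variables.values()
        ],
        "rules": [
            {
                "id": r.id,
                "if": [[var, s] for var, s in r.antecedents],
                "tnorm": r.tnorm,
                "then": _consequent_to_json(r.consequent),
            }
            for r in rb.rules
        ],
    }


def rulebase_from_json(d: dict) -> RuleBase:
    variables = {}
    for v in d["variables"]:
        lv = LinguisticVariable(
            id=VariableId.parse(v["id"]),
            sets={name: TrapezoidMF(*mf) for name, mf in v["sets"].items()},
            artifact_threshold=v.get("artifact_threshold"),
        )
        variables[lv.name] = lv
    rules = [
        FuzzyRule(
            antecedents=[(var, s) for var, s in r["if"]],
            consequent=_consequent_from_json(r["then"]),
            tnorm=r.get("tnorm", "product"),
            id=r.get("id"),
        )
        for r in d["rules"]
    ]
    return RuleBase(rules=rules, variables=variables)


def save_rulebase(rb: RuleBase, path: str | Path) -> None:
    Path(path).write_text(json.dumps(rulebase_to_json(rb), indent=1, sort_keys=True))


def load_rulebase(path: str | Path) -> RuleBase:
    return rulebase_from_json(json.loads(Path(path).read_text()))
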