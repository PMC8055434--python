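"""Trapezoidal fuzzy sets and linguistic variables.

A linguistic variable is one feature axis — an (electrode, band, feature,
window) combination such as ``P8_T_ERS2_300`` — whose values are described
by named fuzzy sets drawn from a fixed vocabulary:

``ref``
    the baseline interval (reference phase behaviour),
``low`` / ``high``
    moderate / strong positive-going bursts (ERS″),
``desync``
    negative-going bursts (ERD″),
``artifact``
    extreme values attributed to ocular/muscle/connectivity artifacts.

Membership evaluation is core-closed and support-open: μ is exactly 1 on
the closed core ``[b, c]`` and exactly 0 at and beyond the support ends
for non-degenerate legs.  A vertical leg (``a == b`` or ``c == d``) gives
a step at the breakpoint, closed on the core side — this is what lets a
perpendicular right leg cut off artifact bursts sharply ("high bursts are
not evaluated").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectral import VariableId

__all__ = ["TrapezoidMF", "LinguisticVariable", "SET_VOCABULARY", "membership"]

#: The fixed fuzzy-set vocabulary for a linguistic variable.
SET_VOCABULARY: frozenset[str] = frozenset({"ref", "low", "high", "desync", "artifact"})


@dataclass(frozen=True)
class TrapezoidMF:
    """Trapezoid breakpoints ``a <= b <= c <= d``; membership 1 on [b, c].

    The upper base [b, c] absorbs the small scattering of baseline power
    (so that noise does not register as false bursts); the legs provide
    the fuzzy transition, and a vertical leg eliminates the slope entirely.
    ``d`` (or ``a``) may be ``inf`` (``-inf``) for a one-sided set.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"breakpoints must be ordered a<=b<=c<=d, got {self}")

    def __call__(self, x: float) -> float:
        return membership(self, x)

    def as_list(self) -> list[float]:
        return [self.a, self.b, self.c, self.d]


def membership(mf: TrapezoidMF, x: float) -> float:
    """Piecewise-linear trapezoid membership of ``x`` in [0, 1].

    Core-closed: μ(b) = μ(c) = 1.  Support-open on non-degenerate legs:
    μ(a) = 0 when a < b.  Vertical legs step to 1 at the breakpoint.
    """
    a, b, c, d = mf.a, mf.b, mf.c, mf.d
    if b <= x <= c:
        return 1.0
    if x < b:
        if x <= a:  # a == b handled above (x < b implies x < a == b is false only if a < b)
            return 0.0
        return (x - a) / (b - a)
    # x > c
    if x >= d:
        return 0.0
    return (d - x) / (d - c)


@dataclass
class LinguisticVariable:
    """A named feature axis with its fuzzy sets and artifact threshold.

    ``sets`` maps names from :data:`SET_VOCABULARY` to trapezoids on the
    feature axis (raw ERS″ units, µV²/Hz).  ``artifact_threshold`` is the
    crisp |ERS″| cutoff attached at calibration time.
    """

    id: VariableId
    sets: dict[str, TrapezoidMF] = field(default_factory=dict)
    artifact_threshold: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.id, str):
            self.id = VariableId.parse(self.id)
        unknown = set(self.sets) - SET_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown fuzzy-set names {sorted(unknown)}; allowed: {sorted(SET_VOCABULARY)}"
            )

    @property
    def name(self) -> str:
        return str(self.id)

    def membership(self, set_name: str, x: float) -> float:
        if set_name not in self.sets:
            raise KeyError(f"variable {self.name} has no set {set_name!r}")
        return membership(self.sets[set_name], x)
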