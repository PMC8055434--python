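"""Baseline-phase calibration and digital-twin tuning of the fuzzy sets.

During a reference (passive-view) phase, each linguistic variable's burst
feature is recorded and summarized by its mean ``m`` and sample standard
deviation ``std`` (conventionally over 100 samples).  The trapezoidal
fuzzy sets are then built around those statistics, scaled by three
dimensionless coefficients ``1 <= c1 <= c2 <= c3``::

    ref    = (m - c1*s,  m - s,     m + s,     m + c1*s)
    low    = (m + s,     m + c1*s,  m + c2*s,  m + c3*s)
    high   = (m + c2*s,  m + c3*s,  m + 3*c3*s,  m + 3*c3*s)   # vertical right leg
    desync = (m - 3*c3*s, m - 3*c3*s, m - c3*s,  m - s)        # mirror, vertical left leg

The vertical right leg of ``high`` cuts off at ``m + 3*c3*s`` so that
extreme artifact bursts get zero membership and are not evaluated; an
optional one-sided ``artifact`` set covers the region beyond the cutoff.

The coefficients can be fixed from experience (``c1=1.2, c2=1.4, c3=2``)
or tuned by a genetic algorithm coupled to a *digital twin*: a replay of
recorded (or synthetic) feature windows on which each candidate
coefficient set is scored.  The per-window cost is itself a two-rule
zero-order TSK system; in baseline mode the rules demand that baseline
samples belong to ``ref`` and not to ``low``::

    R1: IF x is ref THEN y1 = 1 - mu_ref(x)
    R2: IF x is low THEN y2 = mu_low(x)
    E(x) = (mu_ref*y1 + mu_low*y2) / (mu_ref + mu_low)

and in active mode (condition refinement) the mirror pair demands
membership in ``high`` and not in ``ref``.  E is defined as 1 where both
memberships vanish (outside the modelled region is maximal error).  The
GA fitness of a coefficient set is the mean of E over the replayed
windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .membership import LinguisticVariable, TrapezoidMF
from .spectral import VariableId

__all__ = [
    "BaselineStats",
    "CoefficientSet",
    "DigitalTwinTrace",
    "GAConfig",
    "baseline_stats",
    "build_membership_set",
    "build_variable",
    "dt_cost",
    "dt_fitness",
    "optimize_coeffs",
    "DEFAULT_COEFFS",
]

#: Experimentally chosen default tuning coefficients.
DEFAULT_COEFFS: tuple[float, float, float] = (1.2, 1.4, 2.0)

#: Conventional baseline length; a different n only warns.
BASELINE_N = 100


@dataclass(frozen=True)
class BaselineStats:
    """Mean / sample std / count of a variable's baseline feature values."""

    m: float
    std: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"baseline needs at least 2 samples, got {self.n}")
        if self.std < 0:
            raise ValueError("std must be nonnegative")


@dataclass(frozen=True)
class CoefficientSet:
    """Tuning parameters with the trapezoid-validity ordering 1 <= c1 <= c2 <= c3."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.c1 <= self.c2 <= self.c3):
            raise ValueError(
                f"coefficients must satisfy 1 <= c1 <= c2 <= c3, got "
                f"({self.c1}, {self.c2}, {self.c3})"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)


@dataclass
class DigitalTwinTrace:
    """Ordered feature windows replayed by the digital twin.

    ``mode`` is ``baseline`` (reference-phase replay: values should live
    in ``ref``) or ``active`` (condition replay: values should live in
    ``high``).
    """

    variable_id: str
    values: np.ndarray
    mode: str = "baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("baseline", "active"):
            raise ValueError(f"mode must be 'baseline' or 'active', got {self.mode!r}")
        if len(self.values) < 5:
            raise ValueError(
                f"digital-twin trace needs at least 5 windows, got {len(self.values)}"
            )


def baseline_stats(samples: np.ndarray) -> BaselineStats:
    """Arithmetic mean and sample (n-1) standard deviation of the baseline.

    A zero std (flat baseline) is floored at ``1e-6 * max(|m|, 1)`` so that
    degenerate synthetic baselines still yield valid trapezoids.  Warns
    (does not fail) when the sample count differs from the conventional 100.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n < 2:
        raise ValueError(f"baseline statistics need n >= 2 samples, got {n}")
    if n != BASELINE_N:
        warnings.warn(
            f"baseline has {n} samples; the conventional reference phase uses {BASELINE_N}",
            stacklevel=2,
        )
    m = float(np.mean(samples))
    std = float(np.std(samples, ddof=1))
    if std == 0.0:
        std = 1e-6 * max(abs(m), 1.0)
    return BaselineStats(m=m, std=std, n=n)


def build_membership_set(
    stats: BaselineStats,
    coeffs: CoefficientSet,
    include_artifact: bool = True,
) -> dict[str, TrapezoidMF]:
    """Trapezoidal fuzzy sets from baseline statistics and coefficients."""
    m, s = stats.m, stats.std
    c1, c2, c3 = coeffs.as_tuple()
    sets = {
        "ref": TrapezoidMF(m - c1 * s, m - s, m + s, m + c1 * s),
        "low": TrapezoidMF(m + s, m + c1 * s, m + c2 * s, m + c3 * s),
        "high": TrapezoidMF(m + c2 * s, m + c3 * s, m + 3 * c3 * s, m + 3 * c3 * s),
        "desync": TrapezoidMF(m - 3 * c3 * s, m - 3 * c3 * s, m - c3 * s, m - s),
    }
    if include_artifact:
        sets["artifact"] = TrapezoidMF(
            m + 3 * c3 * s, m + 3 * c3 * s, float("inf"), float("inf")
        )
    return sets


def build_variable(
    variable_id: str | VariableId,
    stats: BaselineStats,
    coeffs: CoefficientSet = CoefficientSet(*DEFAULT_COEFFS),
    artifact_threshold: float | None = None,
    include_artifact: bool = True,
) -> LinguisticVariable:
    """A fully calibrated linguistic variable for one feature axis."""
    vid = VariableId.parse(variable_id) if isinstance(variable_id, str) else variable_id
    return LinguisticVariable(
        id=vid,
        sets=build_membership_set(stats, coeffs, include_artifact=include_artifact),
        artifact_threshold=artifact_threshold,
    )


def _trap_mu(mf: TrapezoidMF, x: np.ndarray) -> np.ndarray:
    """Vectorized trapezoid membership (same conventions as membership())."""
    x = np.asarray(x, dtype=float)
    mu = np.zeros_like(x)
    core = (x >= mf.b) & (x <= mf.c)
    mu[core] = 1.0
    if mf.b > mf.a:
        left = (x > mf.a) & (x < mf.b)
        mu[left] = (x[left] - mf.a) / (mf.b - mf.a)
    if mf.d > mf.c:
        right = (x > mf.c) & (x < mf.d)
        mu[right] = (mf.d - x[right]) / (mf.d - mf.c)
    return mu


def dt_cost(
    x: float | np.ndarray,
    sets: dict[str, TrapezoidMF],
    mode: str = "baseline",
) -> float | np.ndarray:
    """Digital-twin per-window error in [0, 1] (vectorized over ``x``).

    Baseline mode scores deviation from reference behaviour; active mode
    scores deviation from a sustained 'high' burst.  Where both rule
    memberships are zero the error is 1.
    """
    scalar = np.isscalar(x)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mu_ref = _trap_mu(sets["ref"], x)
    if mode == "baseline":
        mu_other = _trap_mu(sets["low"], x)
        num = mu_ref * (1.0 - mu_ref) + mu_other * mu_other
    elif mode == "active":
        mu_other = _trap_mu(sets["high"], x)
        num = mu_ref * mu_ref + mu_other * (1.0 - mu_other)
    else:
        raise ValueError(f"mode must be 'baseline' or 'active', got {mode!r}")
    den = mu_ref + mu_other
    out = np.ones_like(x)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return float(out[0]) if scalar else out


def dt_fitness(
    trace: DigitalTwinTrace,
    stats: BaselineStats,
    coeffs: CoefficientSet,
) -> float:
    """Mean digital-twin cost of a coefficient set over a replayed trace."""
    if len(trace.values) == 0:
        raise ValueError("empty digital-twin trace")
    sets = build_membership_set(stats, coeffs, include_artifact=False)
    return float(np.mean(dt_cost(trace.values, sets, mode=trace.mode)))


#: Default per-gene (lower, upper) bounds.  The upper bounds are wide on
#: purpose: the cost optimum scales with the ratio of the calibration std
#: to the spread of the replayed trace, and a trace whose spread matches
#: the calibration std needs leg coefficients well above the hand-tuned
#: defaults before the mean cost can approach zero.
DEFAULT_GENE_BOUNDS: tuple[tuple[float, float], ...] = ((1.0, 12.0), (1.0, 14.0), (1.0, 16.0))


@dataclass
class GAConfig:
    """Genetic-algorithm settings for digital-twin coefficient tuning.

    Defaults follow the small-budget regime that keeps a live calibration
    short: 40 chromosomes, 20 mating parents, 3 genes (c1, c2, c3), and
    10 generations.
    """

    population: int = 40
    parents: int = 20
    generations: int = 10
    gene_bounds: tuple[tuple[float, float], ...] = DEFAULT_GENE_BOUNDS
    mutation_scale: float = 0.6
    elitism: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.parents > self.population:
            raise ValueError("parents must not exceed population")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.elitism < 1 or self.elitism > self.parents:
            raise ValueError("elitism must be in [1, parents]")
        if len(self.gene_bounds) != 3:
            raise ValueError("need bounds for the 3 genes c1, c2, c3")
        for lo, hi in self.gene_bounds:
            if not (1.0 <= lo <= hi):
                raise ValueError(f"infeasible gene bounds ({lo}, {hi}); need 1 <= lo <= hi")


def _repair(genes: np.ndarray, bounds: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Sort genes ascending (enforces c1<=c2<=c3), then clip to bounds.

    The upper bounds are non-decreasing, so clipping after sorting
    preserves the ordering.
    """
    g = np.sort(genes)
    for k, (lo, hi) in enumerate(bounds):
        g[k] = min(max(g[k], lo), hi)
    return g


def optimize_coeffs(
    trace: DigitalTwinTrace,
    stats: BaselineStats,
    cfg: GAConfig,
    init: CoefficientSet | None = None,
    genes: tuple[str, ...] = ("c1", "c2", "c3"),
) -> tuple[CoefficientSet, list[float]]:
    """Tune c1-c3 by a seeded GA against the digital twin.

    Rank (truncation) selection of ``cfg.parents``, uniform crossover,
    Gaussian mutation clipped to the gene bounds, sort-repair of the
    ordering constraint, and elitism.  ``genes`` restricts which
    coefficients move (e.g. ``("c3",)`` for active-mode refinement of an
    already calibrated variable); the others stay at ``init``.  Returns
    the best coefficient set and the per-generation best-cost history
    (non-increasing by elitism; identical across runs with equal seeds).
    """
    if len(trace.values) == 0:
        raise ValueError("empty digital-twin trace")
    unknown = set(genes) - {"c1", "c2", "c3"}
    if unknown or not genes:
        raise ValueError(f"genes must be a nonempty subset of c1/c2/c3, got {genes}")
    rng = np.random.default_rng(cfg.seed)
    bounds = cfg.gene_bounds
    base = np.array((init or CoefficientSet(*DEFAULT_COEFFS)).as_tuple())
    free = np.array([name in genes for name in ("c1", "c2", "c3")])

    def make_individual(g: np.ndarray) -> np.ndarray:
        full = base.copy()
        full[free] = g[free]
        if free.all():
            return _repair(full, bounds)
        # Restricted tuning: project free genes onto the ordering cone
        # without disturbing the fixed ones (which are ordered by init).
        for k, (lo, hi) in enumerate(bounds):
            if free[k]:
                full[k] = min(max(full[k], lo), hi)
        for k in (1, 2):
            if free[k]:
                full[k] = max(full[k], full[k - 1])
        for k in (1, 0):
            if free[k]:
                full[k] = min(full[k], full[k + 1])
        return full

    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    pop = np.array(
        [make_individual(rng.uniform(lows, highs)) for _ in range(cfg.population)]
    )
    costs = np.array([dt_fitness(trace, stats, CoefficientSet(*ind)) for ind in pop])
    order = np.argsort(costs, kind="stable")
    pop, costs = pop[order], costs[order]
    history = [float(costs[0])]

    for _ in range(cfg.generations - 1):
        parents = pop[: cfg.parents]
        children = [pop[k].copy() for k in range(cfg.elitism)]
        while len(children) < cfg.population:
            i, j = rng.integers(0, cfg.parents, size=2)
            mask = rng.random(3) < 0.5
            child = np.where(mask, parents[i], parents[j])
            child = child + rng.normal(0.0, cfg.mutation_scale, size=3) * free
            children.append(make_individual(child))
        pop = np.array(children)
        costs = np.array([dt_fitness(trace, stats, CoefficientSet(*ind)) for ind in pop])
        order = np.argsort(costs, kind="stable")
        pop, costs = pop[order], costs[order]
        history.append(float(costs[0]))

    return CoefficientSet(*pop[0]), history
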