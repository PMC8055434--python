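"""High-level composition: calibrate a feature stream, run windowed
inference, and the scripted simulate → features → calibrate → optimize →
infer chain.

Windowed inference is interpretable by construction: every window's
decision is either a class label (some rule fired), ``artifact`` (an
input exceeded its crisp artifact threshold — online artifact handling),
or ``none`` (no rule fired — an explicit no-decision, never a silent
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    BaselineStats,
    CoefficientSet,
    DEFAULT_COEFFS,
    DigitalTwinTrace,
    GAConfig,
    baseline_stats,
    build_membership_set,
    optimize_coeffs,
)
from .engine import classify
from .rules import FuzzyRule, Label, RuleBase
from .spectral import (
    BAND_CLASS,
    DEFAULT_ARTIFACT_THRESHOLDS,
    BurstFeatureSeries,
    VariableId,
    WindowConfig,
    band_power_series,
    burst_features,
)
from .io import membership_variables
from .synthetic import BurstEvent, SimConfig, generate_raw

__all__ = [
    "extract_features",
    "calibrate_features",
    "optimize_membership",
    "infer_windows",
    "EndToEndResult",
    "run_end_to_end",
]


def extract_features(raw, run_cfg=None) -> BurstFeatureSeries:
    """Dual-window ERS″ extraction: fast bands on 250/125 ms windows,
    slow bands on 300/150 ms, per the run configuration.

    The two conventions produce variables like ``P8_BH_ERS2_250`` and
    ``P8_T_ERS2_300`` in one feature stream; per-variable timestamps keep
    the differing window grids aligned in time.
    """
    from .config import RunConfig

    run_cfg = run_cfg or RunConfig()
    merged = None
    for window in {run_cfg.window_for_band(b.code) for b in run_cfg.bands}:
        bands = tuple(
            b for b in run_cfg.bands if run_cfg.window_for_band(b.code) == window
        )
        feats = burst_features(band_power_series(raw, bands, window))
        if merged is None:
            merged = feats
        else:
            merged.values.update(feats.values)
            merged.window_end_ms.update(feats.window_end_ms)
    return merged


def calibrate_features(
    feats: BurstFeatureSeries,
    coeffs: CoefficientSet = CoefficientSet(*DEFAULT_COEFFS),
    n_baseline: int | None = 100,
    thresholds: dict[str, float] = DEFAULT_ARTIFACT_THRESHOLDS,
) -> dict[str, dict]:
    """Baseline-phase calibration of every variable in a feature stream.

    Statistics come from the first ``n_baseline`` windows (the reference
    phase; None = all windows).  Returns the membership table consumed by
    :func:`fuzzybci.io.save_membership` and :func:`infer_windows`.
    """
    table: dict[str, dict] = {}
    for var in sorted(feats.values):
        vid = VariableId.parse(var)
        samples = feats.values[var]
        if n_baseline is not None:
            samples = samples[:n_baseline]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats = baseline_stats(samples)
        table[var] = {
            "stats": stats,
            "coeffs": coeffs,
            "artifact_threshold": thresholds.get(BAND_CLASS.get(vid.band, "high")),
            "sets": build_membership_set(stats, coeffs),
        }
    return table


def optimize_membership(
    table: dict[str, dict],
    feats: BurstFeatureSeries,
    variables: list[str] | None = None,
    cfg: GAConfig = GAConfig(),
    mode: str = "baseline",
    n_windows: int | None = 100,
    genes: tuple[str, ...] = ("c1", "c2", "c3"),
) -> dict[str, list[float]]:
    """Digital-twin GA tuning of selected variables, each independently.

    Every variable gets its own GA/digital-twin pair (a simple loop, no
    shared state); the table entries are updated in place with the tuned
    coefficients and rebuilt sets.  Returns the per-variable best-cost
    histories.
    """
    histories: dict[str, list[float]] = {}
    for var in variables or sorted(table):
        vals = feats.values[var]
        if n_windows is not None:
            vals = vals[:n_windows]
        trace = DigitalTwinTrace(variable_id=var, values=vals, mode=mode)
        entry = table[var]
        best, history = optimize_coeffs(
            trace, entry["stats"], cfg, init=entry["coeffs"], genes=genes
        )
        entry["coeffs"] = best
        entry["sets"] = build_membership_set(entry["stats"], best)
        histories[var] = history
    return histories


def infer_windows(
    rb: RuleBase,
    feats: BurstFeatureSeries,
    table: dict[str, dict] | None = None,
    mode: str = "single_winner",
) -> pd.DataFrame:
    """Per-window classification log.

    Columns: ``window_end_ms, decision, label, tie`` plus one strength
    column per rule — the structured trace that keeps every decision
    attributable to its rules.  ``decision`` is the label as a string,
    ``"artifact"``, or ``"none"``.
    """
    needed = sorted({var for r in rb.rules for var, _ in r.antecedents})
    for var in needed:
        if var not in feats.values:
            raise KeyError(f"feature stream is missing variable {var!r}")
    n = min(len(feats.values[var]) for var in needed)
    times = feats.window_end_ms[needed[0]][-n:]
    rows = []
    for k in range(n):
        inputs = {var: float(feats.values[var][len(feats.values[var]) - n + k]) for var in needed}
        is_artifact = False
        for var, x in inputs.items():
            thr = rb.variables[var].artifact_threshold
            if thr is not None and abs(x) > thr:
                is_artifact = True
                break
        if is_artifact:
            rows.append((times[k], "artifact", None, False, *([np.nan] * len(rb.rules))))
            continue
        res = classify(rb, inputs, mode=mode)
        decision = str(res.label) if res.fired else "none"
        rows.append((times[k], decision, res.label, res.tie, *res.strengths))
    cols = ["window_end_ms", "decision", "label", "tie"] + [
        r.id or f"rule{j}" for j, r in enumerate(rb.rules)
    ]
    return pd.DataFrame(rows, columns=cols)


def coverage_rules(variables: list[str], start_index: int = 0) -> list[FuzzyRule]:
    """A per-variable rule set mapping each fuzzy state to a condition label.

    ``ref`` votes for the passive/reference class (1), positive bursts
    (``low``/``high``/``artifact``) for the active class (2), and
    ``desync`` for the desynchronization class (3).  Together the sets of
    one variable cover its calibrated axis above the desync floor, so a
    window is undecidable only if every variable is simultaneously far
    below baseline.
    """
    rules = []
    state_label = {"ref": 1, "low": 2, "high": 2, "artifact": 2, "desync": 3}
    for i, var in enumerate(variables):
        for state, label in state_label.items():
            rules.append(
                FuzzyRule(
                    antecedents=[(var, state)],
                    consequent=Label(label),
                    id=f"R{start_index + i}_{state}",
                )
            )
    return rules


@dataclass
class EndToEndResult:
    n_windows: int
    n_no_decision: int
    n_artifact: int
    label_counts: dict[str, int]
    histories: dict[str, list[float]] = field(default_factory=dict)
    decisions: pd.DataFrame | None = None


def run_end_to_end(
    seed: int = 0,
    duration_ms: float = 20000.0,
    electrodes: tuple[str, ...] = ("O2", "P8", "T8"),
    window: WindowConfig = WindowConfig(250, 125),
    ga_generations: int = 10,
) -> EndToEndResult:
    """The scripted pipeline on a default fixture.

    Simulates a recording whose first ~14 s are passive baseline and
    whose tail carries alpha and high-beta bursts, extracts ERS″
    features, calibrates every variable on the first 100 baseline
    windows, GA-tunes the two burst-carrying variables, classifies every
    window with per-variable coverage rules, and tallies the decisions.
    """
    bursts = [
        BurstEvent("O2", "A", onset_ms=15000.0, duration_ms=180.0, gain=2.5),
        BurstEvent("O2", "A", onset_ms=17000.0, duration_ms=150.0, gain=2.5),
        BurstEvent("P8", "BH", onset_ms=16000.0, duration_ms=150.0, gain=2.5),
        BurstEvent("P8", "BH", onset_ms=18000.0, duration_ms=150.0, gain=2.5),
    ]
    cfg = SimConfig(
        duration_ms=duration_ms, electrodes=electrodes, bursts=bursts, seed=seed
    )
    raw = generate_raw(cfg)
    feats = burst_features(band_power_series(raw, cfg.bands, window))
    table = calibrate_features(feats)
    ga = GAConfig(generations=ga_generations, seed=seed)
    histories = optimize_membership(
        table,
        feats,
        variables=[f"O2_A_ERS2_{int(window.window_ms)}", f"P8_BH_ERS2_{int(window.window_ms)}"],
        cfg=ga,
    )
    variables = sorted(feats.values)
    rb = RuleBase(rules=coverage_rules(variables), variables=membership_variables(table))
    decisions = infer_windows(rb, feats, table)
    counts = decisions["decision"].value_counts().to_dict()
    return EndToEndResult(
        n_windows=len(decisions),
        n_no_decision=int(counts.get("none", 0)),
        n_artifact=int(counts.get("artifact", 0)),
        label_counts={k: int(v) for k, v in counts.items() if k not in ("none", "artifact")},
        histories=histories,
        decisions=decisions,
    )
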