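"""Supervised fuzzy-classifier training by rule granulation and rule
consolidation (RGRC).

Each rule is a *granule*: a per-class fuzzy region described, per
feature, by a peak position and two standard deviations — a two-sided
Gaussian whose left and right widths differ.  Granule membership is the
product (t-norm) of the per-feature curves, and classification is
single-winner: a sample takes the class of the granule with maximal
membership.

Training proceeds in two stages.  *Granulation* seeds one granule per
class at the class feature means.  *Consolidation* then iterates three
moves, each accepted only if the global single-winner training error
does not increase:

1. split the worst rule — the granule contributing the largest number of
   misclassified governed samples — by spawning a new granule at the
   centroid of its errors;
2. transfer misclassified samples to the best-matching granule of their
   true class and refit both granules;
3. re-rank rules by (support, error) and drop unsupported rules, except
   that a sparse rule (down to a single governed sample) survives when
   removing it would increase the error — sparse bursts are signal here,
   not outliers.

The loop stops at the first iteration in which no transfer is accepted
("consolidation stabilization") or after ``max_iterations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GaussianGranule",
    "TrainConfig",
    "IterationRecord",
    "granule_membership",
    "granulate",
    "consolidate",
    "evaluate",
    "train",
]

_SIGMA_FLOOR_FRAC = 1e-6


@dataclass
class GaussianGranule:
    """One fuzzy rule: class label + per-feature two-sided Gaussian."""

    label: int
    peak: np.ndarray
    sigma_left: np.ndarray
    sigma_right: np.ndarray
    support: int = 0
    error: int = 0  # misclassified governed samples (global-error contribution)

    def __post_init__(self) -> None:
        self.peak = np.asarray(self.peak, dtype=float)
        self.sigma_left = np.asarray(self.sigma_left, dtype=float)
        self.sigma_right = np.asarray(self.sigma_right, dtype=float)
        if not (self.peak.shape == self.sigma_left.shape == self.sigma_right.shape):
            raise ValueError("peak and sigma arrays must share one shape")
        if np.any(self.sigma_left <= 0) or np.any(self.sigma_right <= 0):
            raise ValueError("granule sigmas must be positive")


@dataclass
class TrainConfig:
    """Consolidation budget and rule-retention threshold."""

    max_iterations: int = 15
    min_support: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    error: int
    transfers: int
    splits: int
    dropped: int
    n_rules: int


def granule_membership(g: GaussianGranule, x: np.ndarray) -> float | np.ndarray:
    """Two-sided Gaussian membership, product over features.

    For feature j the curve is ``exp(-0.5 ((x_j - peak_j)/sigma)^2)`` with
    ``sigma_left`` below the peak and ``sigma_right`` above; membership is
    1 exactly at the peak vector.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(g.peak):
        raise ValueError(
            f"feature dimension mismatch: granule has {len(g.peak)}, input has {X.shape[1]}"
        )
    dev = X - g.peak
    sigma = np.where(dev < 0, g.sigma_left, g.sigma_right)
    mu = np.exp(-0.5 * np.sum((dev / sigma) ** 2, axis=1))
    return float(mu[0]) if single else mu


def _membership_matrix(granules: list[GaussianGranule], X: np.ndarray) -> np.ndarray:
    return np.column_stack([granule_membership(g, X) for g in granules])


def _predict(granules: list[GaussianGranule], X: np.ndarray) -> np.ndarray:
    """Single-winner labels; membership ties break to the lower granule index."""
    mm = _membership_matrix(granules, X)
    win = np.argmax(mm, axis=1)  # argmax takes the first (lowest) index on ties
    labels = np.array([g.label for g in granules])
    return labels[win]


def _govern(granules: list[GaussianGranule], X: np.ndarray) -> np.ndarray:
    return np.argmax(_membership_matrix(granules, X), axis=1)


def _fit_sigmas(
    values: np.ndarray, peak: np.ndarray, floor: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-side RMS deviations around a peak, floored per feature."""
    dev = values - peak
    s_l = np.empty(len(peak))
    s_r = np.empty(len(peak))
    for j in range(len(peak)):
        below = dev[dev[:, j] < 0, j]
        above = dev[dev[:, j] > 0, j]
        s_l[j] = np.sqrt(np.mean(below**2)) if len(below) else 0.0
        s_r[j] = np.sqrt(np.mean(above**2)) if len(above) else 0.0
        if s_l[j] == 0.0 and s_r[j] > 0.0:
            s_l[j] = s_r[j]
        if s_r[j] == 0.0 and s_l[j] > 0.0:
            s_r[j] = s_l[j]
    return np.maximum(s_l, floor), np.maximum(s_r, floor)


def _fit_granule(label: int, values: np.ndarray, floor: np.ndarray) -> GaussianGranule:
    peak = np.mean(values, axis=0)
    s_l, s_r = _fit_sigmas(values, peak, floor)
    return GaussianGranule(label=int(label), peak=peak, sigma_left=s_l, sigma_right=s_r)


def _sigma_floor(X: np.ndarray) -> np.ndarray:
    rng = np.ptp(X, axis=0)
    return _SIGMA_FLOOR_FRAC * np.where(rng > 0, rng, 1.0)


def granulate(X: np.ndarray, y: np.ndarray) -> list[GaussianGranule]:
    """Seed one granule per class at the class feature means."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a nonempty (n_samples, n_features) matrix")
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    floor = _sigma_floor(X)
    granules = []
    for label in sorted(np.unique(y).tolist()):
        vals = X[y == label]
        if len(vals) < 2:
            raise ValueError(f"class {label} has fewer than 2 samples")
        granules.append(_fit_granule(label, vals, floor))
    _update_support(granules, X, y)
    return granules


def _update_support(granules: list[GaussianGranule], X: np.ndarray, y: np.ndarray) -> int:
    """Recompute support/error per granule; return the global error count."""
    gov = _govern(granules, X)
    total = 0
    for k, g in enumerate(granules):
        mask = gov == k
        g.support = int(np.sum(mask))
        g.error = int(np.sum(y[mask] != g.label))
        total += g.error
    return total


def consolidate(
    granules: list[GaussianGranule],
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[list[GaussianGranule], list[IterationRecord]]:
    """Iterative split / transfer / re-rank consolidation.

    Every structural move is kept only if the global single-winner error
    does not increase, so the error trajectory is non-increasing by
    construction (asserted).  Stops at the first iteration with no
    accepted transfer.  Returns the final rule list and an iteration log
    whose last entry is the stabilization iteration.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    floor = _sigma_floor(X)
    granules = [replace(g) for g in granules]
    # Explicit assignment sets drive the refits; start from governance.
    assign = list(_govern(granules, X))
    error = _update_support(granules, X, y)
    log: list[IterationRecord] = []

    def refit(k: int) -> GaussianGranule | None:
        members = [i for i, a in enumerate(assign) if a == k]
        if not members:
            return None
        return _fit_granule(granules[k].label, X[members], floor)

    for it in range(1, cfg.max_iterations + 1):
        transfers = splits = dropped = 0

        # (i) split the worst rule at its error centroid
        _update_support(granules, X, y)
        worst = max(range(len(granules)), key=lambda k: granules[k].error)
        if granules[worst].error > cfg.min_support:
            gov = _govern(granules, X)
            mis = np.where((gov == worst) & (y != granules[worst].label))[0]
            labels, counts = np.unique(y[mis], return_counts=True)
            maj = int(labels[np.argmax(counts)])
            new_members = [int(i) for i in mis if y[i] == maj]
            candidate = _fit_granule(maj, X[new_members], floor)
            trial = granules + [candidate]
            trial_err = _update_support(trial, X, y)
            if trial_err <= error:
                granules = trial
                for i in new_members:
                    assign[i] = len(granules) - 1
                error = trial_err
                splits += 1
            else:
                _update_support(granules, X, y)

        # (ii) transfer misclassified samples toward their true class
        pred = _predict(granules, X)
        for i in np.where(pred != y)[0]:
            targets = [k for k, g in enumerate(granules) if g.label == y[i]]
            if not targets:
                continue
            mus = [granule_membership(granules[k], X[i]) for k in targets]
            target = targets[int(np.argmax(mus))]
            source = assign[i]
            if source == target:
                continue
            old_src, old_tgt = granules[source], granules[target]
            old_assign = assign[i]
            assign[i] = target
            new_tgt = refit(target)
            new_src = refit(source)
            granules[target] = new_tgt if new_tgt is not None else old_tgt
            if new_src is not None:
                granules[source] = new_src
            trial_err = _update_support(granules, X, y)
            if trial_err <= error:
                error = trial_err
                transfers += 1
            else:
                granules[source], granules[target] = old_src, old_tgt
                assign[i] = old_assign
                _update_support(granules, X, y)

        # (iii) re-rank by (support desc, error asc); drop unsupported rules
        # unless removing them would increase the error (sparse-data rule)
        error = _update_support(granules, X, y)
        order = sorted(
            range(len(granules)), key=lambda k: (-granules[k].support, granules[k].error)
        )
        granules = [granules[k] for k in order]
        remap = {old: new for new, old in enumerate(order)}
        assign = [remap[a] for a in assign]
        for k in range(len(granules) - 1, -1, -1):
            if granules[k].support >= cfg.min_support and granules[k].support > 0:
                continue
            if len(granules) == 1:
                break
            trial = granules[:k] + granules[k + 1 :]
            if _update_support(trial, X, y) <= error:
                granules = trial
                gov = _govern(granules, X)
                assign = [
                    int(gov[i]) if a == k else (a - 1 if a > k else a)
                    for i, a in enumerate(assign)
                ]
                dropped += 1
        error = _update_support(granules, X, y)

        if log:
            assert error <= log[-1].error, "consolidation increased the global error"
        log.append(
            IterationRecord(
                iteration=it,
                error=error,
                transfers=transfers,
                splits=splits,
                dropped=dropped,
                n_rules=len(granules),
            )
        )
        if transfers == 0:
            break

    return granules, log


def evaluate(
    granules: list[GaussianGranule], X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[tuple[int, int], int]]:
    """Single-winner accuracy and (true, predicted) confusion counts."""
    if not granules:
        raise ValueError("no rules to evaluate")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    pred = _predict(granules, X)
    confusion: dict[tuple[int, int], int] = {}
    for t, p in zip(y, pred):
        confusion[(int(t), int(p))] = confusion.get((int(t), int(p)), 0) + 1
    return float(np.mean(pred == y)), confusion


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[list[GaussianGranule], list[IterationRecord]]:
    """Granulate then consolidate; the standard training entry point."""
    return consolidate(granulate(X, y), X, y, cfg)
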