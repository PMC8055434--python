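"""Baseline statistics, trapezoid construction, digital-twin cost, and GA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzybci.calibration import (
    BaselineStats,
    CoefficientSet,
    DigitalTwinTrace,
    GAConfig,
    baseline_stats,
    build_membership_set,
    dt_cost,
    dt_fitness,
    optimize_coeffs,
)
from fuzzybci.membership import membership
from fuzzybci.synthetic import generate_baseline_power

UNIT_STATS = BaselineStats(0.0, 1.0, 100)
DEFAULTS = CoefficientSet(1.2, 1.4, 2.0)


class TestBaselineStats:
    def test_hand_mean_and_sample_std(self):
        with pytest.warns(UserWarning, match="100"):
            s = baseline_stats([2, 4, 6])
        assert s.m == 4.0
        assert s.std == pytest.approx(2.0)  # sqrt((4+0+4)/2)

    def test_constant_baseline_gets_epsilon_floor(self):
        with pytest.warns(UserWarning):
            s = baseline_stats([5.0] * 10)
        assert s.std == pytest.approx(1e-6 * 5.0)

    def test_hundred_samples_no_warning(self, recwarn):
        baseline_stats(np.zeros(100) + np.arange(100))
        assert not [w for w in recwarn if "100" in str(w.message)]

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            baseline_stats([1.0])


class TestBuildMembership:
    def test_hand_substituted_trapezoids(self):
        sets = build_membership_set(UNIT_STATS, DEFAULTS)
        assert sets["ref"].as_list() == [-1.2, -1.0, 1.0, 1.2]
        assert sets["low"].as_list() == [1.0, 1.2, 1.4, 2.0]
        assert sets["high"].as_list() == [1.4, 2.0, 6.0, 6.0]
        assert sets["desync"].as_list() == [-6.0, -6.0, -2.0, -1.0]

    def test_artifact_region_excluded_from_high(self):
        # beyond m + 3*c3*s the vertical right leg cuts membership to zero
        sets = build_membership_set(UNIT_STATS, DEFAULTS)
        assert membership(sets["high"], 6.0) == 1.0
        assert membership(sets["high"], 6.0001) == 0.0
        assert membership(sets["artifact"], 6.0001) == 1.0

    def test_mean_is_pure_reference(self):
        sets = build_membership_set(UNIT_STATS, DEFAULTS)
        assert membership(sets["ref"], 0.0) == 1.0
        assert membership(sets["low"], 0.0) == 0.0
        assert membership(sets["high"], 0.0) == 0.0

    def test_coefficient_ordering_required(self):
        with pytest.raises(ValueError):
            CoefficientSet(1.4, 1.2, 2.0)
        with pytest.raises(ValueError):
            CoefficientSet(0.9, 1.2, 2.0)


class TestDigitalTwinCost:
    def test_canonical_hand_values(self, unit_sets):
        # ref core -> 0; low core only -> 1; half/half -> 0.5
        assert dt_cost(0.0, unit_sets, "baseline") == pytest.approx(0.0)
        assert dt_cost(1.3, unit_sets, "baseline") == pytest.approx(1.0)
        assert dt_cost(1.1, unit_sets, "baseline") == pytest.approx(0.5)

    def test_active_mode_high_core(self, unit_sets):
        assert dt_cost(3.0, unit_sets, "active") == pytest.approx(0.0)
        assert dt_cost(0.0, unit_sets, "active") == pytest.approx(1.0)

    def test_outside_modelled_region_is_maximal(self, unit_sets):
        assert dt_cost(-5.0, unit_sets, "baseline") == 1.0
        assert dt_cost(100.0, unit_sets, "baseline") == 1.0

    @given(x=st.floats(-20, 20), mode=st.sampled_from(["baseline", "active"]))
    @settings(max_examples=200, derandomize=True)
    def test_bounded(self, x, mode):
        sets = build_membership_set(UNIT_STATS, DEFAULTS)
        assert 0.0 <= dt_cost(x, sets, mode) <= 1.0

    def test_fitness_matches_loop_oracle(self):
        vals = np.array([0.0, 0.5, 1.1, 1.3, 2.5, -0.4, -3.0])
        trace = DigitalTwinTrace("O2_A_ERS2_250", vals, "baseline")
        sets = build_membership_set(UNIT_STATS, DEFAULTS, include_artifact=False)
        expected = np.mean([dt_cost(float(v), sets, "baseline") for v in vals])
        assert dt_fitness(trace, UNIT_STATS, DEFAULTS) == pytest.approx(expected)

    def test_in_core_trace_costs_nothing(self):
        trace = DigitalTwinTrace("O2_A_ERS2_250", np.linspace(-0.9, 0.9, 20), "baseline")
        assert dt_fitness(trace, UNIT_STATS, DEFAULTS) == 0.0

    def test_low_core_trace_costs_everything(self):
        trace = DigitalTwinTrace("O2_A_ERS2_250", np.full(10, 1.3), "baseline")
        assert dt_fitness(trace, UNIT_STATS, DEFAULTS) == 1.0

    def test_baseline_band_costs_zero_for_any_valid_coeffs(self):
        # values within m +/- s sit in the ref core for every c1 > 1
        rng = np.random.default_rng(0)
        vals = rng.uniform(-0.999, 0.999, size=50)
        trace = DigitalTwinTrace("O2_A_ERS2_250", vals, "baseline")
        for coeffs in [CoefficientSet(1.01, 1.5, 2), CoefficientSet(2, 2, 2)]:
            assert dt_fitness(trace, UNIT_STATS, coeffs) == 0.0


class TestGA:
    def _trace(self, seed):
        return DigitalTwinTrace(
            "O2_A_ERS2_250", generate_baseline_power(0, 1, 60, seed=seed), "baseline"
        )

    def test_seeded_determinism(self):
        trace = self._trace(3)
        cfg = GAConfig(generations=5, seed=9)
        b1, h1 = optimize_coeffs(trace, UNIT_STATS, cfg)
        b2, h2 = optimize_coeffs(trace, UNIT_STATS, cfg)
        assert h1 == h2
        assert b1.as_tuple() == b2.as_tuple()

    def test_history_non_increasing(self):
        trace = self._trace(4)
        _, hist = optimize_coeffs(trace, UNIT_STATS, GAConfig(seed=1))
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))
        assert len(hist) == 10

    def test_converges_on_synthetic_baseline(self):
        trace = self._trace(5)
        best, hist = optimize_coeffs(trace, UNIT_STATS, GAConfig(seed=2))
        assert hist[-1] < 0.05
        assert 1.0 <= best.c1 <= best.c2 <= best.c3

    def test_restricted_genes_keep_fixed_coefficients(self):
        trace = DigitalTwinTrace(
            "O2_A_ERS2_250", generate_baseline_power(2.5, 0.3, 40, seed=8), "active"
        )
        init = CoefficientSet(1.2, 1.4, 2.0)
        best, _ = optimize_coeffs(
            trace, UNIT_STATS, GAConfig(generations=5, seed=3), init=init, genes=("c3",)
        )
        assert best.c1 == init.c1
        assert best.c2 == init.c2
        assert best.c2 <= best.c3

    def test_parameter_recovery_classifies_heldout_identically(self):
        # sets built with known coeffs generate an in-high-core active trace;
        # c3 refinement must recover sets that classify >= 95% of a held-out
        # trace the same way as the generating sets
        true = CoefficientSet(1.2, 1.4, 2.0)
        true_sets = build_membership_set(UNIT_STATS, true, include_artifact=False)
        rng = np.random.default_rng(12)
        fit = rng.uniform(2.05, 5.9, size=60)  # inside the true 'high' core [2, 6]
        held = rng.uniform(0.0, 8.0, size=400)
        trace = DigitalTwinTrace("O2_A_ERS2_250", fit, "active")
        best, _ = optimize_coeffs(
            trace,
            UNIT_STATS,
            GAConfig(seed=4),
            init=CoefficientSet(1.2, 1.4, 1.4),
            genes=("c3",),
        )
        got_sets = build_membership_set(UNIT_STATS, best, include_artifact=False)

        def in_high(sets, x):
            return membership(sets["high"], x) >= 0.5

        agree = np.mean([in_high(true_sets, x) == in_high(got_sets, x) for x in held])
        assert agree >= 0.95

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(gene_bounds=((0.5, 2.0), (1.0, 3.0), (1.0, 4.0)))
        with pytest.raises(ValueError):
            GAConfig(parents=50, population=40)
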