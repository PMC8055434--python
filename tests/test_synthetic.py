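"""Synthetic EEG generator: determinism, stationarity, burst injection,
Parseval consistency, and the labelled dataset."""

import numpy as np
import pytest

from fuzzybci.spectral import (
    DEFAULT_BANDS,
    WindowConfig,
    band_power_series,
    burst_series,
    locate_burst_onset,
)
from fuzzybci.synthetic import (
    ArtifactEvent,
    BurstEvent,
    SimConfig,
    generate_baseline_power,
    generate_labelled_dataset,
    generate_raw,
)

CFG250 = WindowConfig(250, 125)


class TestGenerateRaw:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(duration_ms=2000, electrodes=("O2", "P8"), seed=5)
        a = generate_raw(cfg)
        b = generate_raw(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_stationary_baseline_low_cv(self):
        cfg = SimConfig(duration_ms=8000, electrodes=("O2",), noise_sigma=0.0, seed=2)
        raw = generate_raw(cfg)
        bps = band_power_series(raw, cfg.bands, CFG250)
        assert bps.n_windows >= 30
        for key, p in bps.entries.items():
            cv = np.std(p) / np.mean(p)
            assert cv < 0.5, f"{key} CV {cv:.2f}"

    def test_unknown_burst_target_rejected(self):
        with pytest.raises(ValueError, match="unknown electrode"):
            SimConfig(electrodes=("O2",), bursts=[BurstEvent("XX", "A", 500.0)])
        with pytest.raises(ValueError, match="unknown band"):
            SimConfig(electrodes=("O2",), bursts=[BurstEvent("O2", "Z", 500.0)])

    def test_burst_gain_must_exceed_one(self):
        with pytest.raises(ValueError):
            BurstEvent("O2", "A", 500.0, gain=0.9)

    def test_burst_localized_within_one_step(self):
        ev = BurstEvent("O2", "G", onset_ms=1000.0, duration_ms=200.0, gain=4.5)
        cfg = SimConfig(duration_ms=2000, electrodes=("O2",), bursts=[ev], seed=3)
        raw = generate_raw(cfg)
        bps = band_power_series(raw, cfg.bands, CFG250)
        _, e2 = burst_series(bps.entries[("O2", "G")])
        est = locate_burst_onset(e2, bps.window_end_ms[2:], CFG250, duration_ms=200.0)
        assert abs(est - 1000.0) <= CFG250.step_ms

    def test_burst_crosstalk_bounded(self):
        # the injected burst moves its own (electrode, band) series beyond
        # 3 sigma of the no-burst variability; every other electrode stays
        # bit-identical and spectrally non-adjacent bands stay within 3
        # sigma.  (An amplitude-modulated 200 ms burst has ~5 Hz of
        # modulation bandwidth, so the directly adjacent band is excluded
        # from the bound.)
        base_cfg = SimConfig(duration_ms=4000, electrodes=("O2", "P8"), seed=4)
        ev = BurstEvent("O2", "A", onset_ms=2000.0, duration_ms=200.0, gain=3.0)
        burst_cfg = SimConfig(
            duration_ms=4000, electrodes=("O2", "P8"), bursts=[ev], seed=4
        )
        quiet = band_power_series(generate_raw(base_cfg), base_cfg.bands, CFG250)
        noisy = band_power_series(generate_raw(burst_cfg), burst_cfg.bands, CFG250)
        adjacent = {("O2", "T"), ("O2", "B")}
        for key in quiet.entries:
            delta = np.max(np.abs(noisy.entries[key] - quiet.entries[key]))
            spread = 3 * np.std(quiet.entries[key])
            if key == ("O2", "A"):
                assert delta > spread
            elif key[0] == "P8":
                assert delta == 0.0, key
            elif key not in adjacent:
                assert delta <= max(spread, 1e-9), key

    def test_artifact_spike_is_broadband_and_local(self):
        ev = ArtifactEvent("O2", onset_ms=1000.0, amplitude=120.0, width_ms=30.0)
        cfg = SimConfig(duration_ms=2000, electrodes=("O2", "P8"), artifacts=[ev], seed=6)
        raw = generate_raw(cfg)
        i_o2 = raw.electrodes.index("O2")
        i_p8 = raw.electrodes.index("P8")
        k = round(1.0 * raw.fs)  # 1000 ms
        assert abs(raw.samples[i_o2, k]) > 5 * np.std(raw.samples[i_p8])

    def test_parseval_total_band_power(self):
        # noise-free tones on FFT bins: per-band mean density * n_bins * df
        # must sum to the analytic total A^2/2 within 1%
        fs = 256.0
        t = np.arange(1024) / fs
        tones = [(6.0, 2.0), (10.0, 3.0), (20.0, 1.5), (30.0, 1.0)]
        x = sum(a * np.sin(2 * np.pi * f * t) for f, a in tones)
        from fuzzybci.spectral import band_power_window

        df = fs / 1024
        total = 0.0
        for band in DEFAULT_BANDS:
            n_bins = np.sum(
                (np.fft.rfftfreq(1024, 1 / fs) >= band.lo)
                & (np.fft.rfftfreq(1024, 1 / fs) < band.hi)
            )
            total += band_power_window(x, fs, band) * n_bins * df
        analytic = sum(a**2 / 2 for _, a in tones)
        assert total == pytest.approx(analytic, rel=0.01)


class TestBaselinePower:
    def test_reproducible(self):
        a = generate_baseline_power(0, 1, 50, seed=1)
        b = generate_baseline_power(0, 1, 50, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_clt_mean_bound(self):
        x = generate_baseline_power(2.0, 0.5, 1000, seed=2)
        assert abs(np.mean(x) - 2.0) < 4 * 0.5 / np.sqrt(1000)

    def test_zero_std_constant(self):
        assert np.ptp(generate_baseline_power(3.0, 0.0, 10, seed=3)) == 0.0


class TestLabelledDataset:
    def test_balanced_labels_and_reproducible(self):
        ds = generate_labelled_dataset(n_trials=30, seed=11)
        counts = np.bincount(ds.labels)[1:]
        assert counts.max() - counts.min() <= 1
        ds2 = generate_labelled_dataset(n_trials=30, seed=11)
        X1, _ = ds.to_matrix()
        X2, _ = ds2.to_matrix()
        np.testing.assert_array_equal(X1, X2)

    def test_label_matrix_one_hot(self):
        ds = generate_labelled_dataset(n_trials=9, seed=1)
        L = ds.label_matrix()
        assert L.shape == (9, 3)
        np.testing.assert_array_equal(L.sum(axis=1), np.ones(9, dtype=int))

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_labelled_dataset(n_trials=2, seed=0)
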