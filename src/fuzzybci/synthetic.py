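"""Seeded synthetic EEG with controlled baselines, bursts, and artifacts.

The generator emulates the statistical structure the fuzzy pipeline
relies on — stationary per-band baseline power, condition-locked band
bursts, and transient broadband artifacts — without claiming
physiological realism (no 1/f spectrum, volume conduction, or blink
morphology).  Each electrode is a superposition of band-limited
random-phase sinusoids (on a 4 Hz grid by default, amplitudes
normalized so a band's total power equals ``amp**2 / 2``) plus white
noise.  Grid-aligned tones land exactly on the FFT bins of the canonical
250 ms analysis window, so baseline band power is window-stationary and
has an exact analytic expectation; residual fluctuation comes from the
white-noise floor.

A burst multiplies the target band's envelope by ``gain`` over
``[onset, onset + duration]`` with 40 ms raised-cosine ramps (sharp
rectangular gating would splatter power across bands and trip the
artifact thresholds).  An artifact adds a broadband Gaussian-envelope
voltage spike on one electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import TrialDataset
from .spectral import (
    DEFAULT_BANDS,
    BandSpec,
    RawEEG,
    WindowConfig,
    band_power_series,
    burst_features,
)

__all__ = [
    "BurstEvent",
    "ArtifactEvent",
    "SimConfig",
    "DEFAULT_ELECTRODES",
    "CONDITION_SIGNATURES",
    "generate_raw",
    "generate_baseline_power",
    "generate_labelled_dataset",
]

#: The 12-channel consumer-headset montage used throughout.
DEFAULT_ELECTRODES: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "T7", "T8", "P7", "P8", "O1", "O2",
)

#: Per-band baseline oscillation amplitudes (µV), loosely 1/f-ordered and
#: scaled so fast-band baseline power density stays near 1 µV²/Hz — well
#: below the 10-unit fast-band artifact cutoff even during genuine bursts.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {"T": 8.0, "A": 10.0, "B": 4.0, "BH": 3.5, "G": 3.0}

#: Raised-cosine on/off ramp for burst envelopes.  Sharp gating splatters
#: modulation sidebands across neighbouring bands; 40 ms keeps the
#: splatter below the baseline noise of non-adjacent bands while staying
#: well below the shortest burst duration.
_RAMP_MS = 40.0


@dataclass(frozen=True)
class BurstEvent:
    """A condition-locked band-power burst on one electrode.

    ``gain`` multiplies the band's oscillation amplitude (so band power
    scales by ``gain**2``) over ``[onset, onset + duration]``.  Typical
    burst durations are 100-200 ms.
    """

    electrode: str
    band: str
    onset_ms: float
    duration_ms: float = 150.0
    gain: float = 3.0

    def __post_init__(self) -> None:
        if self.gain <= 1.0:
            raise ValueError(f"burst gain must exceed 1, got {self.gain}")
        if self.duration_ms < 100.0:
            raise ValueError(
                f"burst duration {self.duration_ms} ms is below the 100 ms minimum "
                "(shorter bursts cannot span an analysis step)"
            )


@dataclass(frozen=True)
class ArtifactEvent:
    """A transient broadband voltage spike (ocular/muscle-like)."""

    electrode: str
    onset_ms: float
    amplitude: float = 80.0
    width_ms: float = 30.0


@dataclass
class SimConfig:
    """Synthetic recording configuration (fully seeded)."""

    fs: float = 256.0
    duration_ms: float = 2000.0
    electrodes: tuple[str, ...] = DEFAULT_ELECTRODES
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_sigma: float = 2.0
    tone_spacing_hz: float = 4.0
    bursts: list[BurstEvent] = field(default_factory=list)
    artifacts: list[ArtifactEvent] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        top = max(b.hi for b in self.bands)
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} must exceed twice the top band edge {top} Hz")
        if self.duration_ms < 500.0:
            raise ValueError(
                f"duration {self.duration_ms} ms is too short for three 250/125 ms windows"
            )
        for ev in self.bursts:
            if ev.electrode not in self.electrodes:
                raise ValueError(f"burst references unknown electrode {ev.electrode!r}")
            if ev.band not in {b.code for b in self.bands}:
                raise ValueError(f"burst references unknown band {ev.band!r}")
        for ev in self.artifacts:
            if ev.electrode not in self.electrodes:
                raise ValueError(f"artifact references unknown electrode {ev.electrode!r}")


def _burst_envelope(t_ms: np.ndarray, events: list[BurstEvent]) -> np.ndarray:
    """Multiplicative envelope: 1 at baseline, `gain` inside each burst."""
    env = np.ones_like(t_ms)
    for ev in events:
        rise = np.clip((t_ms - ev.onset_ms) / _RAMP_MS, 0.0, 1.0)
        fall = np.clip((ev.onset_ms + ev.duration_ms - t_ms) / _RAMP_MS, 0.0, 1.0)
        shape = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
        env += (ev.gain - 1.0) * shape
    return env


def generate_raw(cfg: SimConfig) -> RawEEG:
    """Synthesize a seeded multichannel recording per the configuration."""
    rng = np.random.default_rng(cfg.seed)
    n = round(cfg.duration_ms / 1000.0 * cfg.fs)
    t = np.arange(n) / cfg.fs
    t_ms = t * 1000.0
    samples = np.zeros((len(cfg.electrodes), n))
    for e_i, electrode in enumerate(cfg.electrodes):
        x = cfg.noise_sigma * rng.standard_normal(n) if cfg.noise_sigma > 0 else np.zeros(n)
        for band in cfg.bands:
            amp = cfg.band_amplitudes.get(band.code, 0.0)
            if amp <= 0:
                continue
            # tones sit on the tone-spacing grid (default 4 Hz, the bin
            # spacing of a 250 ms window at 256 Hz): on-bin tones leak into
            # no other band and give window-stationary baseline power
            lo_grid = np.ceil(band.lo / cfg.tone_spacing_hz) * cfg.tone_spacing_hz
            tones = np.arange(lo_grid, band.hi, cfg.tone_spacing_hz)
            if len(tones) == 0:
                tones = np.array([(band.lo + band.hi) / 2])
            phases = rng.uniform(0, 2 * np.pi, size=len(tones))
            osc = np.sin(
                2 * np.pi * tones[:, None] * t[None, :] + phases[:, None]
            ).sum(axis=0) * (amp / np.sqrt(len(tones)))
            events = [
                ev for ev in cfg.bursts
                if ev.electrode == electrode and ev.band == band.code
            ]
            if events:
                osc *= _burst_envelope(t_ms, events)
            x += osc
        for ev in cfg.artifacts:
            if ev.electrode == electrode:
                x += ev.amplitude * np.exp(-0.5 * ((t_ms - ev.onset_ms) / (ev.width_ms / 2)) ** 2)
        samples[e_i] = x
    return RawEEG(fs=cfg.fs, electrodes=list(cfg.electrodes), samples=samples, t0=0.0)


def generate_baseline_power(m: float, std: float, n: int, seed: int | None = None) -> np.ndarray:
    """``n`` seeded Gaussian feature draws — a reference-phase replay trace."""
    if std < 0:
        raise ValueError("std must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.normal(m, std, size=n)


#: Condition burst signatures for the three-condition study fixture:
#: 1 (audio attention)      — temporal theta + gamma bursts;
#: 2 (cognitive-map forming) — parietal high-beta/gamma + frontal theta, stronger;
#: 3 (visuospatial traversing) — parietal gamma only.
CONDITION_SIGNATURES: dict[int, tuple[tuple[str, str, float], ...]] = {
    1: (("T7", "T", 3.5), ("T8", "T", 3.5), ("T7", "G", 3.5), ("T8", "G", 3.5)),
    2: (("P7", "BH", 4.0), ("P8", "BH", 4.0), ("P8", "G", 4.0), ("F3", "T", 4.0), ("F4", "T", 4.0)),
    3: (("P8", "G", 3.5), ("P7", "G", 3.5)),
}

#: Focused montage for the labelled dataset (the electrodes of interest).
DATASET_ELECTRODES: tuple[str, ...] = ("F3", "F4", "T7", "T8", "P7", "P8")


def generate_labelled_dataset(
    n_trials: int = 300,
    seed: int | None = None,
    signatures: dict[int, tuple[tuple[str, str, float], ...]] = CONDITION_SIGNATURES,
    electrodes: tuple[str, ...] = DATASET_ELECTRODES,
    trial_duration_ms: float = 1250.0,
    window: WindowConfig = WindowConfig(250, 125),
    noise_sigma: float = 2.0,
) -> TrialDataset:
    """Labelled trials with distinct per-condition burst signatures.

    Trials cycle through the conditions (balanced ±1).  Each trial gets
    one burst per signature entry, onset jittered in [400, 800] ms, and
    its ERS″ feature matrix over all (electrode, band) variables of the
    focused montage.
    """
    conditions = sorted(signatures)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions with distinct signatures")
    if n_trials < len(conditions):
        raise ValueError(f"n_trials={n_trials} is fewer than {len(conditions)} conditions")
    rng = np.random.default_rng(seed)
    trials: list[pd.DataFrame] = []
    labels = []
    for i in range(n_trials):
        cond = conditions[i % len(conditions)]
        onset = float(rng.uniform(400.0, 700.0))
        bursts = [
            BurstEvent(
                electrode=el,
                band=band,
                onset_ms=onset + float(rng.uniform(-40.0, 40.0)),
                duration_ms=float(rng.uniform(150.0, 250.0)),
                gain=gain * float(rng.uniform(0.9, 1.1)),
            )
            for el, band, gain in signatures[cond]
        ]
        cfg = SimConfig(
            duration_ms=trial_duration_ms,
            electrodes=electrodes,
            bursts=bursts,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        raw = generate_raw(cfg)
        feats = burst_features(band_power_series(raw, cfg.bands, window))
        cols = sorted(feats.values)
        first = cols[0]
        frame = pd.DataFrame(
            {c: feats.values[c] for c in cols}, index=feats.window_end_ms[first]
        )
        frame.index.name = "window_end_ms"
        trials.append(frame)
        labels.append(cond)
    return TrialDataset(trials=trials, labels=np.array(labels), classes=tuple(conditions))
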