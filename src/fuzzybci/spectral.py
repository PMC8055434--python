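"""Windowed EEG band power and ERS″/ERD″ burst features.

Event-related synchronization / desynchronization (ERS/ERD) describe the
increase/decrease of a frequency band's power relative to a reference
interval.  The burst feature used throughout this package, written ERS″
(ERD″ for the negative-going case), is the *second finite difference* of
windowed band power: a large positive ERS″ marks the onset of a short
power burst, a large negative one marks its offset.  Because the feature
is computed on a sliding window of length ``window_ms`` advanced by
``step_ms``, the reported burst latency equals one window step.

Band power is computed as mean periodogram power density (µV²/Hz) over
the FFT bins falling inside a band, per analysis window.  Windows are
short (64–77 samples at 256 Hz), so a plain rectangular-window
periodogram is used without Welch sub-averaging.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "RawEEG",
    "BandSpec",
    "WindowConfig",
    "BandPowerSeries",
    "BurstFeatureSeries",
    "DEFAULT_BANDS",
    "DEFAULT_ARTIFACT_THRESHOLDS",
    "BAND_CLASS",
    "VariableId",
    "segment_windows",
    "band_power_window",
    "band_power_series",
    "burst_series",
    "flag_artifact",
    "workload_score",
    "valence_score",
    "burst_features",
]


class SpectralError(ValueError):
    """Raised for invalid windowing/band-power requests."""


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[lo, hi)`` in Hz with a short code (T, A, B, BH, G)."""

    code: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise SpectralError(
                f"band {self.code!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})"
            )


#: Default band table: theta, alpha, beta, high beta, gamma.  The recording
#: chain is assumed band-limited to 4-50 Hz; a delta band is deliberately
#: absent.  High beta (18-25 Hz) is split out because fast-band bursts are
#: accessed on a shorter window than the slow bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("T", 4.0, 8.0),
    BandSpec("A", 8.0, 13.0),
    BandSpec("B", 13.0, 18.0),
    BandSpec("BH", 18.0, 25.0),
    BandSpec("G", 25.0, 45.0),
)

#: Band class used by the artifact thresholds: slow-wave bands carry much
#: more 1/f power than fast bands, so artifact cutoffs are class-specific.
BAND_CLASS: dict[str, str] = {"T": "low", "A": "low", "B": "high", "BH": "high", "G": "high"}

#: Artifact thresholds on |ERS''| in raw power-density units: ocular/muscle
#: and connectivity artifacts show bursts over 150 units in the slow bands
#: and over 10 units in the fast bands.
DEFAULT_ARTIFACT_THRESHOLDS: dict[str, float] = {"low": 150.0, "high": 10.0}


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry in milliseconds.

    Fast bands (B, BH, G) are conventionally analysed with 250/125 ms,
    slow bands (T, A) with 300/150 ms; the burst latency equals ``step_ms``.
    """

    window_ms: float
    step_ms: float

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise SpectralError("window_ms and step_ms must be positive")
        if self.step_ms > self.window_ms:
            raise SpectralError(
                f"step_ms ({self.step_ms}) must not exceed window_ms ({self.window_ms})"
            )

    def window_samples(self, fs: float) -> int:
        # Nearest-sample rounding: 300 ms at 256 Hz is 76.8 samples -> 77.
        return round(self.window_ms * fs / 1000.0)

    def step_samples(self, fs: float) -> int:
        return round(self.step_ms * fs / 1000.0)


@dataclass
class RawEEG:
    """Multichannel raw EEG: ``samples`` is (n_electrodes, n_samples) in µV."""

    fs: float
    electrodes: list[str]
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise SpectralError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.electrodes):
            raise SpectralError(
                f"samples must be (n_electrodes, n_samples); got shape "
                f"{self.samples.shape} for {len(self.electrodes)} electrodes"
            )
        if len(set(self.electrodes)) != len(self.electrodes):
            raise SpectralError("electrode names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class BandPowerSeries:
    """Per-window, per-(electrode, band) power density stream.

    ``entries`` maps ``(electrode, band_code)`` to a 1-D array of power
    densities (µV²/Hz), one per analysis window; ``window_end_ms`` holds
    the common window-end timestamps.
    """

    window_cfg: WindowConfig
    entries: dict[tuple[str, str], np.ndarray]
    window_end_ms: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.window_end_ms)
        for key, vals in self.entries.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals) != n:
                raise SpectralError(f"series {key} has {len(vals)} windows, expected {n}")
            if np.any(vals < 0):
                raise SpectralError(f"series {key} contains negative power")
            self.entries[key] = vals

    @property
    def n_windows(self) -> int:
        return len(self.window_end_ms)


_VARIABLE_RE = re.compile(
    r"^(?P<electrode>[A-Za-z]+[0-9]*)_(?P<band>[A-Z]+)_(?P<feature>ERS[12]?)_(?P<window>[0-9]+)$"
)


@dataclass(frozen=True)
class VariableId:
    """One linguistic-variable axis: ``{electrode}_{band}_{feature}_{window_ms}``.

    ``feature`` is ``ERS`` (raw band power), ``ERS1`` (first difference) or
    ``ERS2`` (second difference, the burst feature).  ``P8_T_ERS2_300`` reads:
    theta-band burst feature over the right-parietal electrode P8, computed
    on 300 ms windows (150 ms step, hence 150 ms burst latency).
    """

    electrode: str
    band: str
    feature: str
    window_ms: int

    def __post_init__(self) -> None:
        if self.feature not in ("ERS", "ERS1", "ERS2"):
            raise SpectralError(f"unknown feature {self.feature!r}")

    def __str__(self) -> str:
        return f"{self.electrode}_{self.band}_{self.feature}_{self.window_ms}"

    @classmethod
    def parse(cls, text: str) -> "VariableId":
        m = _VARIABLE_RE.match(text)
        if m is None:
            raise SpectralError(
                f"malformed variable id {text!r}; expected "
                "'{electrode}_{band}_{feature}_{window_ms}' like 'P8_T_ERS2_300'"
            )
        return cls(m["electrode"], m["band"], m["feature"], int(m["window"]))


@dataclass
class BurstFeatureSeries:
    """ERS/ERS′/ERS″ values per window, keyed by variable id string."""

    window_cfg: WindowConfig
    values: dict[str, np.ndarray] = field(default_factory=dict)
    window_end_ms: dict[str, np.ndarray] = field(default_factory=dict)


def segment_windows(n_samples: int, cfg: WindowConfig, fs: float) -> list[tuple[int, int]]:
    """Half-open sample index ranges of the sliding analysis windows.

    Window length is ``round(window_ms*fs/1000)`` samples, hop
    ``round(step_ms*fs/1000)``; the count is ``floor((n-w)/s) + 1``.
    """
    w = cfg.window_samples(fs)
    s = cfg.step_samples(fs)
    if n_samples < w:
        raise SpectralError(
            f"signal of {n_samples} samples is shorter than one "
            f"{cfg.window_ms} ms window ({w} samples at {fs} Hz); no windows"
        )
    count = (n_samples - w) // s + 1
    return [(k * s, k * s + w) for k in range(count)]


def band_power_window(x: np.ndarray, fs: float, band: BandSpec) -> float:
    """Mean periodogram power density (µV²/Hz) over bins with lo <= f < hi."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise SpectralError(f"window of {len(x)} samples is too short (need >= 8)")
    if band.hi > fs / 2:
        raise SpectralError(
            f"band {band.code} [{band.lo}, {band.hi}) exceeds Nyquist {fs / 2} Hz"
        )
    freqs, pxx = _signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not np.any(mask):
        raise SpectralError(
            f"band {band.code} [{band.lo}, {band.hi}) contains no FFT bin at "
            f"{len(x)} samples / {fs} Hz"
        )
    return float(np.mean(pxx[mask]))


def band_power_series(
    raw: RawEEG,
    bands: tuple[BandSpec, ...] | list[BandSpec] = DEFAULT_BANDS,
    cfg: WindowConfig = WindowConfig(250, 125),
) -> BandPowerSeries:
    """Windowed band power for every (electrode, band) pair.

    ``window_end_ms`` is ``t0 + range_end/fs*1000`` per window.  All
    windows of one electrode are transformed in a single vectorised
    periodogram call.
    """
    ranges = segment_windows(raw.n_samples, cfg, raw.fs)
    w = ranges[0][1] - ranges[0][0]
    starts = np.array([r[0] for r in ranges])
    window_end_ms = raw.t0 + (starts + w) / raw.fs * 1000.0

    for band in bands:
        if band.hi > raw.fs / 2:
            raise SpectralError(
                f"band {band.code} [{band.lo}, {band.hi}) exceeds Nyquist {raw.fs / 2} Hz"
            )

    freqs = np.fft.rfftfreq(w, d=1.0 / raw.fs)
    masks = {b.code: (freqs >= b.lo) & (freqs < b.hi) for b in bands}
    for b in bands:
        if not np.any(masks[b.code]):
            raise SpectralError(f"band {b.code} contains no FFT bin at window length {w}")

    entries: dict[tuple[str, str], np.ndarray] = {}
    idx = starts[:, None] + np.arange(w)[None, :]
    for e_i, electrode in enumerate(raw.electrodes):
        segs = raw.samples[e_i][idx]  # (n_windows, w)
        _, pxx = _signal.periodogram(segs, fs=raw.fs, window="boxcar", detrend=False, axis=-1)
        for b in bands:
            entries[(electrode, b.code)] = np.mean(pxx[:, masks[b.code]], axis=1)
    return BandPowerSeries(window_cfg=cfg, entries=entries, window_end_ms=window_end_ms)


def burst_series(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second finite differences (ERS′, ERS″) of a power series.

    ``ERS1[k] = p[k] - p[k-1]`` (length n-1) and
    ``ERS2[k] = p[k] - 2 p[k-1] + p[k-2]`` (length n-2), in µV²/Hz.
    The burst latency of a peak equals one window step.
    """
    p = np.asarray(p, dtype=float)
    if len(p) < 3:
        raise SpectralError(
            f"power series of length {len(p)} is too short; the second "
            "difference needs at least 3 windows"
        )
    ers1 = np.diff(p)
    ers2 = np.diff(p, n=2)
    return ers1, ers2


def flag_artifact(
    ers2: float,
    band: BandSpec | str,
    thresholds: dict[str, float] = DEFAULT_ARTIFACT_THRESHOLDS,
    band_class: dict[str, str] = BAND_CLASS,
) -> bool:
    """True iff |ERS″| exceeds the artifact threshold for the band's class.

    Slow bands (theta, alpha) use the 'low' threshold (default 150 units),
    fast bands (beta, high beta, gamma) the 'high' one (default 10 units).
    """
    code = band.code if isinstance(band, BandSpec) else band
    if code not in band_class:
        raise SpectralError(f"band {code!r} missing from band-class map {sorted(band_class)}")
    cls = band_class[code]
    if cls not in thresholds:
        raise SpectralError(f"no artifact threshold for band class {cls!r}")
    thr = thresholds[cls]
    if thr <= 0:
        raise SpectralError("artifact thresholds must be positive")
    return abs(ers2) > thr


def workload_score(
    beta: np.ndarray, theta: np.ndarray, alpha: np.ndarray, log_base: float = 10.0
) -> float:
    """Workload/engagement score ``log( sum(beta) / sum(theta + alpha) )``.

    The beta/(theta+alpha) ratio over the electrodes of interest indexes
    cognitive workload, engagement, attention and fatigue.  Base-10
    logarithm by default (score magnitudes comparable across montages).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    if not (len(beta) == len(theta) == len(alpha)) or len(beta) < 1:
        raise SpectralError("beta, theta, alpha need equal electrode counts >= 1")
    denom = float(np.sum(theta) + np.sum(alpha))
    num = float(np.sum(beta))
    if denom <= 0:
        raise SpectralError(f"theta+alpha power sum must be positive, got {denom}")
    if num <= 0:
        raise SpectralError(f"beta power sum must be positive, got {num}")
    return math.log(num / denom, log_base)


def valence_score(alpha_f3: float, beta_f3: float, alpha_f4: float, beta_f4: float) -> float:
    """Frontal alpha/beta asymmetry valence index ``aF4/bF4 - aF3/bF3``.

    Estimates emotional valence by comparing alpha and beta power in the
    left (F3) and right (F4) frontal channels.  Note: a commonly printed
    form of this index repeats the F4 ratio in both terms and is therefore
    identically zero; the corrected right-minus-left contrast is used here.
    """
    if beta_f3 <= 0 or beta_f4 <= 0:
        raise SpectralError("beta power at F3 and F4 must be positive")
    return alpha_f4 / beta_f4 - alpha_f3 / beta_f3


def locate_burst_onset(
    ers2: np.ndarray,
    window_end_ms: np.ndarray,
    cfg: WindowConfig,
    duration_ms: float = 150.0,
) -> float:
    """Estimate a burst's onset time from its ERS″ trough.

    A short power burst (duration D below the window length W) produces a
    smooth bump in windowed power whose second difference is most
    negative when the *middle* stencil window sits on the bump plateau.
    The plateau is centred ``step - (W - D)/2`` after the onset, so the
    onset estimate inverts that stencil offset from the start of the
    most-negative ERS″ window.  Unbiased for an isolated burst of the
    stated duration; resolution is one window step.
    """
    ers2 = np.asarray(ers2, dtype=float)
    if len(ers2) != len(window_end_ms):
        raise SpectralError("ers2 and window_end_ms lengths differ")
    k = int(np.argmin(ers2))
    start = float(window_end_ms[k]) - cfg.window_ms
    return start - cfg.step_ms + (cfg.window_ms - duration_ms) / 2.0


def burst_features(
    bps: BandPowerSeries,
    features: tuple[str, ...] = ("ERS2",),
) -> BurstFeatureSeries:
    """Derive ERS/ERS′/ERS″ series from a band-power stream.

    Differenced series are aligned to the *latest* window of their stencil,
    so an ERS2 series is two windows shorter than the power series and its
    timestamps start at the third window end.
    """
    out = BurstFeatureSeries(window_cfg=bps.window_cfg)
    w_ms = int(round(bps.window_cfg.window_ms))
    for (electrode, band), p in bps.entries.items():
        ers1, ers2 = burst_series(p) if len(p) >= 3 else (np.diff(p), None)
        for feat in features:
            vid = str(VariableId(electrode, band, feat, w_ms))
            if feat == "ERS":
                out.values[vid] = p.copy()
                out.window_end_ms[vid] = bps.window_end_ms.copy()
            elif feat == "ERS1":
                out.values[vid] = ers1
                out.window_end_ms[vid] = bps.window_end_ms[1:].copy()
            else:
                if ers2 is None:
                    raise SpectralError("series too short for ERS2 (need >= 3 windows)")
                out.values[vid] = ers2
                out.window_end_ms[vid] = bps.window_end_ms[2:].copy()
    return out
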