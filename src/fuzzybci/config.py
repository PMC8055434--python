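"""Run configuration: montage, band table, dual window conventions,
artifact thresholds, file paths.

Fast-band rhythms (beta, high beta, gamma) are accessed every 125 ms on
250 ms windows; slow-band rhythms (theta, alpha) every 150 ms on 300 ms
windows — so the burst latency of a variable follows its band class.
The window length is part of every variable id, which is what keeps the
two conventions unambiguous inside one rule base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .spectral import (
    BAND_CLASS,
    DEFAULT_ARTIFACT_THRESHOLDS,
    DEFAULT_BANDS,
    BandSpec,
    WindowConfig,
)

__all__ = ["RunConfig", "load_run_config", "FAST_WINDOW", "SLOW_WINDOW"]

FAST_WINDOW = WindowConfig(250, 125)
SLOW_WINDOW = WindowConfig(300, 150)

#: Band class -> window convention.
WINDOW_BY_CLASS: dict[str, WindowConfig] = {"high": FAST_WINDOW, "low": SLOW_WINDOW}


@dataclass
class RunConfig:
    """Everything a scripted run needs, loadable from YAML."""

    montage: tuple[str, ...] = ()
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    window_fast: WindowConfig = FAST_WINDOW
    window_slow: WindowConfig = SLOW_WINDOW
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_THRESHOLDS)
    )
    band_class: dict[str, str] = field(default_factory=lambda: dict(BAND_CLASS))
    paths: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    log_level: str = "INFO"

    def window_for_band(self, band_code: str) -> WindowConfig:
        cls = self.band_class.get(band_code, "high")
        return self.window_fast if cls == "high" else self.window_slow


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a RunConfig YAML document; referenced paths must exist."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    kwargs: dict = {}
    if "montage" in doc:
        kwargs["montage"] = tuple(doc["montage"])
    if "bands" in doc:
        kwargs["bands"] = tuple(
            BandSpec(b["code"], float(b["lo"]), float(b["hi"])) for b in doc["bands"]
        )
    for key, cls_key in (("window_fast", "window_fast"), ("window_slow", "window_slow")):
        if key in doc:
            kwargs[cls_key] = WindowConfig(
                float(doc[key]["window_ms"]), float(doc[key]["step_ms"])
            )
    for key in ("thresholds", "band_class", "paths"):
        if key in doc:
            kwargs[key] = dict(doc[key])
    for key in ("seed", "log_level"):
        if key in doc:
            kwargs[key] = doc[key]
    cfg = RunConfig(**kwargs)
    for name, p in cfg.paths.items():
        resolved = (path.parent / p).resolve() if not Path(p).is_absolute() else Path(p)
        if not resolved.exists():
            raise FileNotFoundError(f"run config path {name!r} -> {resolved} does not exist")
    return cfg
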