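"""File formats: raw-EEG / band-power / feature / label CSV and the
membership, rule-base, and model JSON documents.

All CSVs are plain text with a header row; malformed rows are rejected
with their 1-based file line number.  JSON documents round-trip
bit-exactly (floats are serialized with full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import BaselineStats, CoefficientSet
from .membership import LinguisticVariable, TrapezoidMF
from .rgrc import GaussianGranule
from .spectral import (
    BandPowerSeries,
    BurstFeatureSeries,
    RawEEG,
    VariableId,
    WindowConfig,
)

__all__ = [
    "SchemaError",
    "write_raw_csv",
    "read_raw_csv",
    "write_band_power_csv",
    "read_band_power_csv",
    "write_feature_csv",
    "read_feature_csv",
    "write_labels_csv",
    "read_labels_csv",
    "save_membership",
    "load_membership",
    "membership_variables",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """A file does not conform to its schema (bad/missing columns or rows)."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        # +2: one for the header row, one for 0- vs 1-based indexing
        lines = [int(i) + 2 for i in bad[:5]]
        raise SchemaError(f"{path}: non-numeric {col!r} values at line(s) {lines}")
    if vals.isna().any():
        lines = [int(i) + 2 for i in df.index[vals.isna()][:5]]
        raise SchemaError(f"{path}: empty {col!r} values at line(s) {lines}")
    return vals


# --- raw EEG ---------------------------------------------------------------

def write_raw_csv(raw: RawEEG, path: str | Path, sidecar: str | Path | None = None) -> None:
    """``time_ms,<electrode>,...`` plus a YAML sidecar carrying fs and montage."""
    path = Path(path)
    t_ms = raw.t0 + np.arange(raw.n_samples) / raw.fs * 1000.0
    df = pd.DataFrame({"time_ms": t_ms})
    for i, el in enumerate(raw.electrodes):
        df[el] = raw.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    sidecar.write_text(
        yaml.safe_dump({"fs": raw.fs, "t0": raw.t0, "electrodes": list(raw.electrodes)})
    )


def read_raw_csv(path: str | Path, sidecar: str | Path | None = None) -> RawEEG:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    if not sidecar.exists():
        raise SchemaError(f"metadata sidecar {sidecar} not found")
    meta = yaml.safe_load(sidecar.read_text())
    df = pd.read_csv(path)
    _require_columns(df, ["time_ms"] + list(meta["electrodes"]), path)
    samples = np.vstack([_numeric(df, el, path).to_numpy() for el in meta["electrodes"]])
    return RawEEG(
        fs=float(meta["fs"]),
        electrodes=list(meta["electrodes"]),
        samples=samples,
        t0=float(meta.get("t0", 0.0)),
    )


# --- band power ------------------------------------------------------------

def write_band_power_csv(bps: BandPowerSeries, path: str | Path) -> None:
    """Long format ``window_end_ms,electrode,band,power``."""
    rows = []
    for (el, band), vals in bps.entries.items():
        for t, p in zip(bps.window_end_ms, vals):
            rows.append((t, el, band, p))
    pd.DataFrame(rows, columns=["window_end_ms", "electrode", "band", "power"]).to_csv(
        path, index=False
    )


def read_band_power_csv(path: str | Path, window_cfg: WindowConfig) -> BandPowerSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["window_end_ms", "electrode", "band", "power"], path)
    _numeric(df, "window_end_ms", path)
    power = _numeric(df, "power", path)
    if (power < 0).any():
        lines = [int(i) + 2 for i in df.index[power < 0][:5]]
        raise SchemaError(f"{path}: negative power at line(s) {lines}")
    entries = {}
    window_end = None
    for (el, band), grp in df.groupby(["electrode", "band"], sort=True):
        grp = grp.sort_values("window_end_ms")
        entries[(el, band)] = grp["power"].to_numpy(dtype=float)
        if window_end is None:
            window_end = grp["window_end_ms"].to_numpy(dtype=float)
    return BandPowerSeries(window_cfg=window_cfg, entries=entries, window_end_ms=window_end)


# --- burst features --------------------------------------------------------

def write_feature_csv(feats: BurstFeatureSeries, path: str | Path) -> None:
    """Long format ``window_end_ms,variable,value`` with ids like P8_T_ERS2_300."""
    rows = []
    for var in sorted(feats.values):
        for t, v in zip(feats.window_end_ms[var], feats.values[var]):
            rows.append((t, var, v))
    pd.DataFrame(rows, columns=["window_end_ms", "variable", "value"]).to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> BurstFeatureSeries:
    """Rebuild a feature stream; the step is inferred from the timestamps."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["window_end_ms", "variable", "value"], path)
    _numeric(df, "window_end_ms", path)
    _numeric(df, "value", path)
    values: dict[str, np.ndarray] = {}
    times: dict[str, np.ndarray] = {}
    window_ms = None
    step_ms = None
    for var, grp in df.groupby("variable", sort=True):
        vid = VariableId.parse(str(var))  # rejects malformed ids
        grp = grp.sort_values("window_end_ms")
        if var in values:
            raise SchemaError(f"{path}: duplicate variable id {var}")
        values[var] = grp["value"].to_numpy(dtype=float)
        times[var] = grp["window_end_ms"].to_numpy(dtype=float)
        if window_ms is None:
            window_ms = vid.window_ms
            diffs = np.diff(times[var])
            step_ms = float(np.median(diffs)) if len(diffs) else float(vid.window_ms)
    cfg = WindowConfig(window_ms=float(window_ms), step_ms=min(step_ms, float(window_ms)))
    return BurstFeatureSeries(window_cfg=cfg, values=values, window_end_ms=times)


# --- condition labels ------------------------------------------------------

def write_labels_csv(intervals: pd.DataFrame, path: str | Path) -> None:
    _check_intervals(intervals, path)
    intervals.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["start_ms", "end_ms", "label"], path)
    _numeric(df, "start_ms", path)
    _numeric(df, "end_ms", path)
    _check_intervals(df, path)
    return df


def _check_intervals(df: pd.DataFrame, path) -> None:
    _require_columns(df, ["start_ms", "end_ms", "label"], path)
    if (df["end_ms"] <= df["start_ms"]).any():
        raise SchemaError(f"{path}: label intervals must have end_ms > start_ms")
    s = df.sort_values("start_ms")
    overlap = s["start_ms"].to_numpy()[1:] < s["end_ms"].to_numpy()[:-1]
    if overlap.any():
        raise SchemaError(f"{path}: overlapping label intervals")


# --- membership JSON -------------------------------------------------------

def save_membership(
    table: dict[str, dict],
    path: str | Path,
) -> None:
    """Per-variable calibration document.

    Each entry holds the baseline stats (m, std, n), the coefficients
    (c1-c3), the built sets, and the artifact threshold::

        {"<variable>": {"m":..., "std":..., "n":..., "c1":..., "c2":...,
                        "c3":..., "artifact_threshold":...,
                        "sets": {"ref": [a,b,c,d], ...}}}
    """
    doc = {}
    for var, entry in table.items():
        VariableId.parse(var)
        doc[var] = {
            "m": entry["stats"].m,
            "std": entry["stats"].std,
            "n": entry["stats"].n,
            "c1": entry["coeffs"].c1,
            "c2": entry["coeffs"].c2,
            "c3": entry["coeffs"].c3,
            "artifact_threshold": entry.get("artifact_threshold"),
            "sets": {name: mf.as_list() for name, mf in entry["sets"].items()},
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_membership(path: str | Path) -> dict[str, dict]:
    doc = json.loads(Path(path).read_text())
    table = {}
    for var, e in doc.items():
        table[var] = {
            "stats": BaselineStats(m=e["m"], std=e["std"], n=e["n"]),
            "coeffs": CoefficientSet(e["c1"], e["c2"], e["c3"]),
            "artifact_threshold": e.get("artifact_threshold"),
            "sets": {name: TrapezoidMF(*mf) for name, mf in e["sets"].items()},
        }
    return table


def membership_variables(table: dict[str, dict]) -> dict[str, LinguisticVariable]:
    """Linguistic-variable table from a loaded membership document."""
    return {
        var: LinguisticVariable(
            id=VariableId.parse(var),
            sets=dict(entry["sets"]),
            artifact_threshold=entry.get("artifact_threshold"),
        )
        for var, entry in table.items()
    }


# --- trained RGRC model JSON ----------------------------------------------

def save_model(granules: list[GaussianGranule], path: str | Path) -> None:
    doc = [
        {
            "label": g.label,
            "peak": g.peak.tolist(),
            "sigma_left": g.sigma_left.tolist(),
            "sigma_right": g.sigma_right.tolist(),
            "support": g.support,
            "error": g.error,
        }
        for g in granules
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> list[GaussianGranule]:
    doc = json.loads(Path(path).read_text())
    return [
        GaussianGranule(
            label=int(g["label"]),
            peak=np.array(g["peak"]),
            sigma_left=np.array(g["sigma_left"]),
            sigma_right=np.array(g["sigma_right"]),
            support=int(g.get("support", 0)),
            error=int(g.get("error", 0)),
        )
        for g in doc
    ]
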