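"""On-disk formats: CSV recordings with JSON sidecars, fiducial /
parameter / result tables.

A recording is a CSV with columns ``time_s, ecg, ppg_r, ppg_ir, fcg``
plus a JSON sidecar (same path, ``.json`` suffix) holding ``fs_hz``,
``channels``, ``units``, ``seed`` and the resolved config.  Samples are
written with 17 significant digits so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fiducials import FiducialSet
from .recording import MultimodalRecording

__all__ = [
    "config_hash",
    "write_recording",
    "read_recording",
    "write_fiducials",
    "read_fiducials",
    "write_morph_params",
    "read_morph_params",
]

_FLOAT_FMT = "%.17g"


def config_hash(config: dict) -> str:
    """Short stable hash of a resolved configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(recording: MultimodalRecording, path: str | Path) -> Path:
    """Write CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = recording.data.copy()
    df.insert(0, "time_s", recording.time)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = dict(recording.meta)
    sidecar = {
        "fs_hz": recording.fs,
        "channels": recording.channels,
        "units": meta.pop("units", "a.u."),
        "seed": meta.pop("seed", None),
        "config": meta.pop("config", None),
        "meta": meta,
    }
    sidecar["config_hash"] = config_hash(sidecar.get("config") or {})
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_recording(path: str | Path) -> MultimodalRecording:
    """Read a CSV + sidecar recording, validating shape and sampling rate."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        bad = int(df.index[df.isna().any(axis=1)][0])
        raise ValueError(f"NaN gap in recording; first offending row: {bad}")
    if "time_s" not in df.columns:
        raise ValueError("recording CSV must have a time_s column")
    fs = float(sidecar["fs_hz"])
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        fs_implied = (len(t) - 1) / (t[-1] - t[0])
        if abs(fs_implied - fs) / fs > 1e-6:
            raise ValueError(
                f"timestamps imply fs={fs_implied:.6f} Hz, sidecar says {fs} Hz"
            )
    data = df.drop(columns=["time_s"])
    meta = dict(sidecar.get("meta") or {})
    for key in ("seed", "config", "units"):
        if sidecar.get(key) is not None:
            meta[key] = sidecar[key]
    return MultimodalRecording(data, fs, meta)


_FID_FIELDS = {
    "foot": ("foot_t", "foot_a"),
    "sys_peak": ("sys_peak_t", "sys_peak_a"),
    "notch": ("notch_t", "notch_a"),
    "dia_peak": ("dia_peak_t", "dia_peak_a"),
}


def write_fiducials(
    fiducials: dict[str, list[FiducialSet]], path: str | Path
) -> Path:
    """Long-format CSV: beat_index, channel, marker, time_s, amplitude, quality_flag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for channel, fsets in fiducials.items():
        for f in fsets:
            for marker, (t_field, a_field) in _FID_FIELDS.items():
                rows.append(
                    {
                        "beat_index": f.beat_index,
                        "channel": channel,
                        "marker": marker,
                        "time_s": getattr(f, t_field),
                        "amplitude": getattr(f, a_field),
                        "quality_flag": f.quality_flag,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_fiducials(path: str | Path) -> dict[str, list[FiducialSet]]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, list[FiducialSet]] = {}
    for (channel, beat), grp in df.groupby(["channel", "beat_index"], sort=True):
        kwargs = {"beat_index": int(beat), "quality_flag": grp["quality_flag"].iloc[0]}
        for _, row in grp.iterrows():
            t_field, a_field = _FID_FIELDS[row["marker"]]
            kwargs[t_field] = row["time_s"]
            kwargs[a_field] = row["amplitude"]
        out.setdefault(channel, []).append(FiducialSet(**kwargs))
    for fsets in out.values():
        fsets.sort(key=lambda f: f.beat_index)
    return out


_MS_COLUMNS = {"t_up": "t_up_ms", "t_i": "t_i_ms", "T": "T_ms"}


def write_morph_params(params: pd.DataFrame, path: str | Path) -> Path:
    """Per-beat parameter CSV with time columns in milliseconds."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = params.copy()
    for sec, ms in _MS_COLUMNS.items():
        df[ms] = df.pop(sec) * 1000.0
    cols = ["beat_index", "channel", "t_up_ms", "t_i_ms", "T_ms", "t_up_over_T",
            "h1", "h2", "h3", "h2_over_h1", "h3_over_h1"]
    df[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_morph_params(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for sec, ms in _MS_COLUMNS.items():
        df[sec] = df.pop(ms) / 1000.0
    from .morphology import MORPH_COLUMNS

    return df[MORPH_COLUMNS]
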