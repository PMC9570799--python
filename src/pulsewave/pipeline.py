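"""End-to-end orchestration: simulate-or-load -> preprocess -> fiducials
-> morphology (parameters, PAT, delays) -> cross-correlation -> agreement.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pwio
from .agreement import agreement_table, compare_parameters
from .fiducials import detect_pw_fiducials, detect_r_peaks, segment_beats
from .morphology import compute_morph_params, compute_pat, marker_delays, summarize
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import PPG_CHANNELS, PW_CHANNELS, MultimodalRecording
from .similarity import beat_ncc, derivative, whole_ncc
from .synthgen import SynthConfig, generate_recording

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Exactly one of ``synth`` (simulate) or ``input_path`` (load) must be
    set.  The resolved config (and its hash) is written beside the
    outputs when ``out_dir`` is given.
    """

    synth: SynthConfig | None = None
    input_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    window_frac: float = 0.95
    notch_window_frac: float = 0.5
    max_match_gap: float = 0.4
    whole_max_lag: float = 0.5
    derivative_orders: tuple[int, ...] = (0, 1, 2)
    seed: int = 0
    out_dir: str | None = None

    _KNOWN = None  # set below

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("synth"), dict):
            d["synth"] = SynthConfig(**d["synth"])
        if isinstance(d.get("preprocess"), dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "derivative_orders" in d:
            d["derivative_orders"] = tuple(d["derivative_orders"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "synth": self.synth.to_dict() if self.synth else None,
            "input_path": self.input_path,
            "preprocess": self.preprocess.to_dict(),
            "window_frac": self.window_frac,
            "notch_window_frac": self.notch_window_frac,
            "max_match_gap": self.max_match_gap,
            "whole_max_lag": self.whole_max_lag,
            "derivative_orders": list(self.derivative_orders),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a results bundle.

    Bundle keys: recording (preprocessed), truth (simulated runs only),
    r_peaks, fiducials, params, pat, delays, ncc (DataFrame), agreement,
    agreement_tables, config_hash.  Deterministic given the seed.
    """
    if (config.synth is None) == (config.input_path is None):
        raise ValueError("exactly one of synth / input_path must be set")

    truth = None
    if config.synth is not None:
        synth = dataclasses.replace(config.synth, seed=config.seed)
        raw, truth = _stage("simulate")(generate_recording)(synth)
    else:
        raw = _stage("load")(pwio.read_recording)(config.input_path)

    rec = _stage("preprocess")(preprocess_recording)(raw, config.preprocess)
    fs = rec.fs

    r_peaks = _stage("r_peaks")(detect_r_peaks)(rec["ecg"], fs)
    fiducials = {}
    params = {}
    pat = {}
    for ch in PW_CHANNELS:
        fiducials[ch] = _stage(f"fiducials:{ch}")(detect_pw_fiducials)(
            rec[ch], fs, r_peaks, config.window_frac, config.notch_window_frac
        )
        params[ch] = _stage(f"morphology:{ch}")(compute_morph_params)(
            fiducials[ch], ch
        )
        pat[ch] = _stage(f"pat:{ch}")(compute_pat)(r_peaks, fiducials[ch], ch)

    delays = {
        ch: _stage(f"delays:fcg->{ch}")(marker_delays)(
            fiducials["fcg"], fiducials[ch], config.max_match_gap, ("fcg", ch)
        )
        for ch in PPG_CHANNELS
    }

    ncc_rows = []
    for ch in PPG_CHANNELS:
        for order in config.derivative_orders:
            sig = {}
            for c in ("fcg", ch):
                sig[c] = rec[c] if order == 0 else derivative(rec[c], fs, order)
            w = whole_ncc(sig["fcg"], sig[ch], fs, config.whole_max_lag, order)
            ncc_rows.append(
                {
                    "pair": f"fcg:{ch}",
                    "scope": "whole",
                    "derivative_order": order,
                    "beat_index": np.nan,
                    "ncc": w.ncc,
                    "lag_ms": w.lag * 1000.0,
                }
            )
            beats_f = segment_beats(sig["fcg"], fs, fiducials["fcg"])
            beats_p = segment_beats(sig[ch], fs, fiducials[ch])
            for r in beat_ncc(beats_f, beats_p, fs, derivative_order=order):
                ncc_rows.append(
                    {
                        "pair": f"fcg:{ch}",
                        "scope": "beat",
                        "derivative_order": order,
                        "beat_index": r.beat_index,
                        "ncc": r.ncc,
                        "lag_ms": r.lag * 1000.0,
                    }
                )
    ncc = pd.DataFrame(ncc_rows)

    agreement = {
        ch: _stage(f"agreement:fcg-vs-{ch}")(compare_parameters)(
            params["fcg"], params[ch]
        )
        for ch in PPG_CHANNELS
    }

    resolved = config.to_dict()
    chash = pwio.config_hash(resolved)
    bundle = {
        "recording": rec,
        "truth": truth,
        "r_peaks": r_peaks,
        "fiducials": fiducials,
        "params": params,
        "pat": pat,
        "delays": delays,
        "ncc": ncc,
        "agreement": agreement,
        "agreement_tables": {ch: agreement_table(res) for ch, res in agreement.items()},
        "config_hash": chash,
    }

    if config.out_dir:
        _write_bundle(bundle, resolved, chash, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: dict, resolved: dict, chash: str, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps({"config_hash": chash, **resolved}, indent=1, default=str)
    )
    rec = bundle["recording"]
    rec.meta["config_hash"] = chash
    pwio.write_recording(rec, out / "recording_pp.csv")
    pwio.write_fiducials(bundle["fiducials"], out / "fiducials.csv")
    pd.DataFrame({"r_peak_s": bundle["r_peaks"]}).to_csv(
        out / "r_peaks.csv", index=False
    )
    pwio.write_morph_params(
        pd.concat(bundle["params"].values(), ignore_index=True),
        out / "morph_params.csv",
    )
    delay_rows = []
    for ch, table in bundle["delays"].items():
        s = table.summary()
        s.insert(0, "pair", f"fcg:{ch}")
        delay_rows.append(s)
    pd.concat(delay_rows, ignore_index=True).assign(
        mean_ms=lambda d: d["mean"] * 1000.0, sd_ms=lambda d: d["sd"] * 1000.0
    ).to_csv(out / "marker_delays.csv", index=False)
    bundle["ncc"].to_csv(out / "ncc.csv", index=False, float_format="%.17g")
    summary = {}
    for ch, pseries in bundle["pat"].items():
        mean, sd, n = summarize(pseries.pat)
        summary[f"pat_{ch}_ms"] = {"mean": mean * 1000, "sd": sd * 1000, "n": n}
    (out / "pat_summary.json").write_text(
        json.dumps({"config_hash": chash, **summary}, indent=1)
    )
    for ch, table in bundle["agreement_tables"].items():
        table.to_csv(out / f"agreement_fcg_vs_{ch}.csv")
    if bundle["truth"] is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(bundle["truth"].to_dict(), default=str)
        )
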