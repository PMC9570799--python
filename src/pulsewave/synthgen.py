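"""Synthetic multimodal ECG + PPG + FCG recordings with exact ground truth.

The subject recordings behind the published finger pulse-wave comparisons
are not publicly deposited, so this module generates stand-in recordings
whose fiducial geometry is known exactly: each pulse beat is a piecewise
cubic through its five fiducial anchors (foot, systolic peak, dicrotic
notch, diastolic peak, next foot) with zero slope at every anchor, so the
waveform's local extrema sit exactly on the anchors by construction.

Channel model
-------------
* ``ecg``: a PQRST-like Gaussian-lobe template train; the narrow R lobe
  (20 ms FWHM) dominates so that QRS detection behaves as on real data.
* ``ppg_r``, ``ppg_ir``, ``fcg``: the beat-template train, each delayed
  after the ECG R-peak by its channel's pulse arrival time (PAT, R-peak
  to systolic peak), multiplied by a respiratory amplitude modulation,
  plus an additive respiratory baseline oscillation and white noise.
* The optical channels are emitted with *inverted* polarity (raw light
  intensity: a pulse is a downward deflection), so the preprocessing
  reversal step is exercised; mechanical FCG is emitted pulse-positive.

Defaults follow the published acquisition: 200 Hz sampling, a constant
mechanical-before-optical delay of ~165 ms (PAT 483/485 ms optical vs
315 ms piezoelectric), and sub-millisecond channel skew (0 by default,
bounded at 0.5 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Union

import numpy as np
import pandas as pd
from scipy.interpolate import BPoly

from .recording import CHANNELS, PPG_CHANNELS, PW_CHANNELS, MultimodalRecording
from .fiducials import FiducialSet

__all__ = [
    "BeatMorphology",
    "SynthConfig",
    "GroundTruth",
    "beat_template",
    "generate_recording",
    "SUBJECT1_PPG_R_MORPHOLOGY",
]

#: Time offset of the first ECG R-peak from record start (lead-in), seconds.
R_LEAD_IN = 0.2


@dataclass(frozen=True)
class BeatMorphology:
    """Fiducial geometry of one pulse beat, relative to its foot.

    Times are seconds from the foot; heights are amplitudes above the
    foot, in arbitrary units.  Required ordering: 0 < t_up < t_i < t_dia
    < T and 0 < h2 < h3 <= h1 (the dicrotic notch is a local minimum
    between the systolic and diastolic peaks).
    """

    t_up: float  # foot -> systolic peak
    t_i: float  # foot -> dicrotic notch
    t_dia: float  # foot -> diastolic peak
    T: float  # foot -> next foot
    h1: float = 1.0  # systolic peak height
    h2: float = 0.4  # notch height
    h3: float = 0.6  # diastolic peak height

    def __post_init__(self) -> None:
        pairs = [
            ("0", 0.0, "t_up", self.t_up),
            ("t_up", self.t_up, "t_i", self.t_i),
            ("t_i", self.t_i, "t_dia", self.t_dia),
            ("t_dia", self.t_dia, "T", self.T),
        ]
        for lo_name, lo, hi_name, hi in pairs:
            if not lo < hi:
                raise ValueError(
                    f"anchor ordering violated: {lo_name} ({lo}) must precede "
                    f"{hi_name} ({hi})"
                )
        hpairs = [("0", 0.0, "h2", self.h2), ("h2", self.h2, "h3", self.h3)]
        for lo_name, lo, hi_name, hi in hpairs:
            if not lo < hi:
                raise ValueError(
                    f"height ordering violated: {lo_name} ({lo}) must be below "
                    f"{hi_name} ({hi})"
                )
        if self.h3 > self.h1:
            raise ValueError(
                f"height ordering violated: h3 ({self.h3}) must not exceed "
                f"h1 ({self.h1})"
            )


#: Morphology matching a typical young adult's red-light finger pulse
#: (systolic upstroke 136 ms, notch 366 ms, period 965 ms, notch and
#: diastolic heights 0.393 and 0.600 of the systolic peak).  The
#: diastolic-peak time, which published summary tables do not report,
#: is fixed at 450 ms.
SUBJECT1_PPG_R_MORPHOLOGY = BeatMorphology(
    t_up=0.136, t_i=0.366, t_dia=0.450, T=0.965, h1=1.0, h2=0.393, h3=0.600
)

MorphologySpec = Union[BeatMorphology, Mapping[str, BeatMorphology]]


@dataclass
class SynthConfig:
    """Full ground-truth parameterization of a simulated recording.

    ``pat_*`` are pulse arrival times: the delay from each ECG R-peak to
    the channel's systolic peak (the published PAT definition).  The
    mechanical channel must precede the optical ones (pat_fcg < pat_ppg_*).
    ``seed`` fully determines the output.

    The published recordings' respiratory modulation depth and noise
    level are not reported; ``baseline_amp``, ``am_depth`` and
    ``noise_sd`` defaults are plausible resting-finger placeholders (see
    docs/methods.md), expressed relative to a unit systolic height.
    """

    n_beats: int
    fs_out: float = 200.0
    mean_rr: float = 0.965
    rr_sd: float = 0.0
    morphology: MorphologySpec = SUBJECT1_PPG_R_MORPHOLOGY
    pat_ppg_r: float = 0.483
    pat_ppg_ir: float = 0.485
    pat_fcg: float = 0.315
    pat_sd: float = 0.0
    baseline_amp: float = 0.1
    baseline_freq: float = 0.25
    am_depth: float = 0.1
    noise_sd: float = 0.01
    channel_skew: float = 0.0
    h3_jitter_frac: Union[float, Mapping[str, float]] = 0.0
    ecg_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats <= 0:
            raise ValueError(f"n_beats must be positive, got {self.n_beats}")
        if not 0 <= self.am_depth < 1:
            raise ValueError(f"am_depth must lie in [0, 1), got {self.am_depth}")
        for name in ("fs_out", "mean_rr", "pat_ppg_r", "pat_ppg_ir", "pat_fcg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rr_sd", "pat_sd", "noise_sd", "baseline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.pat_fcg < self.pat_ppg_r and self.pat_fcg < self.pat_ppg_ir):
            raise ValueError(
                "mechanical pulse must precede optical: require "
                f"pat_fcg ({self.pat_fcg}) < pat_ppg_r ({self.pat_ppg_r}) "
                f"and < pat_ppg_ir ({self.pat_ppg_ir})"
            )
        if not 0 <= self.channel_skew <= 0.0005:
            raise ValueError(
                f"channel_skew must lie in [0, 0.5 ms], got {self.channel_skew}"
            )

    def morphology_for(self, channel: str) -> BeatMorphology:
        if isinstance(self.morphology, BeatMorphology):
            return self.morphology
        return self.morphology[channel]

    def pat_for(self, channel: str) -> float:
        return {
            "ppg_r": self.pat_ppg_r,
            "ppg_ir": self.pat_ppg_ir,
            "fcg": self.pat_fcg,
        }[channel]

    def h3_jitter_for(self, channel: str) -> float:
        if isinstance(self.h3_jitter_frac, Mapping):
            return float(self.h3_jitter_frac.get(channel, 0.0))
        return float(self.h3_jitter_frac)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.morphology, BeatMorphology):
            d["morphology"] = asdict(self.morphology)
        else:
            d["morphology"] = {k: asdict(v) for k, v in self.morphology.items()}
        if isinstance(self.h3_jitter_frac, Mapping):
            d["h3_jitter_frac"] = dict(self.h3_jitter_frac)
        return d


@dataclass
class GroundTruth:
    """Exact anchor times imposed by the generator (the recovery oracle).

    All times are seconds from record start, *after* every shift the
    generator applies (PAT, per-beat jitter, channel skew).  Amplitudes
    are the pulse-positive template heights including the multiplicative
    respiratory modulation, excluding baseline and noise.  Beats whose
    template does not fit entirely inside the record, or that lack a
    successor foot, carry quality_flag "partial" and are excluded by
    downstream recovery comparisons.
    """

    r_peak_times: np.ndarray
    fiducials: dict[str, list[FiducialSet]]
    pat: dict[str, float]
    delays: dict[str, float]  # imposed optical-minus-mechanical delay per PPG channel
    rr: np.ndarray

    def complete(self, channel: str) -> list[FiducialSet]:
        """Fiducial sets of the beats fully contained in the record."""
        return [f for f in self.fiducials[channel] if f.quality_flag != "partial"]

    def to_dict(self) -> dict:
        return {
            "r_peak_times": self.r_peak_times.tolist(),
            "fiducials": {
                ch: [asdict(f) for f in fsets] for ch, fsets in self.fiducials.items()
            },
            "pat": self.pat,
            "delays": self.delays,
            "rr": self.rr.tolist(),
        }


def _monotone_quintic(
    t0: float, t1: float, h0: float, h1: float, c0: float, c1: float
) -> BPoly:
    """Quintic from (t0,h0) to (t1,h1), zero slope and curvature c0/c1 at
    the ends, with the end curvatures scaled back toward the plain
    zero-slope cubic's until the segment is monotone.

    With end curvatures exactly +-6*dh/dt^2 the quintic degenerates to
    the monotone cubic smoothstep, so the clip always terminates.
    """
    dt, dh = t1 - t0, h1 - h0
    n0 = 6.0 * dh / dt**2  # the cubic's end curvatures
    n1 = -n0
    lam = 1.0
    grid = t0 + (t1 - t0) * np.linspace(0.0, 1.0, 257)
    tol = 1e-12 * max(1.0, abs(dh))
    for _ in range(60):
        bp = BPoly.from_derivatives(
            [t0, t1],
            [[h0, 0.0, n0 + lam * (c0 - n0)], [h1, 0.0, n1 + lam * (c1 - n1)]],
        )
        step = np.diff(bp(grid))
        if np.all(step >= -tol) if dh > 0 else np.all(step <= tol):
            return bp
        lam *= 0.7
    return BPoly.from_derivatives([t0, t1], [[h0, 0.0, n0], [h1, 0.0, n1]])


def _anchor_spline(knots: np.ndarray, heights: np.ndarray):
    """Smooth monotone-safe interpolant through the fiducial anchors.

    Zero slope at every anchor makes the anchors the curve's only local
    extrema, so ground truth is exact by construction.  At each interior
    anchor the curvature is matched from both sides to the *sharper* of
    the two adjoining zero-slope cubics: a curvature kink at an extremum
    shifts the extremum of any band-limited (sampled / low-pass
    filtered) view of the waveform toward the flatter side, whereas a
    locally C2 quadratic extremum stays put, which keeps the
    preprocessing chain fiducially transparent.  Each inter-anchor
    quintic segment is clipped back toward the plain cubic where needed
    to stay monotone, so no spurious extrema appear.
    """
    k = np.asarray(knots, dtype=float)
    h = np.asarray(heights, dtype=float)
    nat = 6.0 * np.diff(h) / np.diff(k) ** 2
    curv = np.empty_like(h)
    for i in range(len(h)):
        sides = []
        if i > 0:
            sides.append(-nat[i - 1])  # curvature at the right end of segment i-1
        if i < len(h) - 1:
            sides.append(nat[i])  # curvature at the left end of segment i
        curv[i] = max(sides, key=abs)
    pieces = [
        _monotone_quintic(k[i], k[i + 1], h[i], h[i + 1], curv[i], curv[i + 1])
        for i in range(len(h) - 1)
    ]
    coeffs = np.concatenate([p.c for p in pieces], axis=1)
    return BPoly(coeffs, k)


def beat_template(morph: BeatMorphology, fs: float) -> np.ndarray:
    """Sample one pulse beat on a grid of rate ``fs``.

    Anchors are snapped to the nearest sample so the returned waveform
    realizes each fiducial value exactly at one sample.  The waveform is
    0 at both feet, has its global maximum ``h1`` at ``t_up``, a local
    minimum ``h2`` at ``t_i`` and a local maximum ``h3`` at ``t_dia``;
    there are no other local extrema.

    Returns an array of ``round(T*fs) + 1`` samples covering [0, T].
    """
    if fs < 100:
        raise ValueError(f"fs must be at least 100 Hz, got {fs}")
    times = np.array([0.0, morph.t_up, morph.t_i, morph.t_dia, morph.T])
    idx = np.round(times * fs).astype(int)
    if np.any(np.diff(idx) <= 0):
        raise ValueError(
            "anchor times collapse onto the same sample at this rate; "
            "increase fs or spread the anchors"
        )
    heights = np.array([0.0, morph.h1, morph.h2, morph.h3, 0.0])
    spline = _anchor_spline(idx / fs, heights)
    t = np.arange(idx[-1] + 1) / fs
    return np.asarray(spline(t))


def _truncated_rr(rng: np.random.Generator, cfg: SynthConfig, t_dia_max: float) -> np.ndarray:
    """Per-beat RR intervals, redrawn until above the floor.

    The floor is max(0.3 s, t_dia + 2 samples): a beat's template cannot
    end before its diastolic anchor.
    """
    floor = max(0.3, t_dia_max + 2.0 / cfg.fs_out)
    if cfg.mean_rr <= floor and cfg.rr_sd == 0:
        raise ValueError(
            f"mean_rr ({cfg.mean_rr}) must exceed the RR floor ({floor:.3f} s)"
        )
    rr = rng.normal(cfg.mean_rr, cfg.rr_sd, cfg.n_beats)
    for _ in range(1000):
        bad = rr <= floor
        if not bad.any():
            return rr
        rr[bad] = rng.normal(cfg.mean_rr, cfg.rr_sd, bad.sum())
    raise ValueError("could not draw RR intervals above the floor")


def _ecg_train(t: np.ndarray, r_times: np.ndarray, amp: float) -> np.ndarray:
    """PQRST-like Gaussian-lobe train.

    Lobes (center offset from R [s], height, sigma [s]): P and T are low
    and wide; Q/R/S are narrow, the R lobe 20 ms FWHM (sigma ~8.5 ms).
    Physiological realism is limited to what QRS detection needs.
    """
    lobes = (
        (-0.16, 0.12, 0.025),  # P
        (-0.026, -0.10, 0.008),  # Q
        (0.0, 1.00, 0.0085),  # R
        (0.026, -0.15, 0.008),  # S
        (0.28, 0.25, 0.050),  # T
    )
    ecg = np.zeros_like(t)
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    for r in r_times:
        lo = max(0, int((r - 0.5) * fs))
        hi = min(len(t), int((r + 0.6) * fs))
        seg = t[lo:hi]
        for off, h, sig in lobes:
            ecg[lo:hi] += h * np.exp(-0.5 * ((seg - (r + off)) / sig) ** 2)
    return amp * ecg


def generate_recording(config: SynthConfig) -> tuple[MultimodalRecording, GroundTruth]:
    """Simulate a four-channel recording and its exact ground truth.

    The record spans the sum of the RR intervals; the first R-peak sits
    0.2 s after record start, so the tail of the last pulse beat is
    truncated and flagged partial.  Identical config (including seed)
    yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs_out
    t_dia_max = max(config.morphology_for(ch).t_dia for ch in PW_CHANNELS)
    rr = _truncated_rr(rng, config, t_dia_max)
    duration = float(rr.sum())
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    r_times = R_LEAD_IN + np.concatenate(([0.0], np.cumsum(rr[:-1])))
    ecg = _ecg_train(t, r_times, config.ecg_amp)

    data: dict[str, np.ndarray] = {"ecg": ecg}
    fiducials: dict[str, list[FiducialSet]] = {}

    for ch in PW_CHANNELS:
        morph = config.morphology_for(ch)
        pat = config.pat_for(ch)
        jitter = (
            rng.normal(0.0, config.pat_sd, config.n_beats)
            if config.pat_sd > 0
            else np.zeros(config.n_beats)
        )
        h3j = config.h3_jitter_for(ch)
        h3_factors = (
            1.0 + rng.uniform(-h3j, h3j, config.n_beats)
            if h3j > 0
            else np.ones(config.n_beats)
        )
        skew = config.channel_skew if ch in PPG_CHANNELS else 0.0

        pulse = np.zeros(n)
        ch_fids: list[FiducialSet] = []
        feet = r_times + pat + jitter - morph.t_up
        for k in range(config.n_beats):
            foot = feet[k]
            T_k = rr[k]
            h3_k = morph.h3 * h3_factors[k]
            knots = foot + np.array([0.0, morph.t_up, morph.t_i, morph.t_dia, T_k])
            heights = np.array([0.0, morph.h1, morph.h2, h3_k, 0.0])
            spline = _anchor_spline(knots, heights)
            lo = max(0, int(math.ceil(foot * fs)))
            hi = min(n, int(math.ceil((foot + T_k) * fs)))
            if hi > lo:
                pulse[lo:hi] += spline(t[lo:hi])

            next_foot = feet[k + 1] if k + 1 < config.n_beats else foot + T_k
            partial = foot < 0 or foot + T_k > duration or k == config.n_beats - 1
            mod = lambda x: 1.0 + config.am_depth * np.sin(
                2 * np.pi * config.baseline_freq * x
            )
            anchors_t = knots[:4] + skew
            ch_fids.append(
                FiducialSet(
                    beat_index=k,
                    foot_t=anchors_t[0],
                    foot_a=0.0,
                    sys_peak_t=anchors_t[1],
                    sys_peak_a=morph.h1 * mod(anchors_t[1]),
                    notch_t=anchors_t[2],
                    notch_a=morph.h2 * mod(anchors_t[2]),
                    dia_peak_t=anchors_t[3],
                    dia_peak_a=h3_k * mod(anchors_t[3]),
                    quality_flag="partial" if partial else "ok",
                )
            )

        pulse *= 1.0 + config.am_depth * np.sin(2 * np.pi * config.baseline_freq * t)
        phase = rng.uniform(0, 2 * np.pi)
        chan = pulse + config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t + phase
        )
        if config.noise_sd > 0:
            chan = chan + rng.normal(0.0, config.noise_sd, n)
        if skew > 0:
            # sub-sample acquisition skew: channel sampled `skew` late
            chan = np.interp(t - skew, t, chan)
        if ch in PPG_CHANNELS:
            chan = -chan  # raw light intensity: pulses point down
        data[ch] = chan
        fiducials[ch] = ch_fids

    rec = MultimodalRecording(
        data=pd.DataFrame(data, columns=list(CHANNELS)),
        fs=fs,
        meta={"seed": config.seed, "config": config.to_dict(), "units": "a.u."},
    )
    truth = GroundTruth(
        r_peak_times=r_times,
        fiducials=fiducials,
        pat={ch: config.pat_for(ch) for ch in PW_CHANNELS},
        delays={ch: config.pat_for(ch) - config.pat_fcg for ch in PPG_CHANNELS},
        rr=rr,
    )
    return rec, truth
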