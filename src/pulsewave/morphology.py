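"""Per-beat morphological parameters, pulse arrival times and
inter-sensor marker delays.

Morphological parameters follow the standard pulse-wave nomenclature:
t_up (foot to systolic peak), t_i (foot to dicrotic notch), T (foot to
next foot), t_up/T, and the heights h1 (systolic peak), h2 (notch),
h3 (diastolic peak) measured above the beat's own foot, with the
dimensionless ratios h2/h1 and h3/h1.  Raw heights from optical and
mechanical sensors measure different physical quantities; only the
time parameters and the height ratios belong to the cross-sensor
comparison set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiducials import FiducialSet

__all__ = [
    "MORPH_COLUMNS",
    "COMPARED_PARAMETERS",
    "MARKERS",
    "PatSeries",
    "DelayTable",
    "compute_morph_params",
    "compute_pat",
    "marker_delays",
    "summarize",
]

logger = logging.getLogger(__name__)

MORPH_COLUMNS = [
    "beat_index",
    "channel",
    "t_up",
    "t_i",
    "T",
    "t_up_over_T",
    "h1",
    "h2",
    "h3",
    "h2_over_h1",
    "h3_over_h1",
]

#: parameters compared across sensors (raw heights are excluded: optical
#: and mechanical amplitudes are different physical quantities)
COMPARED_PARAMETERS = ("t_up", "t_i", "T", "t_up_over_T", "h2_over_h1", "h3_over_h1")

MARKERS = ("foot", "sys_peak", "notch", "dia_peak")


def summarize(values) -> tuple[float, float, int]:
    """Sample mean, sample SD (n-1 denominator) and count."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("cannot summarize an empty sequence")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
    return float(np.mean(v)), sd, int(len(v))


def compute_morph_params(
    fiducial_sets: list[FiducialSet], channel: str = ""
) -> pd.DataFrame:
    """One row of morphological parameters per beat with a successor foot.

    Times are in seconds, heights relative to the beat's own foot
    amplitude.  Beats flagged ``missing_notch`` yield only t_up, T,
    t_up/T and h1 (notch-dependent fields NaN); beats flagged
    ``partial`` are excluded.
    """
    by_beat = [f.foot_t for f in sorted(fiducial_sets, key=lambda f: f.beat_index)
               if np.isfinite(f.foot_t)]
    if np.any(np.diff(by_beat) <= 0):
        raise ValueError("foot times are not strictly increasing")
    fids = [f for f in fiducial_sets if f.quality_flag != "partial"]
    # successor feet come from complete beats only: a partial (edge) beat's
    # foot sits in the filter settling zone and cannot be trusted for T
    all_feet = sorted(
        (f.foot_t, f.beat_index) for f in fids if np.isfinite(f.foot_t)
    )
    next_foot = {bi: t_next for (_, bi), (t_next, _) in zip(all_feet[:-1], all_feet[1:])}

    rows = []
    for f in fids:
        if f.beat_index not in next_foot:
            continue
        T = next_foot[f.beat_index] - f.foot_t
        t_up = f.sys_peak_t - f.foot_t
        h1 = f.sys_peak_a - f.foot_a
        has_notch = np.isfinite(f.notch_t)
        t_i = f.notch_t - f.foot_t if has_notch else np.nan
        h2 = f.notch_a - f.foot_a if has_notch else np.nan
        h3 = f.dia_peak_a - f.foot_a if np.isfinite(f.dia_peak_a) else np.nan
        rows.append(
            {
                "beat_index": f.beat_index,
                "channel": channel,
                "t_up": t_up,
                "t_i": t_i,
                "T": T,
                "t_up_over_T": t_up / T,
                "h1": h1,
                "h2": h2,
                "h3": h3,
                "h2_over_h1": h2 / h1,
                "h3_over_h1": h3 / h1,
            }
        )
    return pd.DataFrame(rows, columns=MORPH_COLUMNS)


@dataclass
class PatSeries:
    """Per-beat pulse arrival times (R-peak to systolic peak), seconds."""

    channel: str
    beat_index: np.ndarray
    pat: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.pat))

    @property
    def sd(self) -> float:
        return summarize(self.pat)[1]

    @property
    def n(self) -> int:
        return len(self.pat)


def compute_pat(
    r_peaks: np.ndarray, fiducial_sets: list[FiducialSet], channel: str = ""
) -> PatSeries:
    """Pulse arrival time of each beat against the latest preceding R-peak.

    Systolic peaks occurring before the first R-peak are dropped (PAT is
    causal); partial beats are excluded.
    """
    r = np.sort(np.asarray(r_peaks, dtype=float))
    if len(r) == 0:
        raise ValueError("r_peaks is empty")
    idx, pats = [], []
    dropped = 0
    for f in fiducial_sets:
        if f.quality_flag == "partial" or not np.isfinite(f.sys_peak_t):
            continue
        j = int(np.searchsorted(r, f.sys_peak_t, side="right")) - 1
        if j < 0:
            dropped += 1
            continue
        idx.append(f.beat_index)
        pats.append(f.sys_peak_t - r[j])
    if dropped:
        logger.info("compute_pat: dropped %d systolic peaks before first R", dropped)
    return PatSeries(channel, np.asarray(idx), np.asarray(pats))


@dataclass
class DelayTable:
    """Beat-matched optical-minus-mechanical marker delays, seconds.

    ``delays`` has one row per matched beat and one column per marker
    (foot, sys_peak, notch, dia_peak), values = PPG marker time − FCG
    marker time.
    """

    channel_pair: tuple[str, str]  # (fcg-like reference, ppg-like)
    delays: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in MARKERS:
            try:
                mean, sd, n = summarize(self.delays[m])
            except ValueError:  # marker absent on every matched beat
                mean, sd, n = float("nan"), float("nan"), 0
            rows.append({"marker": m, "mean": mean, "sd": sd, "n": n})
        return pd.DataFrame(rows)


def _match_feet(
    feet_a: np.ndarray, feet_b: np.ndarray, max_gap: float
) -> list[tuple[int, int]]:
    """Pair each reference foot with its nearest counterpart within max_gap.

    Equidistant candidates resolve to the earlier one; each counterpart
    is used at most once.
    """
    pairs = []
    used = set()
    for i, fa in enumerate(feet_a):
        diffs = np.abs(feet_b - fa)
        order = np.lexsort((feet_b, diffs))  # distance, then earlier time
        for j in order:
            if diffs[j] > max_gap:
                break
            if j not in used:
                used.add(j)
                pairs.append((i, int(j)))
                break
    return pairs


def marker_delays(
    fids_fcg: list[FiducialSet],
    fids_ppg: list[FiducialSet],
    max_match_gap: float = 0.4,
    channel_pair: tuple[str, str] = ("fcg", "ppg"),
) -> DelayTable:
    """Per-marker time delays between matched mechanical/optical beats.

    Beats are matched by pairing each FCG foot with the nearest PPG foot
    within ``max_match_gap`` seconds; delays are PPG time − FCG time.
    """
    a = [f for f in fids_fcg if f.quality_flag != "partial"]
    b = [f for f in fids_ppg if f.quality_flag != "partial"]
    if not a or not b:
        raise ValueError("no complete beats to match")
    feet_a = np.array([f.foot_t for f in a])
    feet_b = np.array([f.foot_t for f in b])
    pairs = _match_feet(feet_a, feet_b, max_match_gap)
    if not pairs:
        raise ValueError("zero matched beats within the matching gap")
    rows = []
    for i, j in pairs:
        fa, fb = a[i], b[j]
        rows.append(
            {
                "beat_index": fa.beat_index,
                "foot": fb.foot_t - fa.foot_t,
                "sys_peak": fb.sys_peak_t - fa.sys_peak_t,
                "notch": fb.notch_t - fa.notch_t,
                "dia_peak": fb.dia_peak_t - fa.dia_peak_t,
            }
        )
    return DelayTable(channel_pair, pd.DataFrame(rows))
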