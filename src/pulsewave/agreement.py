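"""Regression, correlation and Bland–Altman agreement statistics.

Cross-sensor comparisons regress the mechanical (FCG) parameter on the
optical (PPG) one and assess agreement via the Bland–Altman bias and
limits of agreement.  Differences are signed mechanical − optical
(piezo − PPG) throughout, so a negative bias means the piezoelectric
sensor reads lower.  Bias significance uses a two-sided one-sample
t-test of the differences against zero at alpha = 0.05; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphology import COMPARED_PARAMETERS

__all__ = [
    "AgreementResult",
    "linreg",
    "bland_altman",
    "compare_parameters",
    "pool_subjects",
    "agreement_table",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class AgreementResult:
    parameter: str
    channel_pair: tuple[str, str]  # (optical x, mechanical y)
    slope: float
    intercept: float
    r2: float
    bias: float  # mean(mechanical − optical)
    loa_halfwidth: float  # 1.96 * SD of differences
    bias_p: float
    bias_significant: bool
    n: int


def linreg(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y ~ x; returns (slope, intercept, r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman bias, limits-of-agreement half-width and bias p-value.

    d = y − x; bias = mean(d); half-width = 1.96 * sample SD of d;
    p-value from a two-sided one-sample t-test of mean(d) = 0 (NaN when
    the differences have zero variance — flagged non-significant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples required")
    if len(x) < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = 1.96 * sd
    if sd <= 1e-12 * max(1.0, abs(bias)):  # zero-variance differences
        return bias, loa, float("nan")
    p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return bias, loa, p


def _agree_one(
    parameter: str, x: np.ndarray, y: np.ndarray, channel_pair: tuple[str, str]
) -> AgreementResult:
    slope, intercept, r2 = linreg(x, y)
    bias, loa, p = bland_altman(x, y)
    return AgreementResult(
        parameter=parameter,
        channel_pair=channel_pair,
        slope=slope,
        intercept=intercept,
        r2=r2,
        bias=bias,
        loa_halfwidth=loa,
        bias_p=p,
        bias_significant=bool(np.isfinite(p) and p < ALPHA),
        n=len(x),
    )


def _matched_pairs(
    params_y: pd.DataFrame, params_x: pd.DataFrame, parameters
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = params_x.merge(
        params_y, on="beat_index", suffixes=("_x", "_y"), how="inner"
    )
    out = {}
    for p in parameters:
        cx, cy = f"{p}_x", f"{p}_y"
        if cx not in merged or cy not in merged:
            logger.warning("parameter %s absent from inputs, skipped", p)
            continue
        sub = merged[[cx, cy]].dropna()
        out[p] = (sub[cx].to_numpy(), sub[cy].to_numpy())
    return out


def compare_parameters(
    params_fcg: pd.DataFrame,
    params_ppg: pd.DataFrame,
    parameters=COMPARED_PARAMETERS,
) -> list[AgreementResult]:
    """Agreement statistics for beat-matched morphological parameters.

    ``params_*`` are per-beat parameter tables (one row per beat_index).
    x = optical (PPG), y = mechanical (FCG); raw heights h1/h2/h3 are
    never part of the default comparison set.
    """
    pair = (
        str(params_ppg["channel"].iloc[0]) if len(params_ppg) else "ppg",
        str(params_fcg["channel"].iloc[0]) if len(params_fcg) else "fcg",
    )
    results = []
    for p, (x, y) in _matched_pairs(params_fcg, params_ppg, parameters).items():
        if len(x) < 3:
            logger.warning("parameter %s: fewer than 3 matched beats, skipped", p)
            continue
        results.append(_agree_one(p, x, y, pair))
    return results


def pool_subjects(
    per_subject: list[tuple[pd.DataFrame, pd.DataFrame]],
    parameters=COMPARED_PARAMETERS,
) -> list[AgreementResult]:
    """Agreement on the beat-level concatenation of all subjects.

    ``per_subject`` holds (params_fcg, params_ppg) per subject; pairs are
    matched within each subject first, then concatenated without
    per-subject weighting.
    """
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    pair = ("ppg", "fcg")
    for params_fcg, params_ppg in per_subject:
        if len(params_ppg) and len(params_fcg):
            pair = (
                str(params_ppg["channel"].iloc[0]),
                str(params_fcg["channel"].iloc[0]),
            )
        for p, xy in _matched_pairs(params_fcg, params_ppg, parameters).items():
            pooled.setdefault(p, []).append(xy)
    results = []
    for p, chunks in pooled.items():
        x = np.concatenate([c[0] for c in chunks])
        y = np.concatenate([c[1] for c in chunks])
        if len(x) < 3:
            continue
        results.append(_agree_one(p, x, y, pair))
    return results


def agreement_table(results: list[AgreementResult]) -> pd.DataFrame:
    """Report table: one column per parameter, the standard stat rows."""
    rows = ["slope", "intercept", "r2", "bias", "p_value", "loa_halfwidth", "n"]
    table = {}
    for r in results:
        table[r.parameter] = [
            r.slope,
            r.intercept,
            r.r2,
            r.bias if r.bias_significant else np.nan,  # NS bias left blank
            r.bias_p,
            r.loa_halfwidth,
            r.n,
        ]
    return pd.DataFrame(table, index=rows)
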