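"""Normalized cross-correlation of pulse waveforms and their derivatives.

The NCCF between two segments uses whole-segment means and norms:

    NCCF(l) = sum_t (x_t - xbar)(y_{t+l} - ybar) / sqrt(sum (x-xbar)^2 * sum (y-ybar)^2)

with out-of-range samples treated as the segment mean (zero after
centering).  The NCC is the maximum of the NCCF over the lag search
range; its arg-max lag estimates the delay, positive when the second
signal lags the first (here: positive when the optical channel lags
the mechanical one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["NCCResult", "nccf", "beat_ncc", "whole_ncc", "derivative"]


@dataclass
class NCCResult:
    ncc: float
    lag: float  # seconds; positive = second signal delayed
    scope: str  # "beat" or "whole"
    beat_index: int | None = None
    derivative_order: int = 0


def _centered(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant input: normalized cross-correlation undefined")
    return x - x.mean()


def nccf(x, y, max_lag: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation function over integer-sample lags.

    Returns ``(lags, values)`` with lags in seconds spanning
    [-max_lag, +max_lag] (clipped to the available overlap range).
    Unequal lengths are allowed; the shorter signal is zero-padded after
    centering.  Symmetry: nccf(x, y)(l) == nccf(y, x)(-l).
    """
    xc, yc = _centered(x), _centered(y)
    norm = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    n = max(len(xc), len(yc))
    xp = np.pad(xc, (0, n - len(xc)))
    yp = np.pad(yc, (0, n - len(yc)))
    # full cross-correlation: c[l] = sum_t y[t + l] * x[t]
    c = signal.correlate(yp, xp, mode="full", method="fft")
    lags = signal.correlation_lags(len(yp), len(xp), mode="full")
    L = int(round(max_lag * fs))
    keep = np.abs(lags) <= L
    return lags[keep] / fs, c[keep] / norm


def _max_ncc(x, y, max_lag: float, fs: float) -> tuple[float, float]:
    lags, vals = nccf(x, y, max_lag, fs)
    i = int(np.argmax(vals))
    return float(vals[i]), float(lags[i])


def beat_ncc(
    beats_x: list[tuple[int, np.ndarray]],
    beats_y: list[tuple[int, np.ndarray]],
    fs: float,
    max_lag: float | None = None,
    derivative_order: int = 0,
) -> list[NCCResult]:
    """Beat-by-beat NCC between segments matched by beat index.

    ``beats_*`` are ``(beat_index, samples)`` pairs (the output of beat
    segmentation).  Default lag search range is half the median beat
    length.
    """
    by_y = {bi: seg for bi, seg in beats_y}
    pairs = [(bi, seg, by_y[bi]) for bi, seg in beats_x if bi in by_y]
    if not pairs:
        raise ValueError("no beat pairs share a beat index")
    if max_lag is None:
        med = np.median([len(seg) for _, seg, _ in pairs])
        max_lag = 0.5 * med / fs
    out = []
    for bi, sx, sy in pairs:
        ncc, lag = _max_ncc(sx, sy, max_lag, fs)
        out.append(NCCResult(ncc, lag, "beat", bi, derivative_order))
    return out


def whole_ncc(
    x, y, fs: float, max_lag: float = 0.5, derivative_order: int = 0
) -> NCCResult:
    """Whole-signal NCC and average time lag.

    Positive lag means ``y`` is delayed relative to ``x``.
    """
    ncc, lag = _max_ncc(x, y, max_lag, fs)
    return NCCResult(ncc, lag, "whole", None, derivative_order)


def derivative(pw, fs: float, order: int) -> np.ndarray:
    """Savitzky–Golay differentiation (velocity / acceleration waveform).

    Polynomial order 3 over a ~51 ms window (51 samples at 1 kHz);
    output scaled to physical units per second**order.
    """
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    window = int(round(0.051 * fs))
    if window % 2 == 0:
        window += 1
    window = max(window, 5)
    return signal.savgol_filter(
        np.asarray(pw, dtype=float), window, 3, deriv=order, delta=1.0 / fs
    )
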