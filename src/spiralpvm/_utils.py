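"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_phase(phi):
    """Wrap phase values into [-pi, pi)."""
    return (np.asarray(phi) + np.pi) % TWO_PI - np.pi


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Uses decimal arithmetic on the shortest repr of the float so that
    values entered as printed decimals (e.g. 410.45) round the way a
    printed table would, not the way binary floats happen to fall.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Cyclic moving average; window must be odd, window=1 is the identity."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return values.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([values[-pad:], values, values[:pad]])
    return np.convolve(padded, kernel, mode="valid")


def _plateau_runs(y: np.ndarray):
    """Yield (start, stop) index runs of equal consecutive values."""
    y = np.asarray(y)
    n = len(y)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        yield i, j
        i = j + 1


def local_minima_runs(y: np.ndarray):
    """Interior local minima of a sampled curve, plateau-aware.

    Returns a list of (start, stop) runs where the run value is strictly
    below both neighbouring values. Endpoints are not extrema.
    """
    y = np.asarray(y, dtype=float)
    out = []
    for i, j in _plateau_runs(y):
        if i == 0 or j == len(y) - 1:
            continue
        if y[i - 1] > y[i] and y[j + 1] > y[j]:
            out.append((i, j))
    return out


def local_maxima_runs(y: np.ndarray):
    return [(i, j) for (i, j) in local_minima_runs(-np.asarray(y, dtype=float))]
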