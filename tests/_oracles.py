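"""Independent brute-force oracles for the numeric operators under test.

Deliberately naive (scalar loops, all-pairs searches) and written
against the mathematical definitions only, so they share no code path
with the implementations they check.
"""

import math

import numpy as np


def scalar_hue_degrees(r: int, g: int, b: int) -> float:
    """Hexcone hue in degrees [0, 360) for one 8-bit RGB triple."""
    rf, gf, bf = r / 255.0, g / 255.0, b / 255.0
    mx, mn = max(rf, gf, bf), min(rf, gf, bf)
    if mx == mn:
        return 0.0
    d = mx - mn
    if mx == rf:
        h = 60.0 * ((gf - bf) / d)
    elif mx == gf:
        h = 60.0 * ((bf - rf) / d + 2.0)
    else:
        h = 60.0 * ((rf - gf) / d + 4.0)
    return h + 360.0 if h < 0 else h


def _window_values(plane: np.ndarray, i: int, j: int) -> list[float]:
    """3x3 window around (i, j) with edge replication."""
    h, w = plane.shape
    vals = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ii = min(max(i + di, 0), h - 1)
            jj = min(max(j + dj, 0), w - 1)
            vals.append(float(plane[ii, jj]))
    return vals


def naive_window_stats(plane: np.ndarray):
    """Per-pixel population mean/sd/skewness/kurtosis over 3x3 windows."""
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    mu = np.zeros((h, w))
    sigma = np.zeros((h, w))
    skew = np.zeros((h, w))
    kurt = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = _window_values(plane, i, j)
            m = sum(vals) / 9.0
            var = sum((v - m) ** 2 for v in vals) / 9.0
            s = math.sqrt(var)
            mu[i, j] = m
            sigma[i, j] = s
            if s > 0:
                skew[i, j] = sum(((v - m) / s) ** 3 for v in vals) / 9.0
                kurt[i, j] = sum(((v - m) / s) ** 4 for v in vals) / 9.0
    return mu, sigma, skew, kurt


def brute_chessboard(mask: np.ndarray) -> np.ndarray:
    """All-pairs chessboard distance to the nearest outside pixel.

    The image border counts as outside: outside pixels are enumerated on
    a 1-pixel padded frame.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    outside = np.argwhere(~padded)  # coordinates in padded frame
    dist = np.zeros((h, w), dtype=np.int64)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            pi, pj = i + 1, j + 1
            dist[i, j] = np.min(
                np.maximum(np.abs(outside[:, 0] - pi), np.abs(outside[:, 1] - pj))
            )
    return dist
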