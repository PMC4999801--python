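"""Per-pixel local-correlation feature extraction.

Each pixel is described by a 10-dimensional vector built from the blue
and hue planes: the raw intensities (I_b, I_h) plus, over the pixel's
3x3 neighborhood in each plane, the mean mu, standard deviation sigma,
skewness beta and kurtosis beta_k.  All four window statistics use the
population convention (divide by n = 9); kurtosis is the raw fourth
standardized moment (normal ~ 3), optionally converted to excess form.
Windows with sigma = 0 define skewness and kurtosis as 0, which keeps
every feature finite and marks flat regions distinctly.

Hue is treated as a linear quantity: for this stain pair brown sits at
~0-30 deg and hematoxylin at ~240 deg, so windows never straddle the
0/360 seam in practice; circular statistics are deliberately avoided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .io_images import ChannelPlanes

FEATURE_COLUMNS = (
    "I_b", "I_h", "mu_b", "mu_h", "sigma_b", "sigma_h",
    "beta_b", "beta_h", "betak_b", "betak_h",
)

_WINDOW = 3
_N = _WINDOW * _WINDOW


@dataclass(frozen=True)
class FeatureMatrix:
    """Row-major (H*W, 10) feature matrix with its source shape."""

    values: np.ndarray
    height: int
    width: int
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def plane(self, name: str) -> np.ndarray:
        """A single feature as an (H, W) image."""
        return self.values[:, self.columns.index(name)].reshape(self.height, self.width)


def _window_stack(plane: np.ndarray) -> np.ndarray:
    """(H, W, 3, 3) view of each pixel's edge-replicated 3x3 neighborhood."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2 or plane.shape[0] < _WINDOW or plane.shape[1] < _WINDOW:
        raise DimensionError(f"plane must be at least {_WINDOW}x{_WINDOW}, got {plane.shape}")
    padded = np.pad(plane, 1, mode="edge")
    return np.lib.stride_tricks.sliding_window_view(padded, (_WINDOW, _WINDOW))


def local_moments(plane: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population mean and standard deviation over each 3x3 window.

    mu = (1/9) sum x_i and sigma = sqrt((1/9) sum (x_i - mu)^2), computed
    from deviations (not raw moments) so cancellation error stays at the
    scale of the window spread rather than of the values themselves.
    """
    win = _window_stack(plane)
    mu = win.mean(axis=(2, 3))
    d = win - mu[:, :, None, None]
    sigma = np.sqrt((d * d).mean(axis=(2, 3)))
    return mu, sigma


def local_shape(
    plane: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    excess_kurtosis: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Population skewness and kurtosis over each 3x3 window.

    beta   = (1/9) sum ((x_i - mu)/sigma)^3
    beta_k = (1/9) sum ((x_i - mu)/sigma)^4   (minus 3 if excess form)

    Zero-variance windows return (0, 0) for both statistics.
    """
    win = _window_stack(plane)
    d = win - np.asarray(mu, dtype=np.float64)[:, :, None, None]
    flat = sigma == 0
    safe_sigma = np.where(flat, 1.0, sigma)
    z = d / safe_sigma[:, :, None, None]
    z3 = z * z * z
    skew = z3.mean(axis=(2, 3))
    kurt = (z3 * z).mean(axis=(2, 3))
    if excess_kurtosis:
        kurt = kurt - 3.0
    skew[flat] = 0.0
    kurt[flat] = 0.0
    return skew, kurt


def assemble_features(planes: ChannelPlanes, excess_kurtosis: bool = False) -> FeatureMatrix:
    """Stack (I_b, I_h, mu_b, mu_h, sigma_b, sigma_h, beta_b, beta_h,
    betak_b, betak_h) into one row per pixel, row-major order."""
    h, w = planes.shape
    mu_b, sig_b = local_moments(planes.b_plane)
    mu_h, sig_h = local_moments(planes.h_plane)
    beta_b, betak_b = local_shape(planes.b_plane, mu_b, sig_b, excess_kurtosis)
    beta_h, betak_h = local_shape(planes.h_plane, mu_h, sig_h, excess_kurtosis)
    stack = np.stack(
        [
            np.asarray(planes.b_plane, dtype=np.float64),
            np.asarray(planes.h_plane, dtype=np.float64),
            mu_b, mu_h, sig_b, sig_h, beta_b, beta_h, betak_b, betak_h,
        ],
        axis=-1,
    )
    return FeatureMatrix(values=stack.reshape(h * w, len(FEATURE_COLUMNS)), height=h, width=w)
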