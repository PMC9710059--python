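"""Signal-comparison metrics: Pearson r, RMSE and 1-D SSIM.

All three operate on pairs of equal-length vectors (converted vs measured
segments on the normalised [-1, 1] amplitude scale).  The SSIM is the
standard windowed luminance-contrast-structure product adapted to one
dimension: uniform sliding windows, sample (ddof=1) variances and
covariance, constants ``C1 = (k1 * data_range)**2`` and
``C2 = (k2 * data_range)**2``, averaged over all full windows.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConstantSignalError", "pearson_r", "rmse", "ssim_1d"]

#: SSIM defaults: ~0.44 s of context at 250 Hz, the [-1, 1] span, and the
#: conventional stability constants.
SSIM_WINDOW = 111
SSIM_DATA_RANGE = 2.0
SSIM_K1 = 0.01
SSIM_K2 = 0.03


class ConstantSignalError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("metrics operate on 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return x, y


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x, y = _check_pair(x, y)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0 or sy == 0:
        raise ConstantSignalError("correlation undefined for a constant signal")
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean square error."""
    x, y = _check_pair(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def ssim_1d(
    x: np.ndarray,
    y: np.ndarray,
    window_length: int = SSIM_WINDOW,
    data_range: float = SSIM_DATA_RANGE,
    k1: float = SSIM_K1,
    k2: float = SSIM_K2,
) -> float:
    """Mean structural similarity over uniform sliding windows."""
    x, y = _check_pair(x, y)
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if window_length > len(x):
        raise ValueError(
            f"window ({window_length}) longer than signal ({len(x)})")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    xw = np.lib.stride_tricks.sliding_window_view(x, window_length)
    yw = np.lib.stride_tricks.sliding_window_view(y, window_length)
    mx = xw.mean(axis=1)
    my = yw.mean(axis=1)
    # sample (ddof=1) variances/covariance per window
    nw = window_length
    vx = (xw * xw).mean(axis=1) - mx * mx
    vy = (yw * yw).mean(axis=1) - my * my
    cxy = (xw * yw).mean(axis=1) - mx * my
    corr = nw / (nw - 1)
    vx, vy, cxy = vx * corr, vy * corr, cxy * corr
    ssim_map = ((2 * mx * my + c1) * (2 * cxy + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2))
    return float(ssim_map.mean())
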