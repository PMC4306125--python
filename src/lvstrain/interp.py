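"""Cubic-spline image resampling shared by the cost and registration modules.

Transformed coordinates are generally non-integer, so images are sampled
with a cubic interpolating spline (scipy's separable B-spline machinery).
The spline coefficient image can be prefiltered once and reused across the
many evaluations an optimization performs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["spline_prefilter", "resample", "sample_prefiltered"]

_MODE = "nearest"  # out-of-image samples take the border value


def spline_prefilter(image: np.ndarray) -> np.ndarray:
    """B-spline coefficient image for repeated cubic sampling."""
    return ndimage.spline_filter(np.asarray(image, dtype=float), order=3, mode=_MODE)


def sample_prefiltered(prefiltered: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic sample of a prefiltered image at ``(x, y)`` pixel coordinates."""
    return ndimage.map_coordinates(prefiltered, [y, x], order=3,
                                   prefilter=False, mode=_MODE)


def resample(image: np.ndarray, coords: np.ndarray, *, prefiltered: np.ndarray | None = None):
    """Cubic-spline resample of ``image`` at ``coords``.

    Parameters
    ----------
    image : 2D array
    coords : array of shape (..., 2)
        ``(x, y)`` sample positions in pixel coordinates.
    prefiltered : optional precomputed ``spline_prefilter(image)``.

    Returns
    -------
    values : array with the leading shape of ``coords``
        Out-of-image positions are filled with the border value.
    mask : boolean array, same shape
        True where the sample position lies inside the image.
    """
    image = np.asarray(image, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] != 2:
        raise ValueError("coords must have shape (..., 2)")
    if not np.isfinite(coords).all():
        raise ValueError("coords must be finite")
    if prefiltered is None:
        prefiltered = spline_prefilter(image)
    x, y = coords[..., 0], coords[..., 1]
    vals = sample_prefiltered(prefiltered, x, y)
    h, w = image.shape
    mask = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    if not np.all(mask):
        # border-value fill: re-evaluate at the nearest in-image position
        # (the clamped spline coefficients alone would ring outside)
        fallback = sample_prefiltered(prefiltered, np.clip(x, 0, w - 1),
                                      np.clip(y, 0, h - 1))
        vals = np.where(mask, vals, fallback)
    return vals, mask


def pixel_grid(shape) -> np.ndarray:
    """(H, W, 2) array of ``(x, y)`` pixel-centre coordinates."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return np.stack([xs, ys], axis=-1).astype(float)
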