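"""Fluorescence intensity quantification: ROIs, linescans, normalization.

Measurements are taken either on sum Z-projections or on a single focal
plane, inside user-supplied regions of interest.  Background handling mirrors
manual cytoplasmic sampling: the mean background intensity is subtracted from
the measured value and the result is divided by the background mean,

    normalized = (raw - background_mean) / background_mean,

which makes the quantity invariant to a global multiplicative detector gain
(additive offsets are *not* removed).  For cross-condition comparison, the
background-normalized series is further divided by the maximum
background-normalized value of the control series, so the control series
itself peaks at exactly 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["measure_roi", "linescan", "background_normalize",
           "normalize_series", "control_max"]


def measure_roi(stack: np.ndarray, roi, mode: str = "single_plane", *,
                integrated: bool = False, plane: int | None = None) -> float:
    """Measure a raw intensity value inside a rectangular ROI.

    Parameters
    ----------
    stack : 2D (Y, X) or 3D (Z, Y, X) array.
    roi : (y0, y1, x0, x1) half-open pixel bounds.
    mode : "single_plane" (mean over the ROI in one plane) or "sum_z"
        (pixel-wise sum over Z, then mean over the ROI; with
        ``integrated=True`` the ROI sum instead of the mean).
    plane : required Z index when mode="single_plane" and the stack is 3D.
    """
    y0, y1, x0, x1 = roi
    if stack.ndim == 2:
        img = stack
        if mode == "sum_z":
            raise ValueError("sum_z projection needs a 3D stack")
    elif stack.ndim == 3:
        if mode == "sum_z":
            img = stack.sum(axis=0)
        elif mode == "single_plane":
            if plane is None:
                raise ValueError("single_plane mode on a 3D stack needs a "
                                 "plane index")
            img = stack[plane]
        else:
            raise ValueError(f"unknown mode {mode!r}")
    else:
        raise ValueError("stack must be 2D or 3D")
    h, w = img.shape
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise ValueError(f"ROI {roi} outside image bounds {img.shape}")
    window = img[y0:y1, x0:x1]
    if window.size == 0:
        raise ValueError("empty ROI")
    return float(window.sum() if integrated else window.mean())


def linescan(plane: np.ndarray, p0, p1, width_px: int = 1) -> np.ndarray:
    """Intensity profile along a line, averaged across its width.

    ``p0``/``p1`` are (x, y) pixel endpoints.  The profile is sampled at
    one-pixel pitch along the line with bilinear interpolation and averaged
    over ``width_px`` (odd, >= 1) parallel offsets perpendicular to it.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be odd and >= 1")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    vec = p1 - p0
    length = np.linalg.norm(vec)
    if length == 0:
        raise ValueError("zero-length line")
    d = vec / length
    nrm = np.array([-d[1], d[0]])
    n_samples = int(np.round(length)) + 1
    ts = np.linspace(0, length, n_samples)
    offsets = np.arange(width_px) - width_px // 2
    # sample positions: (width, n_samples, 2) in (x, y)
    pts = (p0[None, None, :] + ts[None, :, None] * d[None, None, :]
           + offsets[:, None, None] * nrm[None, None, :])
    coords = np.stack([pts[..., 1], pts[..., 0]])  # rows (y), cols (x)
    vals = ndimage.map_coordinates(plane.astype(float), coords, order=1,
                                   mode="nearest")
    return vals.mean(axis=0)


def background_normalize(raw, background_mean: float):
    """``(raw - background) / background``; gain-invariant."""
    if background_mean <= 0:
        raise ValueError("background_mean must be positive")
    return (np.asarray(raw, dtype=float) - background_mean) / background_mean


def control_max(control_raw, control_background: float) -> float:
    """Maximum background-normalized value of a control series."""
    return float(np.max(background_normalize(control_raw,
                                             control_background)))


def normalize_series(raw, background_mean: float,
                     control_max_normalized: float):
    """Background-normalize a series and scale by the control maximum.

    ``control_max_normalized`` is the maximum *background-normalized* value
    of the control series (see :func:`control_max`); the control series
    itself therefore maps to a series with maximum exactly 1.
    """
    if control_max_normalized <= 0:
        raise ValueError("control maximum must be positive")
    return background_normalize(raw, background_mean) / control_max_normalized
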