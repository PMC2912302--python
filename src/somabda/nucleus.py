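"""Nucleus proxy: centroid of the area above a relative height threshold.

Probe microscopy of neural cells shows that the tallest part of the cell body
sits over the nucleus.  The centroid C_T of the pixel area whose height
exceeds a fraction T of the maximum height therefore serves as a nucleus
proxy; T = 0.9 (C_90) is the default and is used as the rotation centre of
the pipeline.  The mask may consist of several disjoint patches at high T;
the centroid is taken over all of them without connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan_model import ScanGrid

__all__ = ["ThresholdCentroid", "area_mask", "centroid", "centroid_sweep"]


@dataclass(frozen=True)
class ThresholdCentroid:
    """Centroid of the pixel area above a relative height threshold.

    ``cx``/``cy`` are physical coordinates (µm); ``npix`` is the number of
    pixels above threshold.  For an empty mask (possible within a sweep)
    ``npix`` is 0 and the coordinates are NaN.
    """

    T: float
    cx: float
    cy: float
    npix: int


def area_mask(grid: ScanGrid, T: float) -> np.ndarray:
    """Boolean mask of pixels whose height strictly exceeds ``T * z_max``.

    Raises ``ValueError`` for an all-zero grid or an empty mask (T chosen so
    that no pixel exceeds the cut — the comparison is strict).
    """
    if not 0 <= T < 1 + 1e-12:
        raise ValueError("T must lie in [0, 1]")
    zmax = grid.z.max()
    if zmax <= 0:
        raise ValueError("no structure above threshold: grid is all zero")
    mask = grid.z > T * zmax
    if not mask.any():
        raise ValueError("no structure above threshold")
    return mask


def centroid(mask: np.ndarray, grid: ScanGrid, T: float = float("nan")) -> ThresholdCentroid:
    """Arithmetic mean of the physical coordinates of the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    X, Y = grid.xy
    return ThresholdCentroid(T=T, cx=float(X[mask].mean()), cy=float(Y[mask].mean()), npix=n)


def centroid_sweep(grid: ScanGrid, Ts) -> list[ThresholdCentroid]:
    """One :class:`ThresholdCentroid` per threshold, in input order.

    Thresholds whose mask is empty are reported with ``npix=0`` and NaN
    coordinates rather than raising.
    """
    out = []
    for T in Ts:
        try:
            mask = area_mask(grid, T)
        except ValueError:
            out.append(ThresholdCentroid(T=T, cx=float("nan"), cy=float("nan"), npix=0))
            continue
        out.append(centroid(mask, grid, T))
    return out


def c90(grid: ScanGrid, T: float = 0.9) -> tuple[float, float]:
    """Convenience: the (cx, cy) of the nucleus proxy at threshold ``T``."""
    cen = centroid(area_mask(grid, T), grid, T)
    return cen.cx, cen.cy
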