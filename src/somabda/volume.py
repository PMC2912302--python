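"""Soma volume integration, dimensions, discard rule and the threshold comparator.

The soma volume is the sum of the heights of all rotated-grid pixels inside
the delimited region times the pixel footprint dx·dy (µm³ ≡ fL).  The region
is split into frontal (x′ > 0) and rear (x′ < 0) parts at the nucleus-proxy
level; the x′ = 0 column contributes half to each so the split is exactly
additive and symmetric cells get equal halves.  A recording whose boundary
leaves the original scan footprint cannot be integrated and is flagged
discarded.  The height-threshold comparator — assign every pixel above a
fixed (or relative) height to the soma — is provided for method comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .regrid import RotatedGrid, inverse_map
from .scan_model import ScanGrid

__all__ = [
    "SomaRegion",
    "VolumeReport",
    "soma_volume",
    "threshold_volume",
    "normalized_volume",
]


@dataclass(frozen=True)
class SomaRegion:
    """Delimited soma: per-line boundaries, pixel mask, boundary points.

    ``mask`` is boolean over the rotated grid; ``boundary_points`` are the
    interval endpoints in signed rotated-frame coordinates (x′, y′).
    """

    boundaries: tuple
    mask: np.ndarray = field(repr=False)
    boundary_points: tuple = ()


@dataclass(frozen=True)
class VolumeReport:
    """Per-scan soma quantification.

    Volumes are in µm³ (≡ fL); ``width``/``length``/``height`` are the mask
    extents along y′/x′ and the maximum height (µm); ``basal_area`` is the
    mask pixel count times the pixel footprint (µm²).
    """

    V_total: float
    V_front: float
    V_rear: float
    width: float
    length: float
    height: float
    basal_area: float
    discarded: bool
    theta_h: float
    c90: tuple[float, float]

    @property
    def V_total_pL(self) -> float:
        return self.V_total / 1000.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c90"] = list(self.c90)
        d["V_total_fL"] = self.V_total
        d["V_total_pL"] = self.V_total_pL
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @staticmethod
    def csv_header() -> str:
        return "V_total,V_front,V_rear,width,length,height,basal_area,discarded,theta_h,c90_x,c90_y"

    def to_csv_row(self) -> str:
        return (
            f"{self.V_total!r},{self.V_front!r},{self.V_rear!r},"
            f"{self.width!r},{self.length!r},{self.height!r},{self.basal_area!r},"
            f"{int(self.discarded)},{self.theta_h!r},{self.c90[0]!r},{self.c90[1]!r}"
        )


def soma_volume(rgrid: RotatedGrid, region: SomaRegion, source: ScanGrid) -> VolumeReport:
    """Integrate the delimited region and assemble the per-scan report."""
    dx, dy = rgrid.dx, rgrid.dy
    pix = dx * dy
    mask = region.mask
    if not mask.any():
        return VolumeReport(
            V_total=0.0, V_front=0.0, V_rear=0.0, width=0.0, length=0.0,
            height=0.0, basal_area=0.0, discarded=False,
            theta_h=rgrid.theta_h, c90=rgrid.center,
        )
    XP, YP = np.meshgrid(rgrid.xlevels, rgrid.ylevels)
    xtol = 1e-9 * dx
    z = rgrid.z
    front = mask & (XP > xtol)
    rear = mask & (XP < -xtol)
    mid = mask & (np.abs(XP) <= xtol)
    v_front = (z[front].sum() + 0.5 * z[mid].sum()) * pix
    v_rear = (z[rear].sum() + 0.5 * z[mid].sum()) * pix
    v_total = z[mask].sum() * pix

    xmin, xmax, ymin, ymax = source.bounds()
    pad = 1e-9 * max(dx, dy)
    discarded = False
    for bx, by in region.boundary_points:
        sx, sy = inverse_map((bx, by), rgrid.theta_h, rgrid.center)
        if not (xmin - pad <= sx <= xmax + pad and ymin - pad <= sy <= ymax + pad):
            discarded = True
            break

    return VolumeReport(
        V_total=float(v_total),
        V_front=float(v_front),
        V_rear=float(v_rear),
        width=float(YP[mask].max() - YP[mask].min()),
        length=float(XP[mask].max() - XP[mask].min()),
        height=float(z[mask].max()),
        basal_area=float(mask.sum() * pix),
        discarded=discarded,
        theta_h=rgrid.theta_h,
        c90=rgrid.center,
    )


def threshold_volume(grid: ScanGrid, tau: float, relative: bool = False) -> float:
    """Comparator: Σ z over pixels strictly exceeding the height threshold.

    With ``relative=True`` the effective threshold is ``tau * z_max``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    eff = tau * grid.z.max() if relative else tau
    return float(grid.z[grid.z > eff].sum() * grid.dx * grid.dy)


def normalized_volume(V: float, V_ref: float) -> float:
    """V_n = V / V_ref, with V_ref the column sum of the extension-free twin."""
    if V_ref <= 0:
        raise ValueError("V_ref must be positive")
    return V / V_ref
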