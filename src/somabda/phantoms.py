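"""Synthetic evaluation objects and the parameter sweeps.

The evaluation phantoms are half-ellipsoids on a 30 µm square frame at 1 µm
lateral step (900 pixels — the frame/step compromise that gives live SICM an
acceptable frame rate), with base radius r_0 = 5 µm since an OPC soma is
roughly 10 µm long.  Bipolar processes are emulated by a strip of rows
around the centre raised to a fixed extension height wherever the ellipsoid
lies below it, running to the frame borders in ±x.  Sweeps deform these
objects (flattening at constant volume, growing or widening the extensions)
and compare the boundary-delimitation estimate against the height-threshold
comparator, both normalized to the column-sum volume V_sum of the
extension-free twin.  All sweeps are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, bda_report, bda_report_norot
from .scan_model import ScanGrid
from .volume import threshold_volume

__all__ = [
    "R0",
    "PhantomSpec",
    "half_ellipsoid",
    "add_extensions",
    "v_sum",
    "sweep_flatten",
    "sweep_extension_height",
    "sweep_extension_width",
    "sweep_combined",
]

R0 = 5.0  # base radius, µm


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one evaluation object.

    ``size``/``step`` describe the frame at resolution 1; ``resolution``
    refines the lateral step by that factor at identical physical geometry
    (resolution 10 → 300×300 pixels at 0.1 µm).  The centre sits between
    lattice rows so the even-width extension strip is symmetric about the
    dome.  Extension defaults are height r_0/2 and width 2·r_0/5.
    """

    size: int = 30
    step: float = 1.0
    center: tuple[float, float] = (14.5, 14.5)
    r_x: float = R0
    r_y: float = R0
    r_z: float = R0
    ext_height: float = R0 / 2
    ext_width: float = 2 * R0 / 5
    resolution: int = 1

    def __post_init__(self):
        if min(self.r_x, self.r_y, self.r_z) <= 0:
            raise ValueError("radii must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")

    @property
    def eff_step(self) -> float:
        return self.step / self.resolution

    @property
    def npix(self) -> int:
        return self.size * self.resolution


def half_ellipsoid(spec: PhantomSpec) -> ScanGrid:
    """Rasterize the half-ellipsoid height field on the phantom lattice.

    z(x, y) = r_z · Re √(1 − ((x−x0)/r_x)² − ((y−y0)/r_y)²): the ellipsoid
    height inside its support ellipse and 0 outside (taking the real part
    zeroes the imaginary heights beyond the support).
    """
    step = spec.eff_step
    coords = np.arange(spec.npix) * step
    X, Y = np.meshgrid(coords, coords)
    s = 1.0 - ((X - spec.center[0]) / spec.r_x) ** 2 - ((Y - spec.center[1]) / spec.r_y) ** 2
    z = spec.r_z * np.sqrt(np.clip(s, 0.0, None))
    return ScanGrid(nx=spec.npix, ny=spec.npix, dx=step, dy=step, x0=0.0, y0=0.0, z=z)


def add_extensions(grid: ScanGrid, spec: PhantomSpec) -> ScanGrid:
    """Raise the central strip to the extension height (max composition).

    The strip covers the rows with y in [y0 − w/2, y0 + w/2) — a half-open
    band of round(w/step) rows symmetric about the centre — and spans the
    full ±x extent of the frame.  Taking the maximum of dome and extension
    height avoids a gap where the two meet but also raises some dome-skirt
    pixels, so the object's column sum exceeds the bare dome's.
    """
    if spec.ext_height < 0:
        raise ValueError("extension height must be >= 0")
    z = grid.z.copy()
    y = grid.y
    lo = spec.center[1] - spec.ext_width / 2
    hi = spec.center[1] + spec.ext_width / 2
    rows = (y >= lo - 1e-9) & (y < hi - 1e-9)
    z[rows, :] = np.maximum(z[rows, :], spec.ext_height)
    return grid.with_z(z)


def v_sum(grid: ScanGrid) -> float:
    """Column-sum volume Σ z · dx·dy (µm³)."""
    return float(grid.z.sum() * grid.dx * grid.dy)


_PHANTOM_CONFIG = PipelineConfig(min_height=0.0, plane_correction=False)


def _bda_volume(grid: ScanGrid, rotate: bool) -> float:
    if rotate:
        report, _, _ = bda_report(grid, _PHANTOM_CONFIG, preprocess=False)
    else:
        report, _, _ = bda_report_norot(grid, _PHANTOM_CONFIG)
    return report.V_total


def _flatten_spec(t: float, variant: str, resolution: int = 1) -> PhantomSpec:
    if variant == "rx":
        rx, ry = t * R0, R0
    elif variant == "ry":
        rx, ry = R0, t * R0
    elif variant == "both":
        rx = ry = np.sqrt(t) * R0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return PhantomSpec(r_x=rx, r_y=ry, r_z=R0 / t, resolution=resolution)


def sweep_flatten(
    ts=None,
    mode: str = "bda",
    variant: str = "rx",
) -> pd.DataFrame:
    """Flattening-at-constant-volume sweep: r_z = r_0/t against widening radii.

    Extension-free objects; the delimitation runs without heading/rotation.
    Threshold modes use 0.4·r_z (relative, tracking the flattening) or
    0.4·r_0 (absolute).  Returns columns (t, V, V_sum, V_n).
    """
    if ts is None:
        ts = np.arange(1.0, 2.0001, 0.05)
    rows = []
    for t in np.asarray(ts, float):
        spec = _flatten_spec(t, variant)
        grid = half_ellipsoid(spec)
        vs = v_sum(grid)
        if mode == "bda":
            v = _bda_volume(grid, rotate=False)
        elif mode == "threshold_rel":
            v = threshold_volume(grid, 0.4 * spec.r_z)
        elif mode == "threshold_abs":
            v = threshold_volume(grid, 0.4 * R0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((t, v, vs, v / vs))
    return pd.DataFrame(rows, columns=["t", "V", "V_sum", "V_n"])


def sweep_extension_height(
    hs=None,
    mode: str = "bda",
    resolution: int = 1,
) -> pd.DataFrame:
    """Extension-height sweep on the hemisphere: height h·r_0, h per step 0.01.

    The threshold comparator uses h·r_0 as its threshold (tracking the
    extension height); both estimators are normalized to V_sum of the bare
    hemisphere at the same resolution.  Returns (h, V, V_sum, V_n).
    """
    if hs is None:
        hs = np.arange(0.05, 0.9501, 0.01)
    spec0 = PhantomSpec(resolution=resolution)
    bare = half_ellipsoid(spec0)
    vs = v_sum(bare)
    rows = []
    for h in np.asarray(hs, float):
        spec = replace(spec0, ext_height=h * R0)
        grid = add_extensions(bare, spec)
        if mode == "bda":
            v = _bda_volume(grid, rotate=True)
        elif mode == "threshold":
            v = threshold_volume(grid, h * R0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((h, v, vs, v / vs))
    return pd.DataFrame(rows, columns=["h", "V", "V_sum", "V_n"])


def sweep_extension_width(
    ws=None,
    mode: str = "bda",
    resolution: int = 1,
) -> pd.DataFrame:
    """Extension-width sweep at fixed height r_0/2: strip width w·2·r_y.

    The base width w = 0.2 reproduces the default two-pixel strip.  The
    threshold comparator (threshold r_0/2) is width-blind and stays
    constant.  Returns (w, width_um, V, V_sum, V_n).
    """
    if ws is None:
        ws = np.arange(0.1, 0.9001, 0.05)
    spec0 = PhantomSpec(resolution=resolution)
    bare = half_ellipsoid(spec0)
    vs = v_sum(bare)
    rows = []
    for w in np.asarray(ws, float):
        spec = replace(spec0, ext_width=w * 2 * spec0.r_y)
        grid = add_extensions(bare, spec)
        if mode == "bda":
            v = _bda_volume(grid, rotate=True)
        elif mode == "threshold":
            v = threshold_volume(grid, spec0.ext_height)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append((w, spec.ext_width, v, vs, v / vs))
    return pd.DataFrame(rows, columns=["w", "width_um", "V", "V_sum", "V_n"])


def sweep_combined(
    hs=None,
    ts=None,
    mode: str = "bda",
    resolution: int = 1,
) -> pd.DataFrame:
    """Joint shape/extension sweep: r_x = r_y = √t·r_0, r_z = r_0/t, height h·r_z.

    The threshold comparator uses h·r_z(t).  Each V is normalized to V_sum
    of the extension-free ellipsoid at the same t.  Returns (h, t, V, V_sum, V_n).
    """
    if hs is None:
        hs = np.arange(0.2, 0.6001, 0.01)
    if ts is None:
        ts = np.arange(1.0, 2.0001, 0.05)
    rows = []
    for t in np.asarray(ts, float):
        spec_bare = _flatten_spec(t, "both", resolution)
        bare = half_ellipsoid(spec_bare)
        vs = v_sum(bare)
        for h in np.asarray(hs, float):
            spec = replace(spec_bare, ext_height=h * spec_bare.r_z)
            grid = add_extensions(bare, spec)
            if mode == "bda":
                v = _bda_volume(grid, rotate=True)
            elif mode == "threshold":
                v = threshold_volume(grid, h * spec_bare.r_z)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append((h, t, v, vs, v / vs))
    return pd.DataFrame(rows, columns=["h", "t", "V", "V_sum", "V_n"])
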