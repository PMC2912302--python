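"""Regular-lattice height maps: the core grid type, text I/O and pre-filters.

A scanning-probe topography recording is a complete rectangular lattice of
height samples, one per probe position.  Scan files are plain text with three
whitespace-separated columns (x, y, z, all in micrometres), one pixel per
line, in any row order.  Before the boundary delimitation runs, recordings
are plane-corrected (removing residual substrate tilt) and floor-filtered
(heights below 1 µm are attributed to the culture dish and set to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanGrid",
    "ScanParseError",
    "read_scan",
    "write_scan",
    "plane_correct",
    "floor_filter",
]


class ScanParseError(ValueError):
    """Raised when a scan file does not describe a complete regular lattice."""


@dataclass(frozen=True)
class ScanGrid:
    """A complete regular lattice of height samples.

    Attributes
    ----------
    nx, ny : int
        Pixel counts along x and y (each ≥ 2).
    dx, dy : float
        Lateral step sizes in µm (each > 0).
    x0, y0 : float
        Physical coordinates of pixel (0, 0) in µm.
    z : numpy.ndarray
        Heights in µm, shape ``(ny, nx)``; ``z[iy, ix]`` is the point sample
        at physical position ``(x0 + ix*dx, y0 + iy*dy)``.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    x0: float
    y0: float
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs at least 2 pixels per axis")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("step sizes must be positive")
        z = np.asarray(self.z, dtype=float)
        if z.shape != (self.ny, self.nx):
            raise ValueError(f"z has shape {z.shape}, expected {(self.ny, self.nx)}")
        if not np.all(np.isfinite(z)):
            raise ValueError("heights must be finite")
        object.__setattr__(self, "z", z)

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinates of the columns (length nx)."""
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinates of the rows (length ny)."""
        return self.y0 + self.dy * np.arange(self.ny)

    @property
    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of physical coordinates, each shaped like ``z``."""
        return np.meshgrid(self.x, self.y)

    def bounds(self) -> tuple[float, float, float, float]:
        """Closed bounding rectangle ``(xmin, xmax, ymin, ymax)`` of the lattice."""
        return (
            self.x0,
            self.x0 + (self.nx - 1) * self.dx,
            self.y0,
            self.y0 + (self.ny - 1) * self.dy,
        )

    def with_z(self, z: np.ndarray) -> "ScanGrid":
        """Copy of this grid with replaced heights."""
        return ScanGrid(self.nx, self.ny, self.dx, self.dy, self.x0, self.y0, z)


def _infer_levels(values: np.ndarray, axis_name: str, rtol: float = 1e-6) -> np.ndarray:
    """Unique sorted coordinate levels, verifying a constant step size."""
    levels = np.unique(values)
    if levels.size < 2:
        raise ScanParseError(f"need at least 2 distinct {axis_name} coordinates")
    steps = np.diff(levels)
    step = steps.mean()
    if np.any(np.abs(steps - step) > rtol * abs(step)):
        raise ScanParseError(f"non-constant step size along {axis_name}")
    return levels


def read_scan(path) -> ScanGrid:
    """Read a three-column (x y z) text file into a :class:`ScanGrid`.

    Rows may appear in any order; lines starting with ``#`` and blank lines
    are ignored.  The lattice must be complete: every (x, y) combination of
    the inferred coordinate levels must occur exactly once.
    """
    xs, ys, zs = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise ScanParseError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                x, y, z = (float(p) for p in parts)
            except ValueError as exc:
                raise ScanParseError(f"{path}: line {lineno}: non-numeric token") from exc
            xs.append(x)
            ys.append(y)
            zs.append(z)
    if not xs:
        raise ScanParseError(f"{path}: empty scan file")
    xa, ya, za = np.array(xs), np.array(ys), np.array(zs)
    xlev = _infer_levels(xa, "x")
    ylev = _infer_levels(ya, "y")
    nx, ny = xlev.size, ylev.size
    dx = (xlev[-1] - xlev[0]) / (nx - 1)
    dy = (ylev[-1] - ylev[0]) / (ny - 1)
    ix = np.rint((xa - xlev[0]) / dx).astype(int)
    iy = np.rint((ya - ylev[0]) / dy).astype(int)
    grid = np.full((ny, nx), np.nan)
    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy, ix), 1)
    if np.any(counts > 1):
        raise ScanParseError(f"{path}: duplicate lattice positions")
    if np.any(counts == 0):
        missing = np.argwhere(counts == 0)[0]
        raise ScanParseError(
            f"{path}: incomplete lattice: missing position "
            f"({xlev[missing[1]]}, {ylev[missing[0]]})"
        )
    grid[iy, ix] = za
    return ScanGrid(nx, ny, float(dx), float(dy), float(xlev[0]), float(ylev[0]), grid)


def write_scan(grid: ScanGrid, path) -> None:
    """Write a grid as three-column text, row-major, with full float precision.

    ``read_scan(write_scan(g))`` reproduces ``g`` bit-exactly in z and steps.
    """
    X, Y = grid.xy
    with open(path, "w") as fh:
        for x, y, z in zip(X.ravel(), Y.ravel(), grid.z.ravel()):
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def plane_correct(grid: ScanGrid, substrate_quantile: float = 0.3) -> ScanGrid:
    """Subtract the least-squares substrate plane and re-zero the minimum.

    The plane is fitted to the pixels whose height lies within the lowest
    ``substrate_quantile`` fraction of the frame — in a typical recording the
    culture dish dominates the frame, so the low-height pixels sample the
    substrate.  After subtraction the grid is shifted so its minimum is 0.
    """
    if not 0 < substrate_quantile < 1:
        raise ValueError("substrate_quantile must be in (0, 1)")
    z = grid.z
    cutoff = np.quantile(z, substrate_quantile)
    sel = z <= cutoff
    if sel.sum() < 3:
        raise ValueError("fewer than 3 substrate pixels for the plane fit")
    X, Y = grid.xy
    A = np.column_stack([X[sel], Y[sel], np.ones(sel.sum())])
    coef, *_ = np.linalg.lstsq(A, z[sel], rcond=None)
    plane = coef[0] * X + coef[1] * Y + coef[2]
    corrected = z - plane
    corrected -= corrected.min()
    return grid.with_z(corrected)


def floor_filter(grid: ScanGrid, min_height: float = 1.0) -> ScanGrid:
    """Zero all heights strictly below ``min_height`` (default 1 µm).

    Heights exactly at the cut are retained.  Idempotent.
    """
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    z = grid.z.copy()
    z[z < min_height] = 0.0
    return grid.with_z(z)
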