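"""Heading-aligned resampling of a scan.

The scan is rotated about the nucleus proxy so that the heading direction
becomes the abscissa, and translated so that the proxy sits at the origin.
Heights on the new lattice are obtained by back-rotating each target point
into the source frame and interpolating there: the four surrounding source
pixels define four right triangles (three pixels each); the height is the
mean of the planes through those triangles that contain the point, membership
being decided by the angle-sum test (the angles subtended at the point by the
triangle sides total 2π iff the point is inside).  Points leaving the source
footprint get height 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scan_model import ScanGrid

__all__ = [
    "RotatedGrid",
    "rotated_extent",
    "inverse_map",
    "triangle_plane_z",
    "angle_sum_inclusion",
    "interpolate_z",
    "rotate_scan",
]

ANGLE_TOL = 1e-6  # rad; slack on the 2π inclusion test
SNAP_REL = 1e-9   # lattice-coincidence snap, relative to the step size


@dataclass(frozen=True)
class RotatedGrid:
    """Heading-aligned, translated, interpolated height map.

    ``xlevels``/``ylevels`` are the rotated-frame lattice coordinates (µm,
    steps equal to the source grid's); the origin (0, 0) is always a lattice
    point and carries the rotation centre.  ``z`` is indexed ``[iy, ix]``.
    """

    xlevels: np.ndarray
    ylevels: np.ndarray
    z: np.ndarray = field(repr=False)
    theta_h: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    @property
    def dx(self) -> float:
        return float(self.xlevels[1] - self.xlevels[0]) if self.xlevels.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.ylevels[1] - self.ylevels[0]) if self.ylevels.size > 1 else 1.0

    def to_scan_grid(self) -> ScanGrid:
        """View the rotated lattice as a plain grid (x′ y′ z′), e.g. for I/O."""
        return ScanGrid(
            nx=self.xlevels.size,
            ny=self.ylevels.size,
            dx=self.dx,
            dy=self.dy,
            x0=float(self.xlevels[0]),
            y0=float(self.ylevels[0]),
            z=self.z,
        )


def _frame_coords(px, py, center, theta):
    """Source-frame points → rotated-frame coordinates (x′ along heading)."""
    ux, uy = px - center[0], py - center[1]
    c, s = np.cos(theta), np.sin(theta)
    return c * ux + s * uy, -s * ux + c * uy


def rotated_extent(grid: ScanGrid, center, theta_h: float):
    """Rotated-frame lattice levels covering the back-rotated source rectangle.

    The four source corners are projected onto the heading axis (x′) and its
    perpendicular (y′); the per-side extrema are rounded outward to whole
    multiples of the source steps so the new lattice always covers the source
    footprint and keeps the origin as a lattice point.
    """
    xmin, xmax, ymin, ymax = grid.bounds()
    cx = np.array([xmin, xmax, xmin, xmax])
    cy = np.array([ymin, ymin, ymax, ymax])
    xp, yp = _frame_coords(cx, cy, center, theta_h)
    eps = 1e-9
    klo = int(np.floor(xp.min() / grid.dx + eps))
    khi = int(np.ceil(xp.max() / grid.dx - eps))
    mlo = int(np.floor(yp.min() / grid.dy + eps))
    mhi = int(np.ceil(yp.max() / grid.dy - eps))
    xlevels = np.arange(klo, khi + 1) * grid.dx
    ylevels = np.arange(mlo, mhi + 1) * grid.dy
    return xlevels, ylevels


def inverse_map(pprime, theta_h: float, center):
    """Rotated-frame point → source-frame point (inverse rotation + re-translation)."""
    xq, yq = pprime
    c, s = np.cos(theta_h), np.sin(theta_h)
    return (c * xq - s * yq + center[0], s * xq + c * yq + center[1])


def triangle_plane_z(v1, v2, v3, q) -> float:
    """Height at ``q`` of the unique plane through three 3-D points."""
    A = np.array([[v1[0], v1[1], 1.0], [v2[0], v2[1], 1.0], [v3[0], v3[1], 1.0]])
    det = np.linalg.det(A)
    scale = max(abs(v) for row in A[:, :2] for v in row) or 1.0
    if abs(det) < 1e-12 * scale * scale:
        raise ValueError("triangle vertices are collinear in the lateral plane")
    a, b, c = np.linalg.solve(A, np.array([v1[2], v2[2], v3[2]]))
    return float(a * q[0] + b * q[1] + c)


def angle_sum_inclusion(v1, v2, v3, q, tol: float = ANGLE_TOL) -> bool:
    """True iff the angles subtended at ``q`` by the triangle sides sum to 2π."""
    zeta = _angle_sum(np.asarray(v1, float), np.asarray(v2, float), np.asarray(v3, float), np.asarray(q, float))
    return bool(abs(zeta - 2 * np.pi) <= tol)


def _angle_sum(v1, v2, v3, q):
    vs = [np.asarray(v, float) - q for v in (v1, v2, v3)]
    total = 0.0
    for a, b in ((0, 1), (1, 2), (2, 0)):
        ua, ub = vs[a], vs[b]
        na, nb = np.hypot(*ua), np.hypot(*ub)
        if na == 0 or nb == 0:
            return 2 * np.pi  # query coincides with a vertex: treat as inside
        cosang = np.clip(np.dot(ua, ub) / (na * nb), -1.0, 1.0)
        total += np.arccos(cosang)
    return total


def _interp_many(grid: ScanGrid, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Vectorized source-frame interpolation at arbitrary points.

    Outside the closed bounding rectangle → 0.  Points within ``SNAP_REL`` of
    a lattice point return that pixel's height exactly.  Otherwise: mean of
    the plane heights of the containing triangles among the four surrounding
    right triangles; if the angle-sum test admits none (degenerate float
    cases), the triangle with the largest angle sum is used.
    """
    px = np.atleast_1d(np.asarray(px, float))
    py = np.atleast_1d(np.asarray(py, float))
    out = np.zeros(px.shape, float)
    xmin, xmax, ymin, ymax = grid.bounds()
    pad = 1e-12 * max(abs(xmax - xmin), abs(ymax - ymin))
    inside = (px >= xmin - pad) & (px <= xmax + pad) & (py >= ymin - pad) & (py <= ymax + pad)
    if not inside.any():
        return out
    fx = (px[inside] - grid.x0) / grid.dx
    fy = (py[inside] - grid.y0) / grid.dy
    rx, ry = np.rint(fx), np.rint(fy)
    snap = (np.abs(fx - rx) <= SNAP_REL) & (np.abs(fy - ry) <= SNAP_REL)
    vals = np.empty(fx.shape, float)
    if snap.any():
        ix = np.clip(rx[snap].astype(int), 0, grid.nx - 1)
        iy = np.clip(ry[snap].astype(int), 0, grid.ny - 1)
        vals[snap] = grid.z[iy, ix]
    gen = ~snap
    if gen.any():
        gx, gy = fx[gen], fy[gen]
        ix0 = np.clip(np.floor(gx).astype(int), 0, grid.nx - 2)
        iy0 = np.clip(np.floor(gy).astype(int), 0, grid.ny - 2)
        # local cell coordinates in [0, 1]
        u = gx - ix0
        v = gy - iy0
        zA = grid.z[iy0, ix0]        # corner (0, 0)
        zB = grid.z[iy0, ix0 + 1]    # corner (1, 0)
        zC = grid.z[iy0 + 1, ix0]    # corner (0, 1)
        zD = grid.z[iy0 + 1, ix0 + 1]  # corner (1, 1)
        corners = {
            "A": np.array([0.0, 0.0]),
            "B": np.array([1.0, 0.0]),
            "C": np.array([0.0, 1.0]),
            "D": np.array([1.0, 1.0]),
        }
        # each triangle: right angle at its first vertex, lattice neighbours follow
        tris = (
            (("A", "B", "C"), lambda: zA + (zB - zA) * u + (zC - zA) * v),
            (("B", "A", "D"), lambda: zB + (zA - zB) * (1 - u) + (zD - zB) * v),
            (("C", "A", "D"), lambda: zC + (zA - zC) * (1 - v) + (zD - zC) * u),
            (("D", "B", "C"), lambda: zD + (zB - zD) * (1 - v) + (zC - zD) * (1 - u)),
        )
        q = np.stack([u, v], axis=-1)
        acc = np.zeros(u.shape, float)
        count = np.zeros(u.shape, int)
        best_zeta = np.full(u.shape, -np.inf)
        best_z = np.zeros(u.shape, float)
        for names, plane in tris:
            zeta = _angle_sum_vec(*(corners[n] for n in names), q)
            zt = plane()
            inc = np.abs(zeta - 2 * np.pi) <= ANGLE_TOL
            acc[inc] += zt[inc]
            count[inc] += 1
            better = zeta > best_zeta
            best_zeta[better] = zeta[better]
            best_z[better] = zt[better]
        got = count > 0
        res = np.where(got, acc / np.maximum(count, 1), best_z)
        vals[gen] = res
    out[inside] = vals
    return out


def _angle_sum_vec(v1, v2, v3, q):
    """Angle sum at each query point (…, 2) for a fixed triangle."""
    total = np.zeros(q.shape[:-1], float)
    vs = [v1 - q, v2 - q, v3 - q]
    degenerate = np.zeros(q.shape[:-1], bool)
    for a, b in ((0, 1), (1, 2), (2, 0)):
        ua, ub = vs[a], vs[b]
        na = np.linalg.norm(ua, axis=-1)
        nb = np.linalg.norm(ub, axis=-1)
        degenerate |= (na == 0) | (nb == 0)
        denom = np.where((na == 0) | (nb == 0), 1.0, na * nb)
        cosang = np.clip((ua * ub).sum(axis=-1) / denom, -1.0, 1.0)
        total += np.arccos(cosang)
    total[degenerate] = 2 * np.pi
    return total


def interpolate_z(grid: ScanGrid, p) -> float:
    """Interpolated height at a single source-frame point (0 outside)."""
    return float(_interp_many(grid, np.array([p[0]]), np.array([p[1]]))[0])


def rotate_scan(grid: ScanGrid, center, theta_h: float) -> RotatedGrid:
    """Rotate about ``center`` by ``theta_h`` and resample on the aligned lattice."""
    xlevels, ylevels = rotated_extent(grid, center, theta_h)
    XP, YP = np.meshgrid(xlevels, ylevels)
    sx, sy = inverse_map((XP.ravel(), YP.ravel()), theta_h, center)
    z = _interp_many(grid, sx, sy).reshape(XP.shape)
    # interpolation of nonnegative data stays nonnegative; clip float dust
    np.clip(z, 0.0, None, out=z)
    return RotatedGrid(
        xlevels=xlevels, ylevels=ylevels, z=z, theta_h=float(theta_h),
        center=(float(center[0]), float(center[1])),
    )
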