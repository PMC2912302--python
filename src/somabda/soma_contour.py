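"""Line-wise polynomial delimitation of the soma on the heading-aligned grid.

Every rotated-grid line (fixed y′) is split at the origin into a frontal
(+x′) and a rear (−x′) half, each treated in outward coordinates.  On each
half, least-squares polynomials of degree n (default 3) are fitted to an
increasing number r of consecutive nonzero heights starting at the origin;
among the fits possessing a positive real root, the one with the best
adjusted R² wins, and its smallest positive root is the soma boundary for
that line — a cubic is flexible enough to follow a soma that protrudes into
a process yet still cuts the process off.  Lines with fewer than four
nonzero pixels near the origin (the soma fringe in ±y′, or thin lateral
extensions) are handled by dedicated small-sample rules built from
interpolating parabolas and cubics; these may assign several disjoint
intervals to one line, so the delimited soma may look jagged.  The
procedure always produces a (possibly empty) boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regrid import RotatedGrid
from .volume import SomaRegion

__all__ = [
    "LineProfile",
    "FitCandidate",
    "LineBoundary",
    "line_profile",
    "fit_best",
    "fit_one_point",
    "fit_two_points",
    "fit_three_points",
    "line_boundary",
    "soma_region",
]

_ROOT_IMAG_TOL = 1e-9
_POS_TOL = 1e-9


@dataclass(frozen=True)
class LineProfile:
    """One half-line of the rotated grid in outward coordinates.

    ``xs``/``zs`` run from the origin outward (the rear direction is
    mirrored, so ``xs`` is ascending and nonnegative in both directions).
    ``opposite_z`` is the height at the first lattice position across the
    origin (0 when absent), used to decide whether a fringe line is attached
    to soma mass on the other side.
    """

    yprime: float
    direction: str  # "front" | "rear"
    xs: np.ndarray
    zs: np.ndarray
    dx: float
    opposite_z: float = 0.0

    @property
    def t4(self) -> np.ndarray:
        """Heights at the first four positions (absent positions count as 0)."""
        t = np.zeros(4)
        m = min(4, self.zs.size)
        t[:m] = self.zs[:m]
        return t

    @property
    def N(self) -> int:
        """Number of nonzero heights among the first four positions."""
        return int(np.count_nonzero(self.t4 > 0))

    @property
    def run_len(self) -> int:
        """Length of the maximal gap-free nonzero run starting at the origin."""
        nz = self.zs > 0
        if not nz.size or not nz[0]:
            return 0
        gaps = np.nonzero(~nz)[0]
        return int(gaps[0]) if gaps.size else int(nz.size)


@dataclass(frozen=True)
class FitCandidate:
    """One least-squares fit considered by :func:`fit_best` (diagnostics)."""

    r: int
    degree: int
    coeffs: np.ndarray = field(repr=False)
    goodness: float = float("nan")
    root: float | None = None


@dataclass(frozen=True)
class LineBoundary:
    """Soma intervals for one line and direction, in outward coordinates."""

    yprime: float
    direction: str
    intervals: tuple[tuple[float, float], ...]
    provenance: tuple[str, ...]
    candidates: tuple[FitCandidate, ...] = ()


def line_profile(rgrid: RotatedGrid, yprime: float, direction: str) -> LineProfile:
    """Extract one outward half-line (fixed y′) from the rotated grid."""
    tol = 1e-9 * rgrid.dy
    iy = int(np.argmin(np.abs(rgrid.ylevels - yprime)))
    if abs(rgrid.ylevels[iy] - yprime) > tol:
        raise ValueError(f"y'={yprime} is not a lattice level")
    row = rgrid.z[iy]
    xtol = 1e-9 * rgrid.dx
    if direction == "front":
        sel = rgrid.xlevels >= -xtol
        idx = np.nonzero(sel)[0]
        xs = rgrid.xlevels[idx]
        zs = row[idx]
        opp = row[idx[0] - 1] if idx[0] > 0 else 0.0
    elif direction == "rear":
        sel = rgrid.xlevels <= xtol
        idx = np.nonzero(sel)[0]
        xs = -rgrid.xlevels[idx][::-1]
        zs = row[idx][::-1]
        opp = row[idx[-1] + 1] if idx[-1] + 1 < rgrid.xlevels.size else 0.0
    else:
        raise ValueError("direction must be 'front' or 'rear'")
    return LineProfile(
        yprime=float(yprime), direction=direction, xs=np.abs(xs), zs=zs,
        dx=rgrid.dx, opposite_z=float(opp),
    )


def _smallest_positive_root(coeffs: np.ndarray) -> float | None:
    """Smallest real root > 0 of a polynomial (highest-order coeffs first)."""
    coeffs = np.asarray(coeffs, float)
    scale = np.max(np.abs(coeffs)) if coeffs.size else 0.0
    if scale == 0.0:
        return None
    # numerically vanishing leading coefficients (e.g. a cubic fitted to
    # exactly linear data) would otherwise spawn spurious huge roots
    nz = np.nonzero(np.abs(coeffs) > 1e-12 * scale)[0]
    coeffs = coeffs[nz[0]:]
    if coeffs.size < 2:
        return None
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < _ROOT_IMAG_TOL].real
    pos = real[real > _POS_TOL]
    return float(pos.min()) if pos.size else None


def _adjusted_r2(x: np.ndarray, z: np.ndarray, coeffs: np.ndarray, degree: int) -> float:
    resid = z - np.polyval(coeffs, x)
    sse = float(resid @ resid)
    sst = float(((z - z.mean()) ** 2).sum())
    dof = x.size - degree - 1
    if sst <= 0 or dof <= 0:
        return float("-inf")
    return 1.0 - (sse / sst) * (x.size - 1) / dof


def _polyfit(x: np.ndarray, z: np.ndarray, degree: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        return np.polyfit(x, z, degree)


def fit_best(profile: LineProfile, n: int = 3):
    """Best-goodness polynomial boundary for a well-populated line.

    For each degree from ``n`` down to 1: least-squares fits to the first
    r = deg+2 … run-length points are compared by adjusted R²; the winning
    fit is used if it possesses a positive real root — a best fit without a
    root means the line's contour gives the polynomial no zero crossing to
    delimit at, so the interpolating polynomial through the first deg+1
    points is tried instead.  If every degree is rootless the boundary is
    placed half a step beyond the last nonzero run point.
    Returns ``(intervals, provenance, candidates)``.
    """
    run = profile.run_len
    xs, zs = profile.xs[:run], profile.zs[:run]
    cands: list[FitCandidate] = []
    for deg in range(n, 0, -1):
        best: FitCandidate | None = None
        for r in range(deg + 2, run + 1):
            coeffs = _polyfit(xs[:r], zs[:r], deg)
            root = _smallest_positive_root(coeffs)
            g = _adjusted_r2(xs[:r], zs[:r], coeffs, deg)
            cand = FitCandidate(r=r, degree=deg, coeffs=coeffs, goodness=g, root=root)
            cands.append(cand)
            if np.isfinite(g) and (best is None or g > best.goodness):
                best = cand
        if best is not None and best.root is not None:
            return [(0.0, best.root)], ["fitBest"], cands
        if run >= deg + 1:
            coeffs = _polyfit(xs[: deg + 1], zs[: deg + 1], deg)
            root = _smallest_positive_root(coeffs)
            cands.append(FitCandidate(r=deg + 1, degree=deg, coeffs=coeffs, root=root))
            if root is not None:
                return [(0.0, root)], ["fitBest"], cands
    return [(0.0, float(xs[-1] + profile.dx / 2))], ["fallback"], cands


def fit_one_point(profile: LineProfile):
    """Single nonzero pixel near the origin: parabola through it, or crop.

    The parabola has its vertex at the pixel and zeros one step to either
    side — the only symmetric parabola fixed by one sample and the lattice
    scale.  An isolated pixel at the fourth position is detached from the
    soma and cropped.
    """
    t4 = profile.t4
    (u,) = (np.nonzero(t4 > 0)[0] + 1).tolist()
    return _one_point_interval(profile, u)


def _one_point_interval(profile: LineProfile, u: int):
    if u >= 4:
        return [], []
    xu = profile.xs[u - 1]
    return [(max(0.0, xu - profile.dx), xu + profile.dx)], ["onePoint"]


def _pair_interval(profile: LineProfile, u: int, v: int):
    """Adjacent nonzero pair: cubic with flanking zeros, or crop if detached.

    The cubic through the two pixels and the zeros one step outside each has
    those zeros as roots by construction, so the interval runs between them.
    A pair ending at the fourth position with nothing but zeros between it
    and the origin is treated as a detached structure and cropped.
    """
    t4 = profile.t4
    if v == 4 and not np.any(t4[: u - 1] > 0):
        return [], []
    xlo = profile.xs[u - 1] - profile.dx
    xhi = profile.xs[v - 1] + profile.dx
    return [(max(0.0, xlo), xhi)], ["twoPoints"]


def fit_two_points(profile: LineProfile):
    """Two nonzero pixels among the first four positions."""
    t4 = profile.t4
    u, v = (np.nonzero(t4 > 0)[0] + 1).tolist()
    if v - u == 1:
        return _pair_interval(profile, u, v)
    ivals, prov = _one_point_interval(profile, u)
    return ivals, ["twoPoints"] * len(ivals)


def _interp_cubic_interval(points, fallback_x: float, dx: float):
    """Interval [0, smallest positive root] of the cubic through 4 points."""
    pts = np.asarray(points, float)
    coeffs = _polyfit(pts[:, 0], pts[:, 1], 3)
    root = _smallest_positive_root(coeffs)
    if root is None:
        return [(0.0, fallback_x + dx / 2)], ["fallback"]
    return [(0.0, root)], ["threePoints"]


def fit_three_points(profile: LineProfile):
    """Three nonzero pixels among the first four positions.

    The single zero's position decides the strategy: a zero at the origin
    with soma mass just across it means the soma is asymmetric and the line
    is continued through the opposite-side height; a zero at the origin with
    nothing opposite anchors the cubic at (origin, 0); a zero in the middle
    splits the line into an isolated pixel and an adjacent pair; a zero at
    the fourth position closes the cubic there unless the opposite side
    carries mass.
    """
    t4 = profile.t4
    xs, zs, dx = profile.xs, profile.zs, profile.dx
    (u,) = (np.nonzero(t4 <= 0)[0] + 1).tolist()
    if u == 1:
        pts = [(xs[1], zs[1]), (xs[2], zs[2]), (xs[3], zs[3])]
        if profile.opposite_z > 0:
            pts.insert(0, (xs[0] - dx, profile.opposite_z))
        else:
            pts.insert(0, (xs[0], 0.0))
        return _interp_cubic_interval(pts, xs[3], dx)
    if u in (2, 3):
        iso, pair = (1, (3, 4)) if u == 2 else (4, (1, 2))
        ivals, prov = _one_point_interval(profile, iso)
        piv, pprov = _pair_interval(profile, *pair)
        return ivals + piv, ["threePoints"] * (len(ivals) + len(piv))
    # u == 4: zero at the fourth position
    pts = [(xs[0], zs[0]), (xs[1], zs[1]), (xs[2], zs[2])]
    if profile.opposite_z > 0:
        pts.insert(0, (xs[0] - dx, profile.opposite_z))
    else:
        pts.append((xs[3], 0.0))
    return _interp_cubic_interval(pts, xs[2], dx)


def _merge(intervals, provenance):
    """Sort and merge touching/overlapping closed intervals."""
    if not intervals:
        return (), ()
    order = np.argsort([a for a, _ in intervals])
    merged = []
    prov = []
    for k in order:
        a, b = intervals[k]
        p = provenance[k]
        if merged and a <= merged[-1][1] + 1e-12:
            pa, pb = merged[-1]
            merged[-1] = (pa, max(pb, b))
            if p not in prov[-1]:
                prov[-1] = prov[-1] + "+" + p
        else:
            merged.append((float(a), float(b)))
            prov.append(p)
    return tuple(merged), tuple(prov)


def line_boundary(rgrid: RotatedGrid, yprime: float, direction: str, n: int = 3) -> LineBoundary:
    """Delimit the soma on one line and direction (never raises)."""
    profile = line_profile(rgrid, yprime, direction)
    cands: tuple[FitCandidate, ...] = ()
    N = profile.N
    if N == 0:
        ivals, prov = [], []
    elif N == 4:
        ivals, prov, cl = fit_best(profile, n=n)
        cands = tuple(cl)
    elif N == 3:
        ivals, prov = fit_three_points(profile)
    elif N == 2:
        ivals, prov = fit_two_points(profile)
    else:
        ivals, prov = fit_one_point(profile)
    ivals, prov = _merge(ivals, prov)
    return LineBoundary(
        yprime=float(yprime), direction=direction,
        intervals=ivals, provenance=prov, candidates=cands,
    )


def soma_region(rgrid: RotatedGrid, n: int = 3) -> SomaRegion:
    """Union of line boundaries over all y′ levels and both directions."""
    boundaries = []
    mask = np.zeros_like(rgrid.z, dtype=bool)
    boundary_points = []
    xtol = 1e-9 * rgrid.dx
    for iy, yp in enumerate(rgrid.ylevels):
        for direction in ("front", "rear"):
            lb = line_boundary(rgrid, yp, direction, n=n)
            boundaries.append(lb)
            sign = 1.0 if direction == "front" else -1.0
            for a, b in lb.intervals:
                x_signed = sign * rgrid.xlevels
                inside = (x_signed >= a - xtol) & (x_signed <= b + xtol)
                mask[iy] |= inside
                boundary_points.append((sign * b, float(yp)))
                if a > xtol:
                    boundary_points.append((sign * a, float(yp)))
    return SomaRegion(boundaries=tuple(boundaries), mask=mask, boundary_points=tuple(boundary_points))
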