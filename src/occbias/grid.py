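"""Eckert IV equal-area projection and global square-cell indexing.

The projection maps geographic coordinates on a sphere of radius ``R`` to
planar metres.  The parametric latitude ``theta`` solves

    theta + sin(theta)*cos(theta) + 2*sin(theta) = (2 + pi/2) * sin(lat)

after which

    x = 2 / sqrt(pi * (4 + pi)) * R * lam * (1 + cos(theta))
    y = 2 * sqrt(pi / (4 + pi)) * R * sin(theta)

with ``lam`` the longitude in radians.  Cells are indexed by strict floor
division of the planar coordinates, anchored at the equator / central
meridian intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "AUTHALIC_RADIUS_M",
    "DEFAULT_CELL_SIZE_M",
    "ProjectedPoint",
    "GridCell",
    "solve_theta",
    "project",
    "assign_cell",
    "count_distinct_cells",
]

#: Authalic Earth radius in metres (sphere with the WGS84 ellipsoid's area).
AUTHALIC_RADIUS_M = 6_371_007.181

#: Default grid cell edge, metres.
DEFAULT_CELL_SIZE_M = 10_000.0

_C = 2.0 + math.pi / 2.0
_CX = 2.0 / math.sqrt(math.pi * (4.0 + math.pi))
_CY = 2.0 * math.sqrt(math.pi / (4.0 + math.pi))


@dataclass(frozen=True)
class ProjectedPoint:
    """Planar position in metres east/north of the projection origin."""

    x: float
    y: float


@dataclass(frozen=True)
class GridCell:
    """Integer cell index; ``i`` counts columns east, ``j`` rows north."""

    i: int
    j: int
    cell_size: float = DEFAULT_CELL_SIZE_M


def _theta_equation(theta: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    return theta + np.sin(theta) * np.cos(theta) + 2.0 * np.sin(theta) - rhs


def solve_theta(lat: np.ndarray | float, tol: float = 1e-12, max_iter: int = 50) -> np.ndarray:
    """Solve the parametric-latitude equation by damped Newton iteration.

    Falls back to bisection for any element that has not reached
    ``|residual| < tol`` after ``max_iter`` Newton steps (the derivative
    vanishes at the poles).  Returns ``theta`` in radians, odd in ``lat``.
    """
    lat_arr = np.atleast_1d(np.asarray(lat, dtype=float))
    rhs = _C * np.sin(np.radians(lat_arr))
    theta = np.radians(lat_arr) / 2.0
    half_pi = math.pi / 2.0
    step = np.full_like(theta, np.inf)
    for _ in range(max_iter):
        resid = _theta_equation(theta, rhs)
        deriv = 2.0 * np.cos(theta) * (1.0 + np.cos(theta))
        # Damp the step where the derivative is tiny (near the poles).
        step = resid / np.maximum(deriv, 1e-9)
        theta = np.clip(theta - step, -half_pi, half_pi)
        if np.all(np.abs(step) < 1e-15):
            break
    # Step size, not residual, measures theta error: the derivative
    # vanishes at the poles.  Polish stragglers by bisection.
    resid = _theta_equation(theta, rhs)
    bad = (np.abs(step) >= 1e-13) & (np.abs(resid) >= tol * 1e-3)
    exact_pole = np.abs(np.abs(lat_arr) - 90.0) < 1e-13
    theta[exact_pole] = np.sign(lat_arr[exact_pole]) * half_pi
    bad &= ~exact_pole
    if np.any(bad):
        for k in np.flatnonzero(bad):
            theta[k] = _bisect_theta(float(rhs[k]))
    return theta


def _bisect_theta(rhs: float, width: float = 1e-16) -> float:
    """Bisect to interval width below float64 resolution (pole-safe)."""
    lo, hi = -math.pi / 2.0, math.pi / 2.0
    flo = _theta_equation(np.array(lo), np.array(rhs)).item()
    while hi - lo > width:
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        fmid = _theta_equation(np.array(mid), np.array(rhs)).item()
        if (flo < 0) == (fmid < 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def project(
    lat: np.ndarray | float,
    lon: np.ndarray | float,
    R: float = AUTHALIC_RADIUS_M,
) -> tuple[np.ndarray, np.ndarray]:
    """Project latitude/longitude (degrees) to Eckert IV planar metres.

    ``lat`` must lie in [-90, 90] and ``lon`` in [-180, 180); violations
    raise ``ValueError``.  Accepts scalars or arrays; returns ``(x, y)``
    arrays of the broadcast shape.
    """
    lat_arr, lon_arr = np.broadcast_arrays(
        np.atleast_1d(np.asarray(lat, dtype=float)),
        np.atleast_1d(np.asarray(lon, dtype=float)),
    )
    if np.any((lat_arr < -90.0) | (lat_arr > 90.0)) or np.any(np.isnan(lat_arr)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon_arr < -180.0) | (lon_arr >= 180.0)) or np.any(np.isnan(lon_arr)):
        raise ValueError("longitude out of [-180, 180)")
    theta = solve_theta(lat_arr)
    lam = np.radians(lon_arr)
    x = _CX * R * lam * (1.0 + np.cos(theta))
    y = _CY * R * np.sin(theta)
    return x, y


def project_point(lat: float, lon: float, R: float = AUTHALIC_RADIUS_M) -> ProjectedPoint:
    """Scalar convenience wrapper around :func:`project`."""
    x, y = project(lat, lon, R)
    return ProjectedPoint(float(x[0]), float(y[0]))


def assign_cell(
    x: np.ndarray | float,
    y: np.ndarray | float,
    cell_size: float = DEFAULT_CELL_SIZE_M,
) -> tuple[np.ndarray, np.ndarray]:
    """Map planar metres to integer cell indices with strict floor semantics."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    i = np.floor(np.atleast_1d(np.asarray(x, dtype=float)) / cell_size).astype(np.int64)
    j = np.floor(np.atleast_1d(np.asarray(y, dtype=float)) / cell_size).astype(np.int64)
    return i, j


def assign_cell_point(p: ProjectedPoint, cell_size: float = DEFAULT_CELL_SIZE_M) -> GridCell:
    i, j = assign_cell(p.x, p.y, cell_size)
    return GridCell(int(i[0]), int(j[0]), cell_size)


def count_distinct_cells(
    lats: Iterable[float],
    lons: Iterable[float],
    cell_size: float = DEFAULT_CELL_SIZE_M,
    R: float = AUTHALIC_RADIUS_M,
) -> int:
    """Number of distinct grid cells occupied by the given coordinates.

    Entries with a missing latitude or longitude (NaN) are dropped before
    counting; an empty input yields 0.
    """
    lat_arr = np.asarray(list(lats) if not isinstance(lats, np.ndarray) else lats, dtype=float)
    lon_arr = np.asarray(list(lons) if not isinstance(lons, np.ndarray) else lons, dtype=float)
    ok = ~(np.isnan(lat_arr) | np.isnan(lon_arr))
    lat_arr, lon_arr = lat_arr[ok], lon_arr[ok]
    if lat_arr.size == 0:
        return 0
    x, y = project(lat_arr, lon_arr, R)
    i, j = assign_cell(x, y, cell_size)
    return len(np.unique(np.stack([i, j], axis=1), axis=0))
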