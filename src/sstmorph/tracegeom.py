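"""Geometry of 3D side traces: arc length, resampling, averaging, tangents.

All coordinates are physical (x, y, z) in micrometres.  Polylines are
piecewise linear; arc length is the sum of Euclidean segment lengths,
and interpolation between vertices is linear (no overshoot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Polyline3D",
    "CenterlineSample",
    "arclength",
    "resample_equidistant",
    "average_trace",
    "tangent_at",
    "sample_centerline",
]


@dataclass(frozen=True)
class Polyline3D:
    """Ordered sequence of >= 2 distinct 3D points (x, y, z) in um."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("a polyline needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            i = int(np.flatnonzero(seg == 0)[0])
            raise ValueError(f"consecutive points {i} and {i + 1} coincide")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def total_length(self) -> float:
        return arclength(self)[0]


@dataclass(frozen=True)
class CenterlineSample:
    """One sampling locus on a centerline.

    position : (x, y, z) um; s : arc-length distance from the orifice, um;
    tangent : unit vector of the local tube direction.
    """

    position: np.ndarray
    s: float
    tangent: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        t = np.asarray(self.tangent, dtype=float)
        n = np.linalg.norm(t)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"tangent must be unit length, |t| = {n}")
        object.__setattr__(self, "tangent", t)


def arclength(trace: Polyline3D) -> tuple[float, np.ndarray]:
    """Total arc length and the cumulative length at each vertex.

    Returns
    -------
    total : float
        Sum of Euclidean segment lengths, um.
    cumulative : ndarray, shape (N,)
        Non-decreasing, ``cumulative[0] == 0``, ``cumulative[-1] == total``.
    """
    pts = trace.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cumulative = np.concatenate([[0.0], np.cumsum(seg)])
    return float(cumulative[-1]), cumulative


def _interp_at(trace: Polyline3D, s_targets: np.ndarray) -> np.ndarray:
    """Linear interpolation of vertex coordinates at arc-length positions."""
    _, cum = arclength(trace)
    pts = trace.points
    out = np.empty((len(s_targets), 3))
    for axis in range(3):
        out[:, axis] = np.interp(s_targets, cum, pts[:, axis])
    return out


def resample_equidistant(trace: Polyline3D, n: int) -> Polyline3D:
    """Resample to ``n`` points at arc-length positions k*L/(n-1), k=0..n-1.

    The first and last output points coincide exactly with the input
    endpoints; consecutive spacings are equal to 1e-6 relative.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    total, _ = arclength(trace)
    s_targets = np.linspace(0.0, total, n)
    out = _interp_at(trace, s_targets)
    out[0] = trace.points[0]
    out[-1] = trace.points[-1]
    return Polyline3D(out)


def average_trace(side_a: Polyline3D, side_b: Polyline3D, n_dense: int = 200) -> Polyline3D:
    """Midline of two side traces of the same tubule.

    Both traces must run orifice -> blind end.  Each is resampled to
    ``n_dense`` points by normalized arc length and the output is the
    pointwise midpoint of corresponding pairs — a parameter-free,
    symmetric pairing that copes with unequal vertex counts.
    """
    a0, aL = side_a.points[0], side_a.points[-1]
    b0, bL = side_b.points[0], side_b.points[-1]
    if np.linalg.norm(a0 - bL) < np.linalg.norm(a0 - b0):
        raise ValueError(
            "side traces appear to run in opposite directions "
            "(the start of one is nearest the end of the other); "
            "reverse one trace so both run orifice -> blind end"
        )
    ra = resample_equidistant(side_a, n_dense).points
    rb = resample_equidistant(side_b, n_dense).points
    return Polyline3D(0.5 * (ra + rb))


def tangent_at(trace: Polyline3D, index: int) -> np.ndarray:
    """Unit direction vector from the nearest neighboring vertices.

    Interior vertices use the central difference p[i+1] - p[i-1];
    endpoints use a one-sided difference.
    """
    pts = trace.points
    n = len(trace)
    if not -n <= index < n:
        raise IndexError(f"index {index} out of range for polyline of {n} points")
    index %= n
    if index == 0:
        d = pts[1] - pts[0]
    elif index == n - 1:
        d = pts[-1] - pts[-2]
    else:
        d = pts[index + 1] - pts[index - 1]
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError(f"coincident neighbor points around index {index}")
    return d / norm


def sample_centerline(
    trace: Polyline3D, n: int = 10, last_point_offset: float = 0.0
) -> list[CenterlineSample]:
    """Sample ``n`` equidistant loci with arc-length and local direction.

    The first sample sits at the orifice (s = 0) and the last at
    ``L - last_point_offset`` (default: the final vertex).  Tangents are
    central differences on the resampled polyline.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    total, _ = arclength(trace)
    if not 0.0 <= last_point_offset < total:
        raise ValueError("last_point_offset must lie in [0, total length)")
    s_targets = np.linspace(0.0, total - last_point_offset, n)
    pts = _interp_at(trace, s_targets)
    pts[0] = trace.points[0]
    resampled = Polyline3D(pts)
    return [
        CenterlineSample(position=pts[i], s=float(s_targets[i]), tangent=tangent_at(resampled, i))
        for i in range(n)
    ]
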