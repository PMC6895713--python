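"""Oblique 2D sections through 3D voxel volumes.

Volumes are indexed (z, y, x) with anisotropic spacing allowed; physical
coordinates are (x, y, z) in um with voxel centers at (index + 0.5) * spacing.
Sections are sampled by trilinear interpolation on planes normal to an
arbitrary direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = ["VoxelVolume", "ObliqueSlice", "plane_basis", "extract_slice"]


@dataclass(frozen=True)
class VoxelVolume:
    """3D intensity grid with physical voxel spacing.

    data : ndarray (z, y, x); spacing : (sz, sy, sx) um per voxel.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got ndim={data.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", sp)

    @property
    def physical_size(self) -> tuple[float, float, float]:
        """(x, y, z) extent in um."""
        nz, ny, nx = self.data.shape
        sz, sy, sx = self.spacing
        return (nx * sx, ny * sy, nz * sz)

    def contains(self, point_xyz: np.ndarray) -> bool:
        x, y, z = np.asarray(point_xyz, dtype=float)
        ex, ey, ez = self.physical_size
        return 0.0 <= x <= ex and 0.0 <= y <= ey and 0.0 <= z <= ez


@dataclass(frozen=True)
class ObliqueSlice:
    """A 2D section through a volume.

    ``image[row, col]`` lies at ``origin + a*basis_u + b*basis_v`` where
    ``a = (col - center_pixel[1]) * in_plane_spacing`` and
    ``b = (row - center_pixel[0]) * in_plane_spacing``.  ``valid`` flags
    pixels sampled inside the volume (others hold the fill value).
    """

    image: np.ndarray
    valid: np.ndarray
    in_plane_spacing: float
    center_pixel: tuple[int, int]
    basis_u: np.ndarray
    basis_v: np.ndarray
    normal: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        for name in ("basis_u", "basis_v", "normal", "origin"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        u, v, n = self.basis_u, self.basis_v, self.normal
        for vec, name in ((u, "basis_u"), (v, "basis_v"), (n, "normal")):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit vector")
        if max(abs(u @ v), abs(u @ n), abs(v @ n)) > 1e-9:
            raise ValueError("basis_u, basis_v, normal must be mutually orthogonal")


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed orthonormal in-plane frame for a normal.

    u = normalize(normal x e) with e the global axis least parallel to the
    normal (ties broken in order x, y, z); v = normal x u.  Then
    (u, v, normal) is right-handed: u x v = normal.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("normal must be a non-zero vector")
    n = n / norm
    e = np.zeros(3)
    e[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, e)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def extract_slice(
    volume: VoxelVolume,
    origin: np.ndarray,
    normal: np.ndarray,
    half_width: float,
    spacing: float | None = None,
    fill: float = 0.0,
) -> ObliqueSlice:
    """Square section of side 2*half_width normal to ``normal`` at ``origin``.

    Pixels are trilinearly interpolated at physical positions
    ``origin + a*u + b*v``; positions outside the volume receive ``fill``
    and are flagged False in the validity mask.  In-plane pixel spacing
    defaults to the smallest voxel spacing of the source volume.

    Raises
    ------
    ValueError
        If ``origin`` lies outside the volume, or parameters are invalid.
    """
    origin = np.asarray(origin, dtype=float)
    if spacing is None:
        spacing = min(volume.spacing)
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if half_width <= 0:
        raise ValueError(f"half_width must be > 0, got {half_width}")
    if not volume.contains(origin):
        raise ValueError(
            f"slice origin {tuple(origin)} um lies outside the volume "
            f"(physical extent {volume.physical_size} um)"
        )
    u, v = plane_basis(normal)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)

    n_half = int(round(half_width / spacing))
    offsets = (np.arange(2 * n_half + 1) - n_half) * spacing
    a, b = np.meshgrid(offsets, offsets)  # a varies along columns, b along rows
    pos = origin[None, None, :] + a[..., None] * u[None, None, :] + b[..., None] * v[None, None, :]

    sz, sy, sx = volume.spacing
    # physical (x, y, z) -> fractional array indices (z, y, x); centers at idx+0.5
    iz = pos[..., 2] / sz - 0.5
    iy = pos[..., 1] / sy - 0.5
    ix = pos[..., 0] / sx - 0.5
    shape = volume.data.shape
    valid = (
        (iz >= 0) & (iz <= shape[0] - 1)
        & (iy >= 0) & (iy <= shape[1] - 1)
        & (ix >= 0) & (ix <= shape[2] - 1)
    )
    image = ndi.map_coordinates(
        volume.data.astype(float, copy=False),
        np.stack([iz, iy, ix]),
        order=1,
        mode="constant",
        cval=fill,
    )
    image[~valid] = fill
    return ObliqueSlice(
        image=image,
        valid=valid,
        in_plane_spacing=float(spacing),
        center_pixel=(n_half, n_half),
        basis_u=u,
        basis_v=v,
        normal=n,
        origin=origin,
    )
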