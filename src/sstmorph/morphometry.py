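"""Cross-sectional measurement of tubules: d1, d2, circularity, mean diameter.

The measured object is the envelope of punctate fluorescence around a dark
lumen; each section is smoothed, thresholded, hole-filled, and summarized by
the moment-equivalent ellipse of the connected component at the slice center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .obliqueslice import ObliqueSlice, VoxelVolume, extract_slice
from .tracegeom import Polyline3D, arclength, average_trace, sample_centerline

__all__ = [
    "AxisMeasurement",
    "SSTRecord",
    "MeasureConfig",
    "TubeNotFoundError",
    "preprocess_for_tracing",
    "measure_axes",
    "circularity",
    "measure_sst",
]


class TubeNotFoundError(ValueError):
    """Raised when no foreground component surrounds the slice center."""


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


@dataclass(frozen=True)
class AxisMeasurement:
    """Major/minor axis diameters of one cross-section, um, at arc length s."""

    d1: float
    d2: float
    s: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.d1 >= self.d2 > 0:
            raise ValueError(f"require d1 >= d2 > 0, got d1={self.d1}, d2={self.d2}")

    @property
    def circularity(self) -> float:
        return self.d1 / self.d2

    @property
    def mean_diameter(self) -> float:
        return 0.5 * (self.d1 + self.d2)


@dataclass(frozen=True)
class SSTRecord:
    """All measurements for one tubule, ordered by distance from the orifice."""

    bird_id: str
    sst_id: str
    total_length: float
    measurements: tuple[AxisMeasurement, ...]

    def __post_init__(self) -> None:
        m = tuple(self.measurements)
        s = [x.s for x in m]
        if s != sorted(s):
            raise ValueError("measurements must be sorted by s")
        if m and m[0].s != 0.0:
            raise ValueError("first measurement must be at the orifice (s = 0)")
        object.__setattr__(self, "measurements", m)


@dataclass(frozen=True)
class MeasureConfig:
    """Parameters of the per-slice measurement pipeline."""

    n_points: int = 10
    half_width: float = 30.0  # um; covers the widest observed sections
    slice_spacing: float | None = None  # um/pixel; None -> min voxel spacing
    smoothing_sigma: float = 1.0  # um, in-plane
    threshold_method: str | tuple[str, float] = "otsu"
    estimator: str = "moment"  # or "feret"
    n_dense: int = 200
    last_point_offset: float = 0.0


def preprocess_for_tracing(
    volume: VoxelVolume, dilation_radius: float, gaussian_sigma: float
) -> VoxelVolume:
    """Grayscale ball dilation followed by Gaussian blur, to smooth punctate
    signal before side-tracing.  Radii/sigmas are physical (um) and are
    converted per axis to voxels; shape and spacing are preserved.
    """
    if dilation_radius < 0 or gaussian_sigma < 0:
        raise ValueError("dilation_radius and gaussian_sigma must be >= 0")
    data = volume.data.astype(float, copy=True)
    if dilation_radius > 0:
        rz, ry, rx = (max(int(round(dilation_radius / s)), 0) for s in volume.spacing)
        zz, yy, xx = np.mgrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
        sz, sy, sx = volume.spacing
        ball = (zz * sz) ** 2 + (yy * sy) ** 2 + (xx * sx) ** 2 <= dilation_radius**2
        data = ndi.grey_dilation(data, footprint=ball)
    if gaussian_sigma > 0:
        data = ndi.gaussian_filter(data, sigma=[gaussian_sigma / s for s in volume.spacing])
    return VoxelVolume(data=data, spacing=volume.spacing)


def _threshold(pixels: np.ndarray, method: str | tuple[str, float]) -> float:
    if np.ptp(pixels) == 0 and not (isinstance(method, tuple) and method[0] == "fixed"):
        raise TubeNotFoundError("slice has constant intensity; cannot threshold")
    if method == "otsu":
        return float(threshold_otsu(pixels))
    if method == "halfmax":
        # FWHM-style: half of the near-peak intensity; on a blurred wall the
        # half-maximum contour tracks the emitter envelope, where Otsu lands
        # low and inflates the section outward
        return float(0.5 * np.percentile(pixels, 99.5))
    if isinstance(method, tuple) and len(method) == 2 and method[0] == "fixed":
        return float(method[1])
    raise ValueError(f"unknown threshold method: {method!r}")


def _min_feret(coords: np.ndarray, n_angles: int = 180) -> float:
    """Smallest projection width of a pixel set over rotated directions."""
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = coords @ dirs.T
    return float(np.min(np.ptp(proj, axis=0) + 1.0))


def measure_axes(
    slc: ObliqueSlice,
    smoothing_sigma: float = 1.0,
    threshold_method: str | tuple[str, float] = "otsu",
    estimator: str = "moment",
) -> tuple[float, float]:
    """Major and minor axis diameters (d1 >= d2, um) of the tube section.

    Pipeline: Gaussian-smooth; threshold (Otsu on valid pixels by default);
    fill internal holes (the dark lumen); take the 4-connected component
    containing the slice center; summarize with the moment-equivalent
    ellipse (or min/max Feret diameters with ``estimator="feret"``).

    Raises
    ------
    TubeNotFoundError
        If the center pixel is not inside any filled foreground component.
    """
    if not slc.valid[slc.center_pixel]:
        raise TubeNotFoundError("slice center is outside the volume")
    img = slc.image.astype(float, copy=False)
    if smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=smoothing_sigma / slc.in_plane_spacing)
    thr = _threshold(img[slc.valid], threshold_method)
    mask = (img >= thr) & slc.valid
    # bridge small azimuthal gaps in the granular wall so the lumen is a
    # closed hole; a 2-pixel closing cannot move the envelope materially
    # (union keeps closing extensive despite scipy's border erosion)
    mask = mask | ndi.binary_closing(mask, structure=_disk(2), border_value=0)
    filled = ndi.binary_fill_holes(mask)
    labels = label(filled, connectivity=1)
    lab = labels[slc.center_pixel]
    if lab == 0:
        raise TubeNotFoundError("tube not found at slice center")
    region_mask = labels == lab
    rows, cols = np.nonzero(region_mask)
    touches = (
        rows.min() == 0
        or cols.min() == 0
        or rows.max() == region_mask.shape[0] - 1
        or cols.max() == region_mask.shape[1] - 1
    )
    if touches:
        warnings.warn(
            "measured component touches the slice border; section may be truncated",
            stacklevel=2,
        )
    if estimator == "moment":
        props = regionprops(region_mask.astype(np.uint8))[0]
        d1 = props.axis_major_length * slc.in_plane_spacing
        d2 = props.axis_minor_length * slc.in_plane_spacing
    elif estimator == "feret":
        props = regionprops(region_mask.astype(np.uint8))[0]
        coords = np.column_stack(np.nonzero(region_mask)).astype(float)
        d1 = props.feret_diameter_max * slc.in_plane_spacing
        d2 = _min_feret(coords) * slc.in_plane_spacing
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    if d2 > d1:
        d1, d2 = d2, d1
    return float(d1), float(d2)


def circularity(d1: float, d2: float) -> float:
    """Ratio of major to minor axis diameter; 1 means a circular section.

    The larger argument is treated as the major axis regardless of order.
    """
    lo, hi = min(d1, d2), max(d1, d2)
    if lo <= 0:
        raise ValueError(f"diameters must be positive, got d1={d1}, d2={d2}")
    return hi / lo


def measure_sst(
    volume: VoxelVolume,
    side_a: Polyline3D,
    side_b: Polyline3D,
    config: MeasureConfig = MeasureConfig(),
    bird_id: str = "",
    sst_id: str = "",
) -> SSTRecord:
    """Measure one tubule end to end.

    Averages the two side traces into a luminal centerline, samples it at
    ``config.n_points`` equidistant loci, extracts a section normal to the
    local direction at each locus from the *unprocessed* volume, and
    measures d1/d2 on every section.
    """
    center = average_trace(side_a, side_b, n_dense=config.n_dense)
    total, _ = arclength(center)
    samples = sample_centerline(
        center, n=config.n_points, last_point_offset=config.last_point_offset
    )
    measurements = []
    for i, sample in enumerate(samples):
        try:
            slc = extract_slice(
                volume,
                origin=sample.position,
                normal=sample.tangent,
                half_width=config.half_width,
                spacing=config.slice_spacing,
            )
            d1, d2 = measure_axes(
                slc,
                smoothing_sigma=config.smoothing_sigma,
                threshold_method=config.threshold_method,
                estimator=config.estimator,
            )
        except (ValueError, TubeNotFoundError) as exc:
            raise RuntimeError(
                f"measurement failed at sample {i} (s = {sample.s:.2f} um): {exc}"
            ) from exc
        measurements.append(AxisMeasurement(d1=d1, d2=d2, s=sample.s))
    return SSTRecord(
        bird_id=bird_id,
        sst_id=sst_id,
        total_length=total,
        measurements=tuple(measurements),
    )
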