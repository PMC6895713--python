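import numpy as np
import pytest

from sstmorph import morphometry as mm
from sstmorph import synthgen as sg


def helix(radius=3.0, pitch=2 * np.pi, turns=2.0, n=1000):
    """Polygonal helix; closed-form arc length is 2*pi*turns*sqrt(r^2+b^2)
    with b = pitch/(2*pi)."""
    theta = np.linspace(0.0, 2 * np.pi * turns, n)
    b = pitch / (2 * np.pi)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), b * theta])
    from sstmorph.tracegeom import Polyline3D

    return Polyline3D(pts), theta, b


def arc_positions(poly, points):
    """Arc-length position of each query point along a polyline (oracle:
    exhaustive projection onto every segment)."""
    pts = poly.points
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    out = []
    for q in np.asarray(points, float):
        rel = q - pts[:-1]
        t = np.clip(np.einsum("ij,ij->i", rel, seg) / seglen**2, 0.0, 1.0)
        proj = pts[:-1] + t[:, None] * seg
        d = np.linalg.norm(proj - q, axis=1)
        j = int(np.argmin(d))
        out.append(cum[j] + t[j] * seglen[j])
    return np.array(out)


def cylinder_scene(
    d=10.0,
    length=100.0,
    ellipticity=1.0,
    seed=3,
    spacing=0.5,
    density_per_um_diameter=30.0,
    blur_sigma=0.5,
):
    """Straight synthetic tube along +x with wall granules, plus jitter-free
    side traces.  Wall thickness scales with the tube so the lumen stays
    open at small diameters."""
    thickness = float(np.clip(d / 5.0, 1.8, 2.5))
    c = 25.0 + d
    n_side = int(np.ceil(2 * c / spacing)) + 40
    ctrl = np.column_stack(
        [np.linspace(20, 20 + length, 50), np.full(50, c), np.full(50, c)]
    )
    geom = sg.SSTGeometry(
        centerline_control_points=ctrl,
        total_length=length,
        diameter_profile=(d, 0.0, 0.0),
        ellipticity=ellipticity,
    )
    cfg = sg.RenderConfig(
        volume_shape=(n_side, n_side, int(np.ceil((length + 60) / spacing))),
        voxel_spacing=(spacing, spacing, spacing),
        granule_density=density_per_um_diameter * d,
        granule_sigma=0.45,
        epithelium_thickness=thickness,
        blur_sigma=blur_sigma,
        seed=seed,
    )
    volume, gt = sg.render_sst(geom, cfg)
    side_a, side_b = sg.simulate_side_traces(gt, jitter_sd=0.0, seed=seed + 1)
    return volume, gt, side_a, side_b


MEASURE_CONFIG = mm.MeasureConfig(
    half_width=20.0, smoothing_sigma=0.8, threshold_method="halfmax"
)


@pytest.fixture(scope="session")
def cylinder10():
    """Noise-free d = 10 um cylinder scene reused across tests."""
    return cylinder_scene(d=10.0)
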