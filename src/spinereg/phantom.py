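"""Procedural vertebra phantom and simulated biplanar C-arm acquisition.

This module stands in for the physical rig a cadaver/saw-bone study needs:
a vertebra-like CT volume built from analytic geometric primitives (a
cylindrical vertebral body with cortical shell and trabecular interior,
posterior-element ellipsoids, a spinal canal, and radio-opaque spherical
fiducial markers), plus a simulated C-arm that renders AP and LA views of
the phantom at a known ground-truth pose and corrupts them with additive
Gaussian intensity noise and optional dark instrument overlays.

Because every primitive has exact analytic membership, voxelization can be
verified against a brute-force point-in-primitive oracle, and the generating
pose provides exact ground truth for registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _fill_polygon

from .drr import RoiBox, Volume, render_drr
from .geometry import Pose, ProjectionModel

__all__ = ["PhantomSpec", "RadiographPair", "InstrumentSpec", "default_phantom_spec",
           "default_models", "make_phantom_volume", "simulate_carm_pair",
           "detect_markers", "make_test_scene"]

# Seven asymmetric, non-coplanar marker sites on the body and posterior
# elements (mm, CT frame centered on the vertebral body).
_DEFAULT_MARKERS = np.array([
    [17.0, 0.0, 10.0],
    [-17.0, 3.0, -8.0],
    [11.0, -12.0, 13.0],
    [-10.0, -13.0, -12.0],
    [0.0, -16.5, 2.0],
    [8.0, 20.0, 6.0],
    [0.0, 22.0, -10.0],
])


@dataclass
class PhantomSpec:
    """Parameters of the synthetic vertebra volume.

    Defaults give a single-vertebra crop at CT resolution 0.46 x 0.46 x
    0.7 mm in a 128^3 grid, seven 2 mm fiducial spheres, and a non-trivial
    ground-truth pose.
    """

    volume_size: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.46, 0.46, 0.7)
    body_radius: float = 16.0        # vertebral body cylinder, mm
    body_half_height: float = 13.0
    shell_thickness: float = 2.5     # cortical shell of the body
    canal_radius: float = 6.0        # spinal canal bored through z
    canal_center_y: float = 19.0
    bone_hu: float = 1200.0
    soft_hu: float = 300.0
    marker_hu: float = 3000.0
    marker_radius: float = 2.0
    marker_centers: np.ndarray = field(default_factory=lambda: _DEFAULT_MARKERS.copy())
    ground_truth_pose: Pose = field(
        default_factory=lambda: Pose(2.0, -3.0, 4.0, 2.0, -2.0, 3.0))
    noise_sigma: float = 2.0         # additive image noise, 8-bit units
    seed: int = 0

    def __post_init__(self):
        self.marker_centers = np.atleast_2d(np.asarray(self.marker_centers, float))
        if self.bone_hu <= self.soft_hu or self.soft_hu < 0:
            raise ValueError("need bone_hu > soft_hu >= 0")

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        half = (np.array(self.volume_size) - 1) * np.array(self.spacing) / 2.0
        return -half, half


def default_phantom_spec(**overrides) -> PhantomSpec:
    return PhantomSpec(**overrides)


@dataclass
class InstrumentSpec:
    """A dark polygonal instrument overlay, per view, in pixel coordinates."""

    ap_polygon: np.ndarray | None = None  # (n, 2) rows of (row, col)
    la_polygon: np.ndarray | None = None
    intensity: int = 20


@dataclass
class RadiographPair:
    """The fixed side of a registration: AP and LA radiographs + geometry."""

    ap_image: np.ndarray
    la_image: np.ndarray
    ap_model: ProjectionModel
    la_model: ProjectionModel
    ap_instrument_mask: np.ndarray | None = None
    la_instrument_mask: np.ndarray | None = None


def phantom_hu(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Analytic HU at physical points (n, 3) in the CT frame (vectorized)."""
    pts = np.atleast_2d(np.asarray(pts, float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    hu = np.zeros(len(pts))

    r_body = np.hypot(x, y)
    in_body = (r_body <= spec.body_radius) & (np.abs(z) <= spec.body_half_height)
    hu[in_body] = spec.soft_hu
    shell = in_body & ((r_body >= spec.body_radius - spec.shell_thickness)
                       | (np.abs(z) >= spec.body_half_height - spec.shell_thickness))
    hu[shell] = spec.bone_hu

    # posterior elements: pedicles and a spinous mass (solid bone ellipsoids)
    for cx, cy, cz, ax_, ay, az in ((9.0, 13.0, 0.0, 4.0, 6.0, 5.0),
                                    (-9.0, 13.0, 0.0, 4.0, 6.0, 5.0),
                                    (0.0, 22.0, 0.0, 5.0, 7.0, 7.0)):
        q = ((x - cx) / ax_) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        hu[q <= 1.0] = spec.bone_hu

    # spinal canal bored through everything
    canal = (np.hypot(x, y - spec.canal_center_y) <= spec.canal_radius)
    hu[canal] = 0.0

    # fiducial spheres override all tissue
    for c in spec.marker_centers:
        d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        hu[d2 <= spec.marker_radius ** 2] = spec.marker_hu
    return hu


def make_phantom_volume(spec: PhantomSpec) -> tuple[Volume, np.ndarray, RoiBox]:
    """Voxelize the phantom; returns (volume, marker centers, tight ROI box).

    The grid is centered on the CT frame origin. Raises if any marker sphere
    extends outside the volume.
    """
    lo, hi = spec.extent
    for c in spec.marker_centers:
        if np.any(c - spec.marker_radius < lo) or np.any(c + spec.marker_radius > hi):
            raise ValueError(f"marker at {c} extends outside the volume extent")
    nx, ny, nz = spec.volume_size
    sx, sy, sz = spec.spacing
    origin = lo
    xs = origin[0] + sx * np.arange(nx)
    ys = origin[1] + sy * np.arange(ny)
    zs = origin[2] + sz * np.arange(nz)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vox = phantom_hu(spec, pts).reshape(nx, ny, nz).astype(np.float32)
    vol = Volume(voxels=vox, spacing=spec.spacing, origin=origin)

    margin = 3.0
    if len(spec.marker_centers):
        mk_lo = spec.marker_centers.min(axis=0) - spec.marker_radius
        mk_hi = spec.marker_centers.max(axis=0) + spec.marker_radius
    else:
        mk_lo = np.full(3, np.inf)
        mk_hi = np.full(3, -np.inf)
    prim_lo = np.minimum(
        [-spec.body_radius, -spec.body_radius, -spec.body_half_height], mk_lo) - margin
    prim_hi = np.maximum(
        [max(spec.body_radius, 13.0), 29.0, spec.body_half_height], mk_hi) + margin
    roi = RoiBox(np.maximum(prim_lo, lo), np.minimum(prim_hi, hi))
    return vol, spec.marker_centers.copy(), roi


def default_models(image_size=(96, 96), pixel_spacing=1.25,
                   source_to_detector=1000.0, source_to_iso=700.0
                   ) -> tuple[ProjectionModel, ProjectionModel]:
    """Idealized orthogonal AP and LA views around the world origin.

    The test-scale preset images 96 x 96 pixels at 1.25 mm pitch (a 120 mm
    field collimated to the single vertebra); pass ``image_size=(470, 470),
    pixel_spacing=0.486`` for a full-scale 9-inch C-arm field.
    """
    nu, nv = image_size
    du = dv = float(pixel_spacing)

    def build(src, center, u_axis, v_axis):
        src, center = np.array(src, float), np.array(center, float)
        u_axis, v_axis = np.array(u_axis, float), np.array(v_axis, float)
        org = center - (nu - 1) / 2.0 * du * u_axis - (nv - 1) / 2.0 * dv * v_axis
        return ProjectionModel(source=src, detector_origin=org, u_axis=u_axis,
                               v_axis=v_axis, pixel_spacing=(du, dv),
                               image_size=(nu, nv))

    d_det = source_to_detector - source_to_iso
    ap = build((0.0, -source_to_iso, 0.0), (0.0, d_det, 0.0),
               (1.0, 0.0, 0.0), (0.0, 0.0, -1.0))
    la = build((-source_to_iso, 0.0, 0.0), (d_det, 0.0, 0.0),
               (0.0, 1.0, 0.0), (0.0, 0.0, -1.0))
    return ap, la


def _apply_instrument(img: np.ndarray, poly: np.ndarray | None,
                      intensity: int) -> tuple[np.ndarray, np.ndarray]:
    mask = np.zeros(img.shape, dtype=bool)
    if poly is not None:
        poly = np.asarray(poly, float)
        rr, cc = _fill_polygon(poly[:, 0], poly[:, 1], shape=img.shape)
        mask[rr, cc] = True
        img = img.copy()
        img[mask] = intensity
    return img, mask


def simulate_carm_pair(vol: Volume, ground_truth_pose: Pose, ap_model: ProjectionModel,
                       la_model: ProjectionModel, roi: RoiBox, noise_sigma: float = 0.0,
                       seed: int = 0, instrument: InstrumentSpec | None = None,
                       step: float | None = None,
                       log_response: bool = False) -> RadiographPair:
    """Simulate one biplanar C-arm acquisition of the posed phantom.

    Both views are rendered with the same ray-casting model the registration
    objective uses, then Gaussian noise (sigma in 8-bit intensity units) is
    added and clipped to [0, 255]; an optional instrument polygon is painted
    dark afterwards, as a metal shadow would be. Deterministic given seed.

    With ``log_response`` the windowed gray level follows log(1 + integral)
    instead of the integral itself, emulating a detector whose gray level
    tracks the log of received intensity — useful for robustness
    experiments with the affine-invariant measures.
    """
    ap_dir = ap_model.detector_origin - ap_model.source
    la_dir = la_model.detector_origin - la_model.source
    cosang = abs(ap_dir @ la_dir / (np.linalg.norm(ap_dir) * np.linalg.norm(la_dir)))
    if cosang > 0.5:
        import warnings

        warnings.warn("AP and LA views are far from orthogonal; "
                      "triangulation will be ill-conditioned", stacklevel=2)
    rng = np.random.default_rng(seed)
    images, masks = [], []
    for model, poly in ((ap_model, None if instrument is None else instrument.ap_polygon),
                        (la_model, None if instrument is None else instrument.la_polygon)):
        drr = render_drr(vol, ground_truth_pose, model, roi, step=step)
        if log_response:
            from .drr import window_to_8bit

            img = window_to_8bit(np.log1p(drr.raw_integrals)).astype(float)
        else:
            img = drr.pixels.astype(float)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
        img, mask = _apply_instrument(
            img, poly, 20 if instrument is None else instrument.intensity)
        images.append(img)
        masks.append(mask if mask.any() else None)
    return RadiographPair(ap_image=images[0], la_image=images[1],
                          ap_model=ap_model, la_model=la_model,
                          ap_instrument_mask=masks[0], la_instrument_mask=masks[1])


def detect_markers(vol: Volume, expected_hu: float = 3000.0, min_radius: float = 1.0,
                   tolerance: float = 500.0) -> np.ndarray:
    """Locate fiducial spheres in a CT volume.

    Thresholds at ``expected_hu - tolerance``, labels 26-connected
    components, drops components smaller than a ``min_radius`` sphere, and
    returns intensity-weighted centroids in mm (CT frame). Overlapping
    spheres merge into a single component.
    """
    binary = vol.voxels >= (expected_hu - tolerance)
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), int))
    if n == 0:
        return np.zeros((0, 3))
    voxel_volume = float(np.prod(vol.spacing))
    min_voxels = max(1, int(0.5 * (4.0 / 3.0) * np.pi * min_radius**3 / voxel_volume))
    centers = []
    for lab in range(1, n + 1):
        sel = labels == lab
        if sel.sum() < min_voxels:
            continue
        w = vol.voxels * sel
        com = ndimage.center_of_mass(w)
        centers.append(vol.origin + np.array(com) * np.array(vol.spacing))
    return np.array(centers) if centers else np.zeros((0, 3))


def make_test_scene(spec: PhantomSpec | None = None, noise_sigma: float | None = None,
                    seed: int | None = None, step: float = 1.0,
                    instrument: InstrumentSpec | None = None):
    """Convenience: build the default phantom scene used by the benchmarks.

    Returns (volume, markers, roi, pair, spec) with AP/LA views simulated at
    the spec's ground-truth pose using integration step ``step`` mm.
    """
    spec = spec or default_phantom_spec()
    if noise_sigma is not None:
        spec = replace(spec, noise_sigma=noise_sigma)
    if seed is not None:
        spec = replace(spec, seed=seed)
    vol, markers, roi = make_phantom_volume(spec)
    ap_model, la_model = default_models()
    pair = simulate_carm_pair(vol, spec.ground_truth_pose, ap_model, la_model, roi,
                              noise_sigma=spec.noise_sigma, seed=spec.seed,
                              instrument=instrument, step=step)
    return vol, markers, roi, pair, spec
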