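"""Ray-cast digitally reconstructed radiograph (DRR) rendering.

A DRR simulates an X-ray of a CT volume: for every detector pixel a ray is
cast from the source, clipped to an axis-aligned region-of-interest box in
the CT frame, and the Hounsfield values along it are accumulated by uniform
stepping with trilinear interpolation. The accumulated HU·mm line integrals
are then windowed linearly to an 8-bit image, mirroring a fluoroscopy unit's
automatic brightness scaling. Negative HU (air, soft-tissue below water) is
clamped to zero so that air does not bleach bone contrast.

The per-pixel integration loop is JIT-compiled with numba; a vectorized
numpy path is kept as a fallback so the module works without a compiler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Pose, ProjectionModel, Ray

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = ["Volume", "RoiBox", "DrrImage", "ray_box_intersect",
           "sample_trilinear", "render_drr", "window_to_8bit"]


@dataclass
class Volume:
    """A CT voxel grid with physical spacing and origin.

    ``origin`` is the physical position (mm) of the *center* of voxel
    (0, 0, 0); ``voxels`` is indexed [ix, iy, iz].
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError("volume must be at least 2 voxels per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def size(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (voxel-center to voxel-center), mm."""
        hi = self.origin + (np.array(self.size) - 1) * np.array(self.spacing)
        return self.origin.copy(), hi


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned integration box in the CT frame, mm."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.asarray(self.lower, float))
        object.__setattr__(self, "upper", np.asarray(self.upper, float))
        if self.lower.shape != (3,) or self.upper.shape != (3,):
            raise ValueError("box corners must be 3-vectors")
        if not np.all(self.lower < self.upper):
            raise ValueError("box lower must be strictly below upper")

    def to_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RoiBox":
        return cls(d["lower"], d["upper"])


@dataclass
class DrrImage:
    """A rendered DRR: 8-bit pixels plus the raw HU·mm line integrals."""

    pixels: np.ndarray
    raw_integrals: np.ndarray
    model: ProjectionModel


def ray_box_intersect(ray: Ray, box: RoiBox) -> tuple[float, float] | None:
    """Slab-method ray/AABB intersection.

    Returns parametric (t_near, t_far) along the ray, with t_near clamped to
    0 when the origin is inside the box; ``None`` when the ray misses.
    """
    t0, t1 = 0.0, np.inf
    for ax in range(3):
        o, d = ray.origin[ax], ray.direction[ax]
        lo, hi = box.lower[ax], box.upper[ax]
        if abs(d) < 1e-12:
            if o < lo or o > hi:
                return None
            continue
        ta, tb = (lo - o) / d, (hi - o) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return float(t0), float(t1)


def sample_trilinear(vol: Volume, p) -> float:
    """Trilinear HU sample at a physical point; 0 outside the grid."""
    p = np.asarray(p, float)
    idx = (p - vol.origin) / np.array(vol.spacing)
    return float(_trilinear_one(vol.voxels, idx[0], idx[1], idx[2]))


@njit(cache=True, fastmath=True)
def _trilinear_one(vox, x, y, z):
    nx, ny, nz = vox.shape
    if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
        return 0.0
    ix = int(np.floor(x))
    iy = int(np.floor(y))
    iz = int(np.floor(z))
    if ix == nx - 1:
        ix -= 1
    if iy == ny - 1:
        iy -= 1
    if iz == nz - 1:
        iz -= 1
    fx, fy, fz = x - ix, y - iy, z - iz
    c00 = vox[ix, iy, iz] * (1 - fx) + vox[ix + 1, iy, iz] * fx
    c10 = vox[ix, iy + 1, iz] * (1 - fx) + vox[ix + 1, iy + 1, iz] * fx
    c01 = vox[ix, iy, iz + 1] * (1 - fx) + vox[ix + 1, iy, iz + 1] * fx
    c11 = vox[ix, iy + 1, iz + 1] * (1 - fx) + vox[ix + 1, iy + 1, iz + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True, fastmath=True)
def _cast_rays(vox, vorigin, vspacing, src, dirs, box_lo, box_hi, step, out):
    """Accumulate clamped-HU line integrals for a batch of rays (CT frame)."""
    n = dirs.shape[0]
    for i in range(n):
        dx, dy, dz = dirs[i, 0], dirs[i, 1], dirs[i, 2]
        # slab intersection with the ROI box
        t0, t1 = 0.0, 1e30
        ok = True
        for ax in range(3):
            o = src[ax]
            d = dirs[i, ax]
            lo = box_lo[ax]
            hi = box_hi[ax]
            if abs(d) < 1e-12:
                if o < lo or o > hi:
                    ok = False
                    break
            else:
                ta = (lo - o) / d
                tb = (hi - o) / d
                if ta > tb:
                    ta, tb = tb, ta
                if ta > t0:
                    t0 = ta
                if tb < t1:
                    t1 = tb
                if t0 > t1:
                    ok = False
                    break
        if not ok or t1 <= t0:
            out[i] = 0.0
            continue
        nsteps = int((t1 - t0) / step) + 1
        acc = 0.0
        for k in range(nsteps):
            t = t0 + (k + 0.5) * step
            if t > t1:
                break
            px = (src[0] + t * dx - vorigin[0]) / vspacing[0]
            py = (src[1] + t * dy - vorigin[1]) / vspacing[1]
            pz = (src[2] + t * dz - vorigin[2]) / vspacing[2]
            hu = _trilinear_one(vox, px, py, pz)
            if hu > 0.0:
                acc += hu * step
        out[i] = acc


def window_to_8bit(raw: np.ndarray) -> np.ndarray:
    """Linear min-max scaling of raw integrals into [0, 255].

    A constant input maps to all zeros. Rounding is half-away-from-zero so
    the quantization is bit-exactly reproducible.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.zeros(raw.shape, dtype=np.uint8)
    scaled = (raw - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def _detector_rays(model: ProjectionModel) -> np.ndarray:
    """Unnormalized world-frame ray directions for every detector pixel,
    returned as an (nv*nu, 3) array in row-major (v, u) order."""
    nu, nv = model.image_size
    du, dv = model.pixel_spacing
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv))  # vv varies by row
    pix = (model.detector_origin[None, :]
           + uu.reshape(-1, 1) * du * model.u_axis[None, :]
           + vv.reshape(-1, 1) * dv * model.v_axis[None, :])
    d = pix - model.source[None, :]
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def render_drr(vol: Volume, pose: Pose, model: ProjectionModel, roi: RoiBox,
               step: float | None = None) -> DrrImage:
    """Render one DRR of ``vol`` posed by ``pose`` through ``model``.

    Rays are cast per detector pixel, transformed into the CT frame by the
    inverse pose, clipped to ``roi`` (CT frame) and integrated with uniform
    steps of ``step`` mm (default: half the smallest voxel spacing).
    Pixel (u, v) maps to array element [v, u].
    """
    if step is None:
        step = min(vol.spacing) / 2.0
    step = float(step)
    if step <= 0:
        raise ValueError("step must be positive")
    nu, nv = model.image_size
    dirs_w = _detector_rays(model)
    Tinv = np.linalg.inv(pose.to_matrix())
    src_ct = Tinv[:3, :3] @ model.source + Tinv[:3, 3]
    dirs_ct = dirs_w @ Tinv[:3, :3].T
    out = np.empty(dirs_ct.shape[0], dtype=np.float64)
    _cast_rays(vol.voxels, np.asarray(vol.origin), np.asarray(vol.spacing, float),
               np.ascontiguousarray(src_ct), np.ascontiguousarray(dirs_ct),
               roi.lower, roi.upper, step, out)
    raw = out.reshape(nv, nu)
    return DrrImage(pixels=window_to_8bit(raw), raw_integrals=raw, model=model)
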