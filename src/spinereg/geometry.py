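"""Pinhole X-ray projection geometry and rigid pose parameterization.

A C-arm view is modelled as an ideal pinhole: a point X-ray source and a
planar detector spanned by two orthonormal axes. World coordinates are the
C-arm/tracker frame in millimetres; pixel indices are 0-based and address
pixel centers. A :class:`Pose` holds the six rigid parameters
(Tx, Ty, Tz in mm; Rx, Ry, Rz in degrees) that place the CT frame into the
world frame, rotating about a fixed pivot point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ProjectionModel",
    "Pose",
    "Ray",
    "project_point",
    "backproject_ray",
    "triangulate_rays",
    "estimate_source_position",
    "rigid_fit",
    "initial_registration",
]


def _vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class ProjectionModel:
    """One C-arm view's pinhole geometry.

    Parameters
    ----------
    source : (3,) array
        X-ray source position, mm, world frame.
    detector_origin : (3,) array
        Position of the center of pixel (0, 0), mm.
    u_axis, v_axis : (3,) array
        Orthonormal in-plane detector axes (pixel column / row directions).
    pixel_spacing : (du, dv)
        Detector pixel pitch, mm/pixel.
    image_size : (nu, nv)
        Detector size in pixels.
    """

    source: np.ndarray
    detector_origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_spacing: tuple[float, float]
    image_size: tuple[int, int]

    def __post_init__(self):
        object.__setattr__(self, "source", _vec3(self.source))
        object.__setattr__(self, "detector_origin", _vec3(self.detector_origin))
        object.__setattr__(self, "u_axis", _vec3(self.u_axis))
        object.__setattr__(self, "v_axis", _vec3(self.v_axis))
        object.__setattr__(self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing))
        object.__setattr__(self, "image_size", tuple(int(n) for n in self.image_size))
        if abs(np.linalg.norm(self.u_axis) - 1.0) > 1e-9 or abs(np.linalg.norm(self.v_axis) - 1.0) > 1e-9:
            raise ValueError("u_axis and v_axis must be unit vectors")
        if abs(self.u_axis @ self.v_axis) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthogonal")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        if any(n < 1 for n in self.image_size):
            raise ValueError("image_size must be at least 1x1")
        n = self.normal
        d = abs((self.source - self.detector_origin) @ n)
        if not np.isfinite(d) or d <= 1e-9:
            raise ValueError("source must not lie on the detector plane")

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the detector plane (u x v)."""
        return np.cross(self.u_axis, self.v_axis)

    def pixel_to_world(self, u: float, v: float) -> np.ndarray:
        """World position of continuous pixel coordinate (u, v)."""
        du, dv = self.pixel_spacing
        return self.detector_origin + u * du * self.u_axis + v * dv * self.v_axis

    def to_dict(self) -> dict:
        return {
            "source": self.source.tolist(),
            "detector_origin": self.detector_origin.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "pixel_spacing": list(self.pixel_spacing),
            "image_size": list(self.image_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            source=d["source"],
            detector_origin=d["detector_origin"],
            u_axis=d["u_axis"],
            v_axis=d["v_axis"],
            pixel_spacing=tuple(d["pixel_spacing"]),
            image_size=tuple(d["image_size"]),
        )


@dataclass
class Pose:
    """Six rigid parameters and the transform they define.

    Rotations are intrinsic Rz*Ry*Rx in degrees, pivoted at ``center``:
    a CT point p maps to ``R @ (p - center) + center + t``.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.center = _vec3(self.center)

    @property
    def params(self) -> np.ndarray:
        """The 6-vector (tx, ty, tz, rx, ry, rz)."""
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], float)

    def with_params(self, p) -> "Pose":
        p = np.asarray(p, float)
        return Pose(*p, center=self.center.copy())

    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", [self.rz, self.ry, self.rx], degrees=True).as_matrix()

    def to_matrix(self) -> np.ndarray:
        """Homogeneous 4x4: x -> R (x - c) + c + t."""
        R = self.rotation()
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = self.center + [self.tx, self.ty, self.tz] - R @ self.center
        return T

    @classmethod
    def from_matrix(cls, T: np.ndarray, center=(0.0, 0.0, 0.0)) -> "Pose":
        """Recover the 6 parameters of a rigid 4x4 for a given pivot."""
        T = np.asarray(T, float)
        check_rigid(T)
        c = _vec3(center)
        R = T[:3, :3]
        rz, ry, rx = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)
        t = T[:3, 3] + R @ c - c
        return cls(t[0], t[1], t[2], rx, ry, rz, center=c)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        T = self.to_matrix()
        out = pts @ T[:3, :3].T + T[:3, 3]
        return out[0] if single else out


@dataclass(frozen=True)
class Ray:
    """A half-infinite projection line: origin + t * direction, t >= 0."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _vec3(self.origin))
        d = _vec3(self.direction)
        n = np.linalg.norm(d)
        if n < 1e-15:
            raise ValueError("ray direction must be nonzero")
        object.__setattr__(self, "direction", d / n)

    def at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


def check_rigid(T: np.ndarray, tol: float = 1e-6) -> None:
    """Raise ValueError unless T is a proper rigid 4x4 transform."""
    T = np.asarray(T, float)
    if T.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise ValueError("rotation block is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("transform is a reflection (det < 0)")
    if not np.allclose(T[3], [0, 0, 0, 1], atol=tol):
        raise ValueError("last row must be [0, 0, 0, 1]")


def project_point(model: ProjectionModel, p) -> tuple[float, float]:
    """Project a world point through the source onto the detector.

    Returns continuous pixel coordinates (u, v); these may fall outside the
    physical detector. Raises if ``p`` coincides with the source or the ray
    is parallel to the detector plane.
    """
    p = _vec3(p)
    d = p - model.source
    if np.linalg.norm(d) < 1e-12:
        raise ValueError("cannot project the source point itself")
    n = model.normal
    denom = d @ n
    if abs(denom) < 1e-12:
        raise ValueError("no intersection: ray parallel to detector plane")
    t = ((model.detector_origin - model.source) @ n) / denom
    hit = model.source + t * d
    rel = hit - model.detector_origin
    du, dv = model.pixel_spacing
    return float(rel @ model.u_axis / du), float(rel @ model.v_axis / dv)


def backproject_ray(model: ProjectionModel, u: float, v: float) -> Ray:
    """Ray from the source through detector pixel (u, v)."""
    return Ray(model.source, model.pixel_to_world(u, v) - model.source)


def triangulate_rays(a: Ray, b: Ray) -> tuple[np.ndarray, float]:
    """Closest-approach intersection of two projection lines.

    Returns the midpoint of the shortest segment between the lines and that
    segment's length (the triangulation gap, 0 for truly intersecting rays).
    """
    da, db = a.direction, b.direction
    cross = np.cross(da, db)
    if np.linalg.norm(cross) <= 1e-12:
        raise ValueError("degenerate triangulation: rays are parallel")
    # Solve [da·da  -da·db; da·db  -db·db] [ta tb]^T = [w·da, w·db]^T
    w = b.origin - a.origin
    A = np.array([[da @ da, -da @ db], [da @ db, -db @ db]])
    rhs = np.array([w @ da, w @ db])
    ta, tb = np.linalg.solve(A, rhs)
    pa, pb = a.at(ta), b.at(tb)
    return (pa + pb) / 2.0, float(np.linalg.norm(pa - pb))


def estimate_source_position(lines) -> np.ndarray:
    """Least-squares intersection point of several 3D lines.

    Each line is given as a pair of points it passes through — an up-deck
    calibration marker and the 3D position of its shadow on the detector.
    Minimizes the sum of squared point-to-line distances via the normal
    equations over the line projection operators, with an SVD fallback when
    the system is near-singular (e.g. nearly parallel lines).
    """
    lines = list(lines)
    if len(lines) < 2:
        raise ValueError("need at least 2 lines to estimate the source")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for p0, p1 in lines:
        p0, p1 = _vec3(p0), _vec3(p1)
        d = p1 - p0
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("degenerate line: coincident points")
        d = d / n
        P = np.eye(3) - np.outer(d, d)  # projector onto the line's normal plane
        A += P
        b += P @ p0
    if np.linalg.cond(A) > 1e10:
        sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
        if rank < 3:
            raise ValueError("all lines are (near-)parallel; source not determined")
        return sol
    return np.linalg.solve(A, b)


def rigid_fit(src, dst) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares rigid transform mapping src onto dst.

    Kabsch/Umeyama solution (no scaling). With fiducial correspondences
    known a priori this is the entire "ICP" step — no iteration is needed.

    Returns
    -------
    T : (4, 4) proper rigid transform minimizing sum |T src_i - dst_i|^2.
    rms : (3,) per-axis RMS residual of the fit, mm.
    """
    src = np.atleast_2d(np.asarray(src, float))
    dst = np.atleast_2d(np.asarray(dst, float))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    src_c, dst_c = src - cs, dst - cd
    # collinearity check: second singular value of the centered cloud
    if np.linalg.svd(src_c, compute_uv=False)[1] < 1e-9:
        raise ValueError("source points are collinear; rotation not determined")
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    resid = src @ R.T + t - dst
    return T, np.sqrt((resid**2).mean(axis=0))


def initial_registration(ap_points, la_points, ap_model: ProjectionModel,
                         la_model: ProjectionModel, ct_points) -> Pose:
    """Coarse pose from three paired feature picks on the AP/LA images.

    Each feature is triangulated from its AP and LA pixel coordinates, then a
    closed-form rigid fit maps the corresponding CT points onto the
    triangulated world points. The returned pose pivots at the CT points'
    centroid.
    """
    ap_points = np.atleast_2d(np.asarray(ap_points, float))
    la_points = np.atleast_2d(np.asarray(la_points, float))
    ct_points = np.atleast_2d(np.asarray(ct_points, float))
    if not (len(ap_points) == len(la_points) == len(ct_points) >= 3):
        raise ValueError("need >= 3 matched picks per view and CT points")
    world = []
    for (ua, va), (ul, vl) in zip(ap_points, la_points):
        ray_a = backproject_ray(ap_model, ua, va)
        ray_l = backproject_ray(la_model, ul, vl)
        pt, gap = triangulate_rays(ray_a, ray_l)
        if not np.isfinite(gap):
            raise ValueError("non-finite triangulation gap")
        world.append(pt)
    T, _ = rigid_fit(ct_points, np.array(world))
    return Pose.from_matrix(T, center=ct_points.mean(axis=0))
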