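"""File formats: volumes (MetaImage/NIfTI), 2D images, transforms, configs.

Volumes go through SimpleITK, preserving HU values, physical spacing and
origin. Note the axis convention: SimpleITK stores arrays [z, y, x]; this
package's :class:`~spinereg.drr.Volume` indexes voxels [x, y, z], so arrays
are transposed on the way in and out. All metadata (projection models,
poses, ROIs, results) is JSON; 2D radiographs and masks are 8-bit grayscale
PNG; raw DRR integrals can be dumped as 32-bit float TIFF for debugging.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
import tifffile

from .drr import RoiBox, Volume
from .geometry import Pose, ProjectionModel, check_rigid

__all__ = ["read_volume", "write_volume", "read_image", "write_image",
           "read_transform", "write_transform", "read_model", "write_model",
           "read_pose", "write_pose", "read_roi", "write_roi", "write_float_tiff"]

_VOLUME_EXTS = (".mhd", ".nii", ".nii.gz")


def _volume_ext(path: str) -> str:
    low = path.lower()
    for ext in _VOLUME_EXTS:
        if low.endswith(ext):
            return ext
    raise ValueError(f"unknown volume format for {path!r}; expected one of {_VOLUME_EXTS}")


def read_volume(path: str) -> Volume:
    """Read a MetaImage (.mhd/.raw) or NIfTI (.nii/.nii.gz) volume."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = _volume_ext(path)
    if ext == ".mhd":
        # surface a clear error when the .raw companion is missing
        with open(path) as fh:
            for line in fh:
                if line.startswith("ElementDataFile"):
                    raw = line.split("=", 1)[1].strip()
                    raw_path = os.path.join(os.path.dirname(path) or ".", raw)
                    if raw not in ("LOCAL",) and not os.path.exists(raw_path):
                        raise FileNotFoundError(
                            f"missing raw data companion {raw_path!r} for {path!r}")
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as e:
        raise ValueError(f"corrupt or unreadable volume header in {path!r}: {e}") from e
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path!r}")
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    return Volume(voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
                  spacing=spacing, origin=np.array(img.GetOrigin()))


def write_volume(path: str, vol: Volume) -> None:
    _volume_ext(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, path)


def read_image(path: str) -> np.ndarray:
    """Read an 8-bit grayscale image."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def write_image(path: str, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_float_tiff(path: str, raw: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(raw, dtype=np.float32))


def write_transform(path: str, T: np.ndarray) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": np.asarray(T, float).tolist()}, fh, indent=1)


def read_transform(path: str, validate: bool = True) -> np.ndarray:
    with open(path) as fh:
        data = json.load(fh)
    T = np.asarray(data["matrix"] if isinstance(data, dict) else data, float)
    if T.shape != (4, 4):
        raise ValueError(f"transform in {path!r} is not 4x4")
    if validate:
        check_rigid(T)
    return T


def write_model(path: str, model: ProjectionModel) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model(path: str) -> ProjectionModel:
    with open(path) as fh:
        return ProjectionModel.from_dict(json.load(fh))


def write_pose(path: str, pose: Pose) -> None:
    with open(path, "w") as fh:
        json.dump({"tx": pose.tx, "ty": pose.ty, "tz": pose.tz,
                   "rx": pose.rx, "ry": pose.ry, "rz": pose.rz,
                   "center": pose.center.tolist()}, fh, indent=1)


def read_pose(path: str) -> Pose:
    with open(path) as fh:
        d = json.load(fh)
    return Pose(d["tx"], d["ty"], d["tz"], d["rx"], d["ry"], d["rz"],
                center=np.asarray(d.get("center", [0, 0, 0]), float))


def write_roi(path: str, roi: RoiBox) -> None:
    with open(path, "w") as fh:
        json.dump(roi.to_dict(), fh, indent=1)


def read_roi(path: str) -> RoiBox:
    with open(path) as fh:
        return RoiBox.from_dict(json.load(fh))
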