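"""Intensity similarity measures between a radiograph and a DRR.

Five classical measures are provided — normalized cross-correlation (NCC),
gradient correlation (GC), pattern intensity (PI), gradient difference (GD)
and mutual information (MI) — each computed over an explicit validity mask
so that instrument shadows and out-of-field pixels can be excluded. All
measures are oriented so that *larger is more similar*; a single optimizer
contract therefore serves every measure.

For a biplanar C-arm acquisition the overall score is the arithmetic mean
of the AP-view and LA-view scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MaskedImagePair", "ncc", "gradient_correlation", "pattern_intensity",
           "gradient_difference", "mutual_information", "biplanar_score",
           "get_measure", "MEASURES"]

MIN_MASK_PIXELS = 64


@dataclass
class MaskedImagePair:
    """A fixed (C-arm) / moving (DRR) image pair with a validity mask."""

    fixed: np.ndarray
    moving: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.fixed = np.asarray(self.fixed)
        self.moving = np.asarray(self.moving)
        if self.mask is None:
            self.mask = np.ones(self.fixed.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.fixed.shape == self.moving.shape == self.mask.shape):
            raise ValueError("fixed, moving and mask must share one shape")
        if self.fixed.ndim != 2:
            raise ValueError("images must be 2D")
        if self.mask.sum() < MIN_MASK_PIXELS:
            raise ValueError(
                f"mask keeps {int(self.mask.sum())} pixels; "
                f"at least {MIN_MASK_PIXELS} are required")


def _masked(a: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.asarray(a, dtype=float)[mask]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.sqrt((x**2).sum()), np.sqrt((y**2).sum())
    if sx < 1e-12 or sy < 1e-12:
        raise ValueError("zero variance: image constant over the mask")
    return float((x @ y) / (sx * sy))


def ncc(pair: MaskedImagePair) -> float:
    """Normalized cross-correlation (Pearson r) of the masked intensities.

    Invariant to positive affine intensity changes of either image, which is
    what makes it robust to the arbitrary brightness/contrast of a C-arm.
    """
    return _pearson(_masked(pair.fixed, pair.mask), _masked(pair.moving, pair.mask))


def _sobel_uv(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(img, dtype=float)
    gu = ndimage.sobel(img, axis=1, mode="reflect")  # d/du (columns)
    gv = ndimage.sobel(img, axis=0, mode="reflect")  # d/dv (rows)
    return gu, gv


def _eroded(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)


def gradient_correlation(pair: MaskedImagePair) -> float:
    """Mean of the horizontal- and vertical-gradient NCCs (3x3 Sobel).

    The mask is eroded by one pixel so no Sobel response straddles masked-out
    or out-of-image pixels.
    """
    m = _eroded(pair.mask)
    if m.sum() < MIN_MASK_PIXELS:
        raise ValueError("eroded mask too small for gradient correlation")
    fu, fv = _sobel_uv(pair.fixed)
    mu, mv = _sobel_uv(pair.moving)
    return 0.5 * (_pearson(fu[m], mu[m]) + _pearson(fv[m], mv[m]))


def pattern_intensity(pair: MaskedImagePair, sigma: float = 10.0,
                      radius: int = 3) -> float:
    """Pattern intensity of the difference image d = fixed - moving.

    score = sum over masked pixels x, neighbours x' with 0 < |x-x'| <= radius:
        sigma^2 / (sigma^2 + (d(x) - d(x'))^2)

    The sum runs over every masked center pixel and every offset with
    0 < dx^2 + dy^2 <= radius^2; the difference image is reflect-padded so
    border pixels keep full neighborhoods and the analytic maximum is
    exactly N_masked * K_offsets, attained iff d is locally constant.
    Each term saturates at 1, which desensitizes the measure to isolated
    strong mismatches.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    d = _diff_image(pair)
    offsets = [(dy, dx) for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if (dx or dy) and dx * dx + dy * dy <= radius * radius]
    if not offsets:
        raise ValueError("empty neighborhood")
    s2 = sigma * sigma
    h, w = d.shape
    dp = np.pad(d, radius, mode="symmetric")  # edge-repeating reflection
    center = d[pair.mask]
    total = 0.0
    for dy, dx in offsets:
        nb = dp[radius + dy:radius + dy + h, radius + dx:radius + dx + w]
        diff = center - nb[pair.mask]
        total += float((s2 / (s2 + diff * diff)).sum())
    return total


def _diff_image(pair: MaskedImagePair) -> np.ndarray:
    # scale factor between fixed and moving is taken as 1: both images are
    # min-max windowed to 0..255 upstream, so no scale search is performed.
    return np.asarray(pair.fixed, float) - np.asarray(pair.moving, float)


def gradient_difference(pair: MaskedImagePair) -> float:
    """Gradient difference of the difference image d = fixed - moving.

    score = sum A_u / (A_u + (du d)^2) + sum A_v / (A_v + (dv d)^2)

    with A_u, A_v the variances of the fixed image's Sobel gradients.
    Maximal (= 2 N) when the difference image has zero gradient.
    """
    m = _eroded(pair.mask)
    if m.sum() < MIN_MASK_PIXELS:
        raise ValueError("eroded mask too small for gradient difference")
    d = _diff_image(pair)
    du, dv = _sobel_uv(d)
    fu, fv = _sobel_uv(pair.fixed)
    au = float(fu[m].var())
    av = float(fv[m].var())
    if au < 1e-12 or av < 1e-12:
        raise ValueError("zero gradient variance in the fixed image")
    return float((au / (au + du[m] ** 2)).sum() + (av / (av + dv[m] ** 2)).sum())


def mutual_information(pair: MaskedImagePair, bins: int = 64) -> float:
    """Mutual information (bits) from the joint intensity histogram."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    f = _masked(pair.fixed, pair.mask)
    m = _masked(pair.moving, pair.mask)
    joint, _, _ = np.histogram2d(f, m, bins=bins, range=[[0, 256], [0, 256]])
    p = joint / joint.sum()
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    return entropy(pf) + entropy(pm) - entropy(p.ravel())


MEASURES = {
    "ncc": ncc,
    "gc": gradient_correlation,
    "pi": pattern_intensity,
    "gd": gradient_difference,
    "mi": mutual_information,
}


def get_measure(key: str):
    """Look up a measure by its string key ('ncc'|'gc'|'pi'|'gd'|'mi')."""
    try:
        return MEASURES[key]
    except KeyError:
        raise ValueError(
            f"unknown measure {key!r}; valid options: {sorted(MEASURES)}") from None


def biplanar_score(ap_pair: MaskedImagePair, la_pair: MaskedImagePair,
                   measure="ncc", **kwargs) -> float:
    """Average of the AP-view and LA-view similarity scores."""
    fn = get_measure(measure) if isinstance(measure, str) else measure
    return 0.5 * (fn(ap_pair, **kwargs) + fn(la_pair, **kwargs))
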