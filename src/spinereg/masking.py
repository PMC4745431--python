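"""Instrument-shadow segmentation and effective image-pair construction.

Metal instruments (a dynamic reference frame clamp, retractors) cast dark
shadows on the radiograph that have no counterpart in the DRR and would bias
any intensity measure. The remedy has two parts: the shadow is segmented by
seeded region growing, then the segmented region is painted to zero in BOTH
images — so both carry the identical "noise" — and additionally excluded
from the similarity mask, which guarantees the duplicated region cannot
inflate the score.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .similarity import MaskedImagePair

__all__ = ["region_grow", "make_effective_pair", "circular_field_mask"]


def region_grow(image: np.ndarray, seeds, tolerance: float) -> np.ndarray:
    """Seeded 4-connected flood fill.

    A pixel joins the region when its intensity differs from the *seed's*
    intensity by at most ``tolerance`` (the seed value is fixed, not a
    running mean, so the result is order-independent). The union over all
    seeds is returned.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    for seed in seeds:
        r, c = int(seed[0]), int(seed[1])
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed {seed} out of bounds for image {img.shape}")
        ref = img[r, c]
        if out[r, c]:
            continue
        visited = out.copy()
        q = deque([(r, c)])
        visited[r, c] = True
        while q:
            y, x = q.popleft()
            if abs(img[y, x] - ref) > tolerance:
                continue
            out[y, x] = True
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                if 0 <= ny < h and 0 <= nx < w and not visited[ny, nx]:
                    visited[ny, nx] = True
                    q.append((ny, nx))
    return out


def circular_field_mask(shape, radius_fraction: float = 0.5) -> np.ndarray:
    """Boolean mask of the circular C-arm image field (True = inside)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = radius_fraction * min(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def make_effective_pair(carm: np.ndarray, drr, instrument_mask=None,
                        field_mask=None) -> MaskedImagePair:
    """Build the masked pair actually scored by the similarity measures.

    Pixels under ``instrument_mask`` (True = instrument) are painted to 0 in
    both the radiograph and the DRR and removed from the validity mask;
    pixels outside an optional circular ``field_mask`` (True = usable field)
    are likewise removed.
    """
    fixed = np.asarray(carm)
    moving = drr.pixels if hasattr(drr, "pixels") else np.asarray(drr)
    if fixed.shape != moving.shape:
        raise ValueError("C-arm and DRR image shapes differ")
    valid = np.ones(fixed.shape, dtype=bool)
    if field_mask is not None:
        field_mask = np.asarray(field_mask, bool)
        if field_mask.shape != fixed.shape:
            raise ValueError("field mask shape mismatch")
        valid &= field_mask
    if instrument_mask is not None:
        instrument_mask = np.asarray(instrument_mask, bool)
        if instrument_mask.shape != fixed.shape:
            raise ValueError("instrument mask shape mismatch")
        fixed = fixed.copy()
        moving = moving.copy()
        fixed[instrument_mask] = 0
        moving[instrument_mask] = 0
        valid &= ~instrument_mask
    return MaskedImagePair(fixed=fixed, moving=moving, mask=valid)
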