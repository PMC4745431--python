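"""Independent brute-force reference implementations used to cross-check
the package's vectorized similarity measures and geometry. Everything here
is written as plain nested loops over pixels, deliberately sharing no code
with the implementation under test."""

import math

import numpy as np


def brute_ncc(fixed, moving, mask):
    f = [float(fixed[i, j]) for i in range(fixed.shape[0])
         for j in range(fixed.shape[1]) if mask[i, j]]
    m = [float(moving[i, j]) for i in range(moving.shape[0])
         for j in range(moving.shape[1]) if mask[i, j]]
    mf, mm = sum(f) / len(f), sum(m) / len(m)
    num = sum((a - mf) * (b - mm) for a, b in zip(f, m))
    df = math.sqrt(sum((a - mf) ** 2 for a in f))
    dm = math.sqrt(sum((b - mm) ** 2 for b in m))
    return num / (df * dm)


def _reflect(i, n):
    # scipy.ndimage 'reflect' boundary: (d c b a | a b c d | d c b a)
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def brute_sobel(img, axis):
    """3x3 Sobel with reflect padding, nested loops. axis 1 = d/du (cols)."""
    h, w = img.shape
    sm = [1, 2, 1]
    dv = [-1, 0, 1]
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(-1, 2):
                for b in range(-1, 2):
                    v = float(img[_reflect(i + a, h), _reflect(j + b, w)])
                    if axis == 1:
                        acc += v * dv[b + 1] * sm[a + 1]
                    else:
                        acc += v * dv[a + 1] * sm[b + 1]
            out[i, j] = acc
    return out


def brute_eroded(mask):
    h, w = mask.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for a in range(-1, 2):
                for b in range(-1, 2):
                    y, x = i + a, j + b
                    if y < 0 or y >= h or x < 0 or x >= w or not mask[y, x]:
                        ok = False
            out[i, j] = ok
    return out


def brute_gc(fixed, moving, mask):
    m = brute_eroded(mask)
    fu, fv = brute_sobel(np.asarray(fixed, float), 1), brute_sobel(np.asarray(fixed, float), 0)
    mu, mv = brute_sobel(np.asarray(moving, float), 1), brute_sobel(np.asarray(moving, float), 0)
    return 0.5 * (brute_ncc(fu, mu, m) + brute_ncc(fv, mv, m))


def brute_pi(fixed, moving, mask, sigma=10.0, radius=3):
    d = np.asarray(fixed, float) - np.asarray(moving, float)
    h, w = d.shape
    s2 = sigma * sigma
    total = 0.0
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    if (dy == 0 and dx == 0) or dy * dy + dx * dx > radius * radius:
                        continue
                    nb = d[_reflect(i + dy, h), _reflect(j + dx, w)]
                    total += s2 / (s2 + (d[i, j] - nb) ** 2)
    return total


def brute_gd(fixed, moving, mask):
    m = brute_eroded(mask)
    d = np.asarray(fixed, float) - np.asarray(moving, float)
    du, dv = brute_sobel(d, 1), brute_sobel(d, 0)
    fu, fv = brute_sobel(np.asarray(fixed, float), 1), brute_sobel(np.asarray(fixed, float), 0)
    sel_u = [fu[i, j] for i in range(m.shape[0]) for j in range(m.shape[1]) if m[i, j]]
    sel_v = [fv[i, j] for i in range(m.shape[0]) for j in range(m.shape[1]) if m[i, j]]
    au = float(np.var(sel_u))
    av = float(np.var(sel_v))
    total = 0.0
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j]:
                total += au / (au + du[i, j] ** 2) + av / (av + dv[i, j] ** 2)
    return total


def brute_mi(fixed, moving, mask, bins=64):
    width = 256.0 / bins
    joint = {}
    n = 0
    for i in range(fixed.shape[0]):
        for j in range(fixed.shape[1]):
            if not mask[i, j]:
                continue
            bf = min(int(float(fixed[i, j]) / width), bins - 1)
            bm = min(int(float(moving[i, j]) / width), bins - 1)
            joint[(bf, bm)] = joint.get((bf, bm), 0) + 1
            n += 1
    pf, pm = {}, {}
    for (bf, bm), c in joint.items():
        pf[bf] = pf.get(bf, 0) + c
        pm[bm] = pm.get(bm, 0) + c

    def H(counts):
        return -sum((c / n) * math.log2(c / n) for c in counts if c > 0)

    return H(pf.values()) + H(pm.values()) - H(joint.values())


BRUTE = {"ncc": brute_ncc, "gc": brute_gc, "pi": brute_pi, "gd": brute_gd, "mi": brute_mi}


def brute_flood_fill(image, seeds, tolerance):
    """4-connected region growth against the seed's intensity, recursive-free."""
    img = np.asarray(image, float)
    h, w = img.shape
    out = np.zeros((h, w), dtype=bool)
    for sr, sc in seeds:
        ref = img[sr, sc]
        stack = [(sr, sc)]
        seen = set()
        while stack:
            y, x = stack.pop()
            if (y, x) in seen or y < 0 or y >= h or x < 0 or x >= w:
                continue
            seen.add((y, x))
            if abs(img[y, x] - ref) > tolerance:
                continue
            out[y, x] = True
            stack.extend([(y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)])
    return out


def line_cost(point, lines):
    """Sum of squared distances from a point to a list of (p0, p1) lines."""
    total = 0.0
    p = np.asarray(point, float)
    for p0, p1 in lines:
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        d = p1 - p0
        d = d / np.linalg.norm(d)
        r = p - p0
        total += float(r @ r - (r @ d) ** 2)
    return total
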