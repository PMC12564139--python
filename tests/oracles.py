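"""Independent brute-force oracles: naive loop/enumeration implementations
used only to verify the vectorized library code. Deliberately slow and
simple; they share no code path with the package."""
from __future__ import annotations

import math

import numpy as np


def naive_percentile(values, pct):
    """Linear interpolation between order statistics, written from the
    definition (sort, fractional rank)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 1:
        return v[0]
    h = (n - 1) * pct / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return v[lo] + (v[hi] - v[lo]) * (h - lo)


def naive_first_order(values, n_bins=32):
    v = [float(x) for x in values]
    n = len(v)
    mean = sum(v) / n
    m2 = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    vmin, vmax = min(v), max(v)
    if vmax == vmin:
        levels = [0] * n
    else:
        w = (vmax - vmin) / n_bins
        levels = [min(int((x - vmin) // w), n_bins - 1) for x in v]
    counts = {}
    for lev in levels:
        counts[lev] = counts.get(lev, 0) + 1
    probs = [c / n for c in counts.values()]
    return {
        "fo_mean": mean,
        "fo_variance": m2,
        "fo_skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "fo_kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "fo_minimum": vmin,
        "fo_maximum": vmax,
        "fo_range": vmax - vmin,
        "fo_median": naive_percentile(v, 50),
        "fo_p10": naive_percentile(v, 10),
        "fo_p90": naive_percentile(v, 90),
        "fo_iqr": naive_percentile(v, 75) - naive_percentile(v, 25),
        "fo_energy": sum(x**2 for x in v),
        "fo_entropy": -sum(p * math.log2(p) for p in probs),
        "fo_uniformity": sum(p**2 for p in probs),
    }


def naive_shape(mask, spacing):
    mask = np.asarray(mask).astype(bool)
    sx, sy, sz = spacing
    voxvol = sx * sy * sz
    volume = 0
    area = 0.0
    face_areas = (sy * sz, sx * sz, sx * sy)
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                volume += 1
                for ax, (di, dj, dk) in enumerate(((1, 0, 0), (0, 1, 0), (0, 0, 1))):
                    for sgn in (-1, 1):
                        ni, nj, nk = i + sgn * di, j + sgn * dj, k + sgn * dk
                        outside = not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz)
                        if outside or not mask[ni, nj, nk]:
                            area += face_areas[ax]
    vol_mm3 = volume * voxvol
    sphericity = math.pi ** (1 / 3) * (6 * vol_mm3) ** (2 / 3) / area
    coords = [
        (i * sx, j * sy, k * sz)
        for i in range(nx)
        for j in range(ny)
        for k in range(nz)
        if mask[i, j, k]
    ]
    arr = np.array(coords)
    c = arr - arr.mean(axis=0)
    cov = c.T @ c / len(coords)
    lam = sorted(max(x, 0.0) for x in np.linalg.eigvalsh(cov))
    elong = math.sqrt(lam[1] / lam[2]) if lam[2] > 0 else 1.0
    return {
        "shape_volume": vol_mm3,
        "shape_surface_area": area,
        "shape_sphericity": sphericity,
        "shape_elongation": elong,
    }


def naive_discretize(values, n_bins=32):
    vmin, vmax = min(values), max(values)
    if vmax == vmin:
        return [0 for _ in values], 1
    w = (vmax - vmin) / n_bins
    return [min(int((x - vmin) // w), n_bins - 1) for x in values], n_bins


def naive_glcm(vol, mask, offsets, n_bins=32):
    """Directed-pair enumeration, symmetrized, normalized per offset,
    features averaged over offsets with at least one pair."""
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask).astype(bool)
    roi = [tuple(idx) for idx in np.argwhere(mask)]
    vals = [vol[i] for i in roi]
    levels, L = naive_discretize(vals, n_bins)
    lev = {pos: levels[i] for i, pos in enumerate(roi)}
    per_offset = []
    nx, ny, nz = mask.shape
    for off in offsets:
        counts = np.zeros((L, L))
        for (i, j, k) in roi:
            ni, nj, nk = i + off[0], j + off[1], k + off[2]
            if 0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz and mask[ni, nj, nk]:
                a, b = lev[(i, j, k)], lev[(ni, nj, nk)]
                counts[a, b] += 1
                counts[b, a] += 1
        total = counts.sum()
        if total == 0:
            continue
        per_offset.append(naive_glcm_stats(counts / total))
    if not per_offset:
        return None
    keys = per_offset[0].keys()
    return {k: float(np.mean([d[k] for d in per_offset])) for k in keys}


def naive_glcm_stats(p):
    L = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * p[i, j] for i in range(L) for j in range(L))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if var_i > 0 and var_j > 0:
        corr = sum(
            (i - mu_i) * (j - mu_j) * p[i, j] for i in range(L) for j in range(L)
        ) / math.sqrt(var_i * var_j)
    else:
        corr = 1.0
    asm = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    ent = -sum(
        p[i, j] * math.log2(p[i, j]) for i in range(L) for j in range(L) if p[i, j] > 0
    )
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_asm": asm,
        "glcm_idm": idm,
        "glcm_entropy": ent,
    }


def naive_dice(a, b):
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    inter = int((a & b).sum())
    denom = int(a.sum()) + int(b.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom
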