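"""Independent brute-force oracles used to validate feature and metric
implementations. Everything here is written against the documented
conventions only (explicit loops, no shared code with the package)."""

from __future__ import annotations

import numpy as np


def clamp(v: float, lo: int, hi: int) -> float:
    return min(max(v, lo), hi)


def bilinear(sl: np.ndarray, y: float, x: float) -> float:
    """Bilinear interpolation with nearest-edge clamping."""
    ny, nx = sl.shape
    y = clamp(y, 0, ny - 1)
    x = clamp(x, 0, nx - 1)
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    y1, x1 = min(y0 + 1, ny - 1), min(x0 + 1, nx - 1)
    fy, fx = y - y0, x - x0
    return (
        sl[y0, x0] * (1 - fy) * (1 - fx)
        + sl[y0, x1] * (1 - fy) * fx
        + sl[y1, x0] * fy * (1 - fx)
        + sl[y1, x1] * fy * fx
    )


def neighborhood_mean_sd(data: np.ndarray, r: int, three_d: bool):
    """Mean/SD over the city-block diamond, borders replicated."""
    nz, ny, nx = data.shape
    mean = np.zeros_like(data, dtype=float)
    sd = np.zeros_like(data, dtype=float)
    dzs = (-1, 0, 1) if three_d else (0,)
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if abs(dy) + abs(dx) <= r]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                vals = []
                for dz in dzs:
                    zz = int(clamp(z + dz, 0, nz - 1))
                    for dy, dx in offs:
                        yy = int(clamp(y + dy, 0, ny - 1))
                        xx = int(clamp(x + dx, 0, nx - 1))
                        vals.append(data[zz, yy, xx])
                vals = np.asarray(vals, dtype=float)
                mean[z, y, x] = vals.mean()
                sd[z, y, x] = vals.std()
    return mean, sd


_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_GY = _GX.T


def sobel_magnitude(data: np.ndarray) -> np.ndarray:
    """Per-slice 3×3 Sobel magnitude with edge replication."""
    out = np.zeros_like(data, dtype=float)
    for z in range(data.shape[0]):
        sl = np.pad(data[z].astype(float), 1, mode="edge")
        gx = np.zeros_like(data[z], dtype=float)
        gy = np.zeros_like(data[z], dtype=float)
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                patch = sl[y : y + 3, x : x + 3]
                gx[y, x] = (patch * _GX).sum()
                gy[y, x] = (patch * _GY).sum()
        out[z] = np.sqrt(gx**2 + gy**2)
    return out


ELBP_TIE_EPS = 1e-6  # documented tie tolerance of the bit comparisons


def elbp_codes(data: np.ndarray, radius_outer: float, n: int, image_means=None):
    """The four ELBP channels via per-pixel independent sampling.

    ``image_means`` optionally gives the reference mean per slice (for the
    CI channel); defaults to the whole-slice mean.
    """
    r1, r2 = radius_outer, radius_outer / 2.0
    nz, ny, nx = data.shape
    ci = np.zeros(data.shape)
    ni = np.zeros(data.shape)
    rd = np.zeros(data.shape)
    ad = np.zeros(data.shape)
    for z in range(nz):
        sl = data[z].astype(float)
        ref = sl.mean() if image_means is None else image_means[z]
        for y in range(ny):
            for x in range(nx):
                outer = []
                inner = []
                for k in range(n):
                    a = 2 * np.pi * k / n
                    outer.append(bilinear(sl, y + r1 * np.sin(a), x + r1 * np.cos(a)))
                    inner.append(bilinear(sl, y + r2 * np.sin(a), x + r2 * np.cos(a)))
                c = sl[y, x]
                eps = ELBP_TIE_EPS
                ci[z, y, x] = 1.0 if c - ref > eps else 0.0
                ni[z, y, x] = 1.0 if c - np.mean(outer) > eps else 0.0
                rd[z, y, x] = sum(2**k for k in range(n) if inner[k] - outer[k] > eps)
                ad[z, y, x] = sum(
                    2**k for k in range(n) if outer[k] - outer[(k + 1) % n] > eps
                )
    return ci, ni, rd, ad


def gabor_response(data: np.ndarray, size: int, sigma: float, wavelength: float,
                   theta_deg: float, spacing_xy=(1.0, 1.0)) -> np.ndarray:
    """Direct correlation with an independently constructed cosine Gabor."""
    if size % 2 == 0:
        size += 1
    half = size // 2
    sx, sy = spacing_xy
    kern = np.zeros((size, size))
    th = np.deg2rad(theta_deg)
    for i in range(-half, half + 1):
        for j in range(-half, half + 1):
            xm, ym = j * sx, i * sy
            xr = xm * np.cos(th) + ym * np.sin(th)
            yr = -xm * np.sin(th) + ym * np.cos(th)
            kern[i + half, j + half] = np.exp(-(xr**2 + yr**2) / (2 * sigma**2)) * np.cos(
                2 * np.pi * xr / wavelength
            )
    out = np.zeros_like(data, dtype=float)
    for z in range(data.shape[0]):
        sl = np.pad(data[z].astype(float), half, mode="edge")
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                out[z, y, x] = (sl[y : y + size, x : x + size] * kern).sum()
    return out


def surface_voxels(mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Mask voxels with a face-adjacent background neighbor (border counts)."""
    nz, ny, nx = mask.shape
    out = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                on_surface = False
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not mask[zz, yy, xx]:
                        on_surface = True
                        break
                if on_surface:
                    out.append((z, y, x))
    return out


def surface_distances(a: np.ndarray, b: np.ndarray, spacing):
    """All directed nearest-surface distances A→B by exhaustive pairs (mm)."""
    sx, sy, sz = spacing
    pa = [(x * sx, y * sy, z * sz) for z, y, x in surface_voxels(a)]
    pb = [(x * sx, y * sy, z * sz) for z, y, x in surface_voxels(b)]
    dists = []
    for p in pa:
        best = min(
            np.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2) for q in pb
        )
        dists.append(best)
    return np.asarray(dists)
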