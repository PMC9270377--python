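"""Independent oracles used by the test suite.

Everything here is deliberately coded from the definitions (loops, direct
formulas, dense resampling) rather than through the library's own code
paths, so tests compare two independent routes to the same quantity.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

import slidealign as sa


def low_feature_maps(pt, ps, gt, M=None):
    """Cytoplasm feature maps of both pyramids at the ground-truth l_low."""
    if M is None:
        M = sa.default_stain_matrix()
    maps = []
    for pyr in (pt, ps):
        info = pyr.level_info(gt.l_low)
        img = sa.fetch_region(pyr, gt.l_low, 0, 0, info.width, info.height)
        f = sa.extract_cytoplasm_feature(img, M)
        f.level = gt.l_low
        maps.append(f)
    return maps


def warp_crop_oracle(pyr_source, g, level, u, v, w, h):
    """Whole-level forward-warp of the source then crop, computed directly:
    each output pixel bilinearly samples the full source level at the
    inverse-mapped coordinate (level-calibrated translation)."""
    src = pyr_source.level_raster(level).astype(np.float32)
    A = np.linalg.inv(g.S * g.R[:2, :2])
    T2 = g.T[:2] * 2.0 ** (level - g.l_low)
    Y, X = np.meshgrid(np.arange(v, v + h, dtype=np.float64),
                       np.arange(u, u + w, dtype=np.float64), indexing="ij")
    cy = A[0, 0] * (Y - T2[0]) + A[0, 1] * (X - T2[1])
    cx = A[1, 0] * (Y - T2[0]) + A[1, 1] * (X - T2[1])
    out = np.empty((h, w, 3), np.uint8)
    for c in range(3):
        o = ndimage.map_coordinates(src[..., c], [cy, cx], order=1,
                                    mode="grid-constant", cval=255.0)
        out[..., c] = np.clip(np.rint(o), 0, 255)
    return out


def seam_keep_mask(shape, m, band=2):
    """Mask excluding a +/-band px strip around every tile border."""
    mask = np.ones(shape[:2], bool)
    for t in range(0, shape[1] + 1, m):
        mask[:, max(0, t - band):t + band] = False
    for t in range(0, shape[0] + 1, m):
        mask[max(0, t - band):t + band, :] = False
    return mask


def fov_agreement(fov_data, oracle_data, m, band=2, tol=2):
    """Fraction of non-seam pixels whose channel-max abs diff is <= tol."""
    keep = seam_keep_mask(fov_data.shape, m, band)
    d = np.abs(fov_data.astype(int) - oracle_data.astype(int))
    return float((d[keep].reshape(-1, 3).max(axis=1) <= tol).mean())


def similarity_residual(P, Q, S, R2, T2):
    """Sum of squared residuals of the forward similarity on (x, y) points."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    mapped = Q[:, ::-1] @ (S * R2).T + T2
    return float(((mapped[:, ::-1] - P) ** 2).sum())


def grid_search_min_residual(P, Q, angle_step=0.5, scale_step=0.01,
                             scale_range=(0.5, 2.0)):
    """Brute-force similarity fit: sweep (angle, scale) on a grid, solve
    the translation at each node by centroid matching, return the minimal
    sum of squared residuals."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pyx, Qyx = P[:, ::-1], Q[:, ::-1]
    pbar, qbar = Pyx.mean(axis=0), Qyx.mean(axis=0)
    Pc, Qc = Pyx - pbar, Qyx - qbar
    best = math.inf
    angles = np.arange(-180.0, 180.0, angle_step)
    scales = np.arange(scale_range[0], scale_range[1] + 1e-9, scale_step)
    ca, sa_ = np.cos(np.deg2rad(angles)), np.sin(np.deg2rad(angles))
    for c, s in zip(ca, sa_):
        R = np.array([[c, s], [-s, c]])
        QR = Qc @ R.T  # rotated centred source
        # residual(S) = sum |S*QR - Pc|^2, minimized per grid scale
        for S in scales:
            r = ((S * QR - Pc) ** 2).sum()
            if r < best:
                best = r
    return best


def dog_strongest_extremum(img, sigmas=(2, 3, 4, 6, 8, 10, 12, 16), k=1.6):
    """(y, x) of the strongest difference-of-Gaussians response."""
    img = np.asarray(img, float)
    best = (-1.0, (0, 0))
    for s in sigmas:
        r = ndimage.gaussian_filter(img, s) - ndimage.gaussian_filter(img, k * s)
        m = float(np.abs(r).max())
        if m > best[0]:
            best = (m, np.unravel_index(np.abs(r).argmax(), r.shape))
    return best[1]


def halving_chain(width, height, m):
    """Enumerate factor-2 (ceiling) halvings of (width, height) from the
    base down, stopping once both dims are <= m; returns the list
    base-first."""
    dims = [(width, height)]
    while dims[-1][0] > m or dims[-1][1] > m:
        w, h = dims[-1]
        dims.append((math.ceil(w / 2), math.ceil(h / 2)))
    return dims


def halvings_to_low(width, height, m):
    """Number of halvings from the base until pixel count <= (2m)^2."""
    n = 0
    w, h = width, height
    while w * h > (2 * m) ** 2:
        w, h = math.ceil(w / 2), math.ceil(h / 2)
        n += 1
    return n


def float_box_downsample(base, n_halvings):
    """Direct float box-filter downsampling chain (independent of the
    package's integer halving)."""
    cur = np.asarray(base, dtype=np.float64)
    for _ in range(n_halvings):
        h, w = cur.shape[:2]
        if h % 2 or w % 2:
            cur = np.pad(cur, ((0, h % 2), (0, w % 2), (0, 0)),
                         mode="constant", constant_values=255.0)
        h, w = cur.shape[:2]
        cur = cur.reshape(h // 2, 2, w // 2, 2, cur.shape[2]).mean(axis=(1, 3))
    return cur
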