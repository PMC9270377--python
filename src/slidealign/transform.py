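"""Global similarity transform (scale S, rotation R, translation T).

The registration model is a 2D similarity embedded in 3-vectors with an
inert third component: a point is carried as ``[y, x, 0]`` and mapped by

    [y', x', 0]^T = S * R @ [y, x, 0]^T + T

where ``R`` is a 3x3 proper rotation about the inert axis and ``T`` has a
zero third component.  The transform is estimated once at a low pyramid
level ``l_low``; when applied at a higher-magnification level ``l`` the
translation is rescaled by ``2**delta`` with ``delta = l - l_low`` (factor-2
pyramid level calibration).

Public point arrays are ``(N, 2)`` in (x, y) order — matching landmark CSV
files and screen coordinates; the (y, x, 0) embedding is internal and the
stored ``T`` keeps the (y, x, 0) order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "GlobalTransform",
    "rotation_about_axis",
    "warp_similarity",
    "round_half_away",
]


def rotation_about_axis(angle_deg: float) -> np.ndarray:
    """3x3 proper rotation acting on (y, x, 0) vectors.

    ``angle_deg`` is the standard counter-clockwise rotation of (x, y)
    points; in (y, x) ordering the 2x2 block is ``[[c, s], [-s, c]]``.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def round_half_away(v):
    """Round to nearest integer, halves away from zero (pixel convention)."""
    v = np.asarray(v, dtype=float)
    return (np.sign(v) * np.floor(np.abs(v) + 0.5)).astype(int)


def _as_xy(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError(f"expected (N, 2) point array, got {pts.shape}")
    return pts


@dataclass
class GlobalTransform:
    """Similarity transform estimated at pyramid level ``l_low``.

    Attributes
    ----------
    S : float
        Isotropic scale factor (> 0).
    R : (3, 3) ndarray
        Proper rotation; third axis inert.
    T : (3,) ndarray
        Translation in (y, x, 0) order, in pixels at level ``l_low``.
    l_low : int
        Pyramid level of estimation (levels increase with magnification).
    m : int
        Tile size of the pyramids the transform refers to.
    inliers, mean_residual
        Optional estimation diagnostics (RANSAC inlier count, mean inlier
        residual in pixels at ``l_low``).
    """

    S: float
    R: np.ndarray
    T: np.ndarray
    l_low: int = 0
    m: int = 256
    inliers: int | None = None
    mean_residual: float | None = None

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if self.S <= 0:
            raise DegenerateInputError(f"scale must be positive, got {self.S}")
        if self.R.shape != (3, 3):
            raise InvalidInputError("R must be 3x3")

    # -- geometry ---------------------------------------------------------

    @property
    def R2(self) -> np.ndarray:
        """2x2 rotation block acting on (y, x)."""
        return self.R[:2, :2]

    @property
    def T2(self) -> np.ndarray:
        """Translation (y, x) at l_low."""
        return self.T[:2]

    @property
    def angle_deg(self) -> float:
        """Rotation angle (counter-clockwise for (x, y) points)."""
        return float(np.rad2deg(np.arctan2(self.R[0, 1], self.R[0, 0])))

    def translation_at(self, level: int | None) -> np.ndarray:
        """(y, x) translation calibrated to ``level`` (2**delta scaling)."""
        if level is None:
            return self.T2
        delta = level - self.l_low
        return self.T2 * (2.0 ** delta)

    def apply_xy(self, points_xy, level: int | None = None) -> np.ndarray:
        """Forward-map source points (x, y) into the target frame."""
        pts = _as_xy(points_xy)
        yx = pts[:, ::-1]
        out = yx @ (self.S * self.R2).T + self.translation_at(level)
        return out[:, ::-1]

    def invert_xy(self, points_xy, level: int | None = None) -> np.ndarray:
        """Map target points (x, y) back into the source frame."""
        pts = _as_xy(points_xy)
        yx = pts[:, ::-1] - self.translation_at(level)
        minv = np.linalg.inv(self.S * self.R2)
        out = yx @ minv.T
        return out[:, ::-1]

    def inverse(self) -> "GlobalTransform":
        """Transform mapping target coordinates back to source coordinates."""
        Rt = self.R.T
        Tinv = -(1.0 / self.S) * (Rt @ self.T)
        return GlobalTransform(S=1.0 / self.S, R=Rt, T=Tinv,
                               l_low=self.l_low, m=self.m)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "S": float(self.S),
            "R": [float(v) for v in self.R.ravel()],
            "T": [float(v) for v in self.T],
            "l_low": int(self.l_low),
            "m": int(self.m),
        }
        if self.inliers is not None:
            d["inliers"] = int(self.inliers)
        if self.mean_residual is not None:
            d["mean_residual"] = float(self.mean_residual)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalTransform":
        return cls(
            S=float(d["S"]),
            R=np.asarray(d["R"], dtype=float).reshape(3, 3),
            T=np.asarray(d["T"], dtype=float),
            l_low=int(d["l_low"]),
            m=int(d.get("m", 256)),
            inliers=d.get("inliers"),
            mean_residual=d.get("mean_residual"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "GlobalTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def warp_similarity(
    image: np.ndarray,
    S: float,
    R2: np.ndarray,
    T2: np.ndarray,
    out_shape: tuple[int, int],
    out_origin_yx: tuple[float, float] = (0.0, 0.0),
    src_origin_yx: tuple[float, float] = (0.0, 0.0),
    fill: float = 255.0,
) -> np.ndarray:
    """Render the forward-transformed ``image`` by inverse mapping.

    Output pixel at global target coordinate ``p_t = out_origin + (y, x)``
    samples the source at ``(S R)^-1 (p_t - T2) - src_origin`` with bilinear
    interpolation and constant white fill outside the source raster.
    ``T2`` must already be calibrated to the level being rendered.
    Works on 2D or (H, W, C) uint8/float arrays; returns uint8.
    """
    A = np.linalg.inv(S * np.asarray(R2, dtype=float))
    offset = A @ (np.asarray(out_origin_yx, float) - np.asarray(T2, float))
    offset = offset - np.asarray(src_origin_yx, float)
    img = np.asarray(image)
    single = img.ndim == 2
    if single:
        img = img[..., None]
    out = np.empty(out_shape + (img.shape[2],), dtype=np.float32)
    for c in range(img.shape[2]):
        ndimage.affine_transform(
            img[..., c].astype(np.float32), A, offset=offset,
            output_shape=out_shape, output=out[..., c],
            order=1, mode="grid-constant", cval=fill, prefilter=False,
        )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out[..., 0] if single else out
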