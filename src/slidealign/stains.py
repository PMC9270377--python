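"""Beer-Lambert optical density conversion and color deconvolution.

Serial sections under different stains (H&E vs IHC) share tissue geometry
but not color, so intensity-based matching fails across stains.  The fix is
to work in optical density (OD) space, where stain contributions mix
linearly (Beer-Lambert): each pixel's OD 3-vector is a non-negative
combination of per-stain OD "color" vectors.  Inverting that mixing — color
deconvolution — yields per-stain amount images; a single amount channel
(the cytoplasm feature, channel 0 by default) is comparable across stains
and drives landmark detection.

Conventions: the stain matrix has one *row* per stain and one *column* per
color channel.  A pixel with stain-amount vector ``g`` mixes to OD
``o = g @ rows`` and deconvolution inverts on the right: ``g = o @ rows^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidStateError
from .pyramid import LevelImage

__all__ = [
    "DEFAULT_STAIN_ROWS",
    "StainMatrix",
    "ODImage",
    "StainAmountImage",
    "FeatureMap",
    "rgb_to_od",
    "complete_stain_matrix",
    "default_stain_matrix",
    "deconvolve",
    "mix",
    "extract_cytoplasm_feature",
    "load_stain_matrix",
    "save_stain_matrix",
]

#: Default per-stain OD vectors (rows 1-2); the third stain direction is
#: synthesized by :func:`complete_stain_matrix`.
DEFAULT_STAIN_ROWS = np.array([
    [0.6442, 0.7166, 0.2668],
    [0.0928, 0.9541, 0.2831],
])


@dataclass
class StainMatrix:
    """Normalized OD matrix; rows are unit stain vectors after completion."""

    rows: np.ndarray  # (3, 3)
    completed: bool = False

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.shape != (3, 3):
            raise InvalidInputError("stain matrix must be 3x3")

    @property
    def inverse(self) -> np.ndarray:
        if not self.completed:
            raise InvalidStateError("stain matrix not completed; call "
                                    "complete_stain_matrix first")
        return np.linalg.inv(self.rows)


@dataclass
class ODImage:
    """Per-pixel optical density 3-vectors (dimensionless, >= 0)."""

    data: np.ndarray  # (h, w, 3) float
    I0: float = 255.0


@dataclass
class StainAmountImage:
    """Per-pixel stain amounts g = (g0, g1, g2) from deconvolution."""

    data: np.ndarray  # (h, w, 3) float


@dataclass
class FeatureMap:
    """Single-channel 8-bit cytoplasm feature raster at some pyramid level."""

    data: np.ndarray  # (h, w) uint8
    level: int = 0


def rgb_to_od(image: np.ndarray, I0: float = 255.0) -> ODImage:
    """Convert a 3-channel intensity raster to optical density.

    Per channel ``OD = -log10(max(I, 1) / I0)``; the max(., 1) guard keeps
    fully absorbed pixels finite.  White input (I = I0) maps to zero OD.
    """
    if I0 <= 0:
        raise InvalidInputError("I0 must be positive")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError("expected a 3-channel raster")
    od = -np.log10(np.maximum(img.astype(np.float64), 1.0) / I0)
    return ODImage(data=np.maximum(od, 0.0), I0=float(I0))


def complete_stain_matrix(rows12: np.ndarray) -> StainMatrix:
    """Complete a 2-stain OD matrix to an invertible 3x3.

    The third stain direction is the normalized cross product of the first
    two rows — orthogonal to both, so the completed matrix spans OD space
    and the linear system is solvable at every pixel.  All rows are unit
    normalized.
    """
    rows12 = np.asarray(rows12, dtype=float)
    if rows12.shape != (2, 3):
        raise InvalidInputError("expected two 3-component stain vectors")
    norms = np.linalg.norm(rows12, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateInputError("stain vectors must be nonzero")
    r1, r2 = rows12 / norms[:, None]
    r3 = np.cross(r1, r2)
    n3 = np.linalg.norm(r3)
    if n3 < 1e-8:
        raise DegenerateInputError("stain vectors are collinear")
    return StainMatrix(rows=np.stack([r1, r2, r3 / n3]), completed=True)


def default_stain_matrix() -> StainMatrix:
    """The shipped cytoplasm/counterstain matrix, completed."""
    return complete_stain_matrix(DEFAULT_STAIN_ROWS)


def deconvolve(od: ODImage | np.ndarray, M: StainMatrix) -> StainAmountImage:
    """Per-pixel stain amounts: g = o @ rows^-1 (exact linear inverse)."""
    data = od.data if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    return StainAmountImage(data=data @ M.inverse)


def mix(amounts: StainAmountImage | np.ndarray, M: StainMatrix) -> np.ndarray:
    """Re-mix stain amounts to OD: o = g @ rows.  Inverse of deconvolve."""
    if not M.completed:
        raise InvalidStateError("stain matrix not completed")
    data = amounts.data if isinstance(amounts, StainAmountImage) else \
        np.asarray(amounts, dtype=float)
    return data @ M.rows


def extract_cytoplasm_feature(
    image: LevelImage | np.ndarray,
    M: StainMatrix | None = None,
    channel: int = 0,
    od_ceiling: float = 1.0,
    I0: float = 255.0,
) -> FeatureMap:
    """Deconvolved single-stain amount image, rescaled to 8 bits.

    The selected amount channel is clipped at 0 and mapped linearly so that
    an amount of ``od_ceiling`` (default 1.0) hits 255; larger amounts clip.
    The fixed ceiling keeps the feature map reproducible across slides.
    """
    if channel not in (0, 1, 2):
        raise InvalidInputError("channel must be 0, 1 or 2")
    if M is None:
        M = default_stain_matrix()
    level = 0
    if isinstance(image, LevelImage):
        level = image.level
        image = image.data
    amounts = deconvolve(rgb_to_od(image, I0=I0), M).data[..., channel]
    scaled = np.clip(amounts, 0.0, None) * (255.0 / od_ceiling)
    return FeatureMap(data=np.clip(np.rint(scaled), 0, 255).astype(np.uint8),
                      level=level)


def load_stain_matrix(path) -> StainMatrix:
    """Read a 3x3 (or 2x3, auto-completed) whitespace-separated text matrix."""
    vals = np.loadtxt(Path(path), dtype=float)
    if vals.shape == (2, 3):
        return complete_stain_matrix(vals)
    if vals.shape == (3, 3):
        if np.allclose(vals[2], 0.0):
            return complete_stain_matrix(vals[:2])
        m = StainMatrix(rows=vals / np.linalg.norm(vals, axis=1)[:, None],
                        completed=True)
        if abs(np.linalg.det(m.rows)) < 1e-8:
            raise DegenerateInputError("stain matrix is singular")
        return m
    raise InvalidInputError(f"expected 2x3 or 3x3 matrix, got {vals.shape}")


def save_stain_matrix(M: StainMatrix, path) -> None:
    np.savetxt(Path(path), M.rows, fmt="%.6f")
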