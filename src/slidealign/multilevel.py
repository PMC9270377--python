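"""Real-time FOV localization and propagated tile-wise registration.

Given the global similarity estimated at ``l_low``, any field of view (FOV)
of the target slide at any level ``l >= l_low`` is served from the source
slide without ever warping a full level:

1. the FOV's top-left corner is mapped into the source with the
   level-calibrated inverse transform (translation scaled by ``2**delta``,
   ``delta = l - l_low``);
2. the source tiles covering the mapped FOV are fetched together with a
   q x q tile halo (q odd, default 5), forming one *enlarged area* per
   output tile — the halo guarantees that rotation and scale within the
   method's regime never read outside fetched data (content within
   ``floor(q/2) * m`` px of the tile is always available);
3. each enlarged area is transformed independently (no shared mutable
   state, so areas may be processed concurrently) and the central m x m
   crop becomes one output tile;
4. the n1 x n2 output tiles are stitched into the registered source FOV.

The per-area rendering inverse-maps output-tile target coordinates through
the global similarity into the enlarged source area, so the stitched result
equals a whole-level warp wherever the halo covers the pulled-back content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError
from .pyramid import TilePyramid, fetch_region
from .transform import GlobalTransform, round_half_away, warp_similarity

__all__ = [
    "FOVRequest",
    "EnlargedArea",
    "RegisteredFOV",
    "localize_source_fov",
    "fetch_source_tiles",
    "tile_translation",
    "area_translation",
    "transform_enlarged_area",
    "register_fov",
]


@dataclass(frozen=True)
class FOVRequest:
    """A target-slide viewing rectangle: level ``l``, global top-left
    ``(u, v)`` = (x, y) px, size ``w x h`` px."""

    level: int
    u: int
    v: int
    w: int
    h: int
    m: int = 256

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise InvalidInputError("FOV must have positive size")

    @property
    def n1(self) -> int:
        """Number of tile columns containing the FOV."""
        return math.ceil(self.w / self.m)

    @property
    def n2(self) -> int:
        """Number of tile rows containing the FOV."""
        return math.ceil(self.h / self.m)


@dataclass
class EnlargedArea:
    """The q x q-tile source patch around one output tile.

    ``raster`` is exactly ``(q*m, q*m, 3)``; ``origin_xy`` is its top-left in
    source level-l coordinates; ``target_origin_xy`` is the output tile's
    top-left in target level-l coordinates.  ``T_g`` and ``T_prime`` are the
    per-area translation factors (see :func:`tile_translation` and
    :func:`area_translation`).
    """

    k: int
    o: int
    q: int
    level: int
    raster: np.ndarray
    origin_xy: tuple[int, int]
    target_origin_xy: tuple[int, int]
    T_g: np.ndarray | None = None
    T_prime: np.ndarray | None = None

    def __post_init__(self):
        if self.q % 2 == 0 or self.q < 1:
            raise InvalidInputError("q must be odd and positive")
        if self.raster.shape[0] != self.raster.shape[1] or \
                self.raster.shape[0] % self.q != 0:
            raise InvalidInputError("enlarged-area raster must be q*m square")


@dataclass
class RegisteredFOV:
    """The stitched registered source FOV: exactly (n2*m, n1*m, 3)."""

    data: np.ndarray
    level: int
    source_origin_xy: tuple[int, int]
    n1: int = 0
    n2: int = 0


def localize_source_fov(req: FOVRequest, g: GlobalTransform) -> tuple[int, int]:
    """Source coordinates of the target FOV's top-left corner.

    ``[v_s, u_s, 0]^T = (S R)^-1 ([v_t, u_t, 0]^T - 2**delta T)``, rounded
    to the nearest pixel (halves away from zero).
    """
    if req.level < g.l_low:
        raise InvalidInputError(
            f"FOV level {req.level} below estimation level {g.l_low}")
    if g.S <= 0 or abs(np.linalg.det(g.S * g.R2)) < 1e-18:
        raise DegenerateInputError("singular S*R")
    src = g.invert_xy(np.array([[req.u, req.v]], dtype=float),
                      level=req.level)[0]
    u_s, v_s = round_half_away(src)
    return int(u_s), int(v_s)


def fetch_source_tiles(
    pyr_source: TilePyramid,
    u_s: int,
    v_s: int,
    n1: int,
    n2: int,
    l: int,
    q: int = 5,
) -> dict[tuple[int, int], np.ndarray]:
    """All source tiles needed for the FOV's enlarged areas.

    Returns ``{(i, j): tile}`` for the n1 x n2 grid anchored at the tile
    containing ``(u_s, v_s)`` plus a ``floor(q/2)``-tile halo on every side.
    Tiles beyond the slide border come back white.
    """
    if q % 2 == 0 or q < 1:
        raise InvalidInputError("q must be odd and positive")
    m = pyr_source.m
    a, b = math.floor(u_s / m), math.floor(v_s / m)
    h = q // 2
    return {
        (i, j): pyr_source.tile(l, i, j)
        for j in range(b - h, b + n2 + h)
        for i in range(a - h, a + n1 + h)
    }


def tile_translation(k: int, o: int, R: np.ndarray, m: int, q: int = 5) -> np.ndarray:
    """Per-enlarged-area translation factor
    ``T_g = -m R [(o - floor(q/2)), (k - floor(q/2)), 0]^T``
    (k = tile column, o = tile row; (y, x, 0) ordering)."""
    h = q // 2
    vec = np.array([float(o - h), float(k - h), 0.0])
    return -m * (np.asarray(R, dtype=float) @ vec)


def area_translation(
    k: int, o: int, R: np.ndarray, m: int, q: int = 5,
    lambda_x: float = 0.0, lambda_y: float = 0.0,
) -> np.ndarray:
    """Composed translation
    ``T' = R [-(m - 2*lambda_x) floor(q/2), -(m - 2*lambda_y) floor(q/2), 0]^T + T_g``
    where lambda_x/lambda_y are optional inter-tile overlap margins
    (0 by default: tiles abut exactly)."""
    h = q // 2
    shift = np.array([-(m - 2.0 * lambda_x) * h, -(m - 2.0 * lambda_y) * h, 0.0])
    return np.asarray(R, dtype=float) @ shift + tile_translation(k, o, R, m, q)


def _assemble_area(
    pyr_source: TilePyramid,
    tiles: dict[tuple[int, int], np.ndarray],
    k: int, o: int, l: int, q: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    m = pyr_source.m
    h = q // 2
    raster = np.empty((q * m, q * m, 3), dtype=np.uint8)
    for dj in range(q):
        for di in range(q):
            i, j = k - h + di, o - h + dj
            tile = tiles.get((i, j))
            if tile is None:
                tile = pyr_source.tile(l, i, j)
            raster[dj * m:(dj + 1) * m, di * m:(di + 1) * m] = tile
    return raster, ((k - h) * m, (o - h) * m)


def transform_enlarged_area(
    B: EnlargedArea,
    g: GlobalTransform,
    lambda_x: float = 0.0,
    lambda_y: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp one enlarged area and select its registration output tile.

    Returns ``(B_prime, z)``: the transformed q*m x q*m area rendered in
    output-tile-centred target coordinates, and the central m x m crop
    ``z`` — the canonical output-tile position, pinned by the requirement
    that the identity transform passes source tiles through unchanged.
    ``B.T_g``/``B.T_prime`` are filled in with the per-area translation
    factors; the rendering uses the equivalent composed affine (inverse
    mapping), which matches a whole-level warp wherever the halo covers.
    """
    m = B.raster.shape[0] // B.q
    hm = (B.q // 2) * m
    B.T_g = tile_translation(B.k, B.o, g.R, m, B.q)
    B.T_prime = area_translation(B.k, B.o, g.R, m, B.q, lambda_x, lambda_y)
    tx, ty = B.target_origin_xy
    T2 = g.translation_at(B.level)
    B_prime = warp_similarity(
        B.raster, g.S, g.R2, T2,
        out_shape=(B.q * m, B.q * m),
        out_origin_yx=(ty - hm, tx - hm),
        src_origin_yx=(B.origin_xy[1], B.origin_xy[0]),
    )
    z = B_prime[hm:hm + m, hm:hm + m]
    return B_prime, z


def register_fov(
    req: FOVRequest,
    pyr_source: TilePyramid,
    g: GlobalTransform,
    q: int = 5,
    lambda_x: float = 0.0,
    lambda_y: float = 0.0,
) -> RegisteredFOV:
    """Produce the registered source FOV for a target viewing rectangle.

    Localizes the FOV in the source, fetches the covering tiles plus halo,
    transforms each enlarged area independently and stitches the n1 x n2
    output tiles.  Per-request work is O(n1 * n2 * q**2 * m**2) and two runs
    with identical inputs are bit-identical.
    """
    m = pyr_source.m
    if req.m != m:
        raise InvalidInputError(f"request tile size {req.m} != pyramid {m}")
    u_s, v_s = localize_source_fov(req, g)
    n1, n2 = req.n1, req.n2
    tiles = fetch_source_tiles(pyr_source, u_s, v_s, n1, n2, req.level, q)
    a, b = math.floor(u_s / m), math.floor(v_s / m)
    out = np.empty((n2 * m, n1 * m, 3), dtype=np.uint8)
    for r in range(n2):
        for c in range(n1):
            k, o = a + c, b + r
            raster, origin = _assemble_area(pyr_source, tiles, k, o,
                                            req.level, q)
            area = EnlargedArea(
                k=k, o=o, q=q, level=req.level, raster=raster,
                origin_xy=origin,
                target_origin_xy=(req.u + c * m, req.v + r * m),
            )
            _, z = transform_enlarged_area(area, g, lambda_x, lambda_y)
            out[r * m:(r + 1) * m, c * m:(c + 1) * m] = z
    return RegisteredFOV(data=out, level=req.level,
                         source_origin_xy=(u_s, v_s), n1=n1, n2=n2)
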