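"""Synthetic dual-stain serial-section phantoms with known ground truth.

The generator emulates the preparation chain of a serial-section slide
pair: shared tissue geometry (gland-like rings with lumina, nuclei and
stroma on a white background), rendered twice under different stain
profiles through the Beer-Lambert mixing model, with the source render
displaced by a known similarity transform (rotation, isotropic scale,
translation), an optional smooth local "sectioning" jitter field that the
global model cannot capture, and Gaussian sensor noise.  The known
transform and gland-center landmark pairs are the test oracle standing in
for expert annotations on scanner data.

Everything is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import disk

from .errors import InvalidInputError
from .pyramid import TilePyramid, build_pyramid, compute_level_dims, \
    select_low_level_for_dims
from .stains import StainMatrix, default_stain_matrix
from .transform import GlobalTransform, rotation_about_axis

__all__ = [
    "BACKGROUND", "STROMA", "EPITHELIUM", "LUMEN", "NUCLEUS",
    "StainProfile", "PhantomSpec", "PhantomGeometry", "PhantomGroundTruth",
    "DEFAULT_PROFILE_A", "DEFAULT_PROFILE_B",
    "generate_geometry", "render_stain", "make_pair", "sample_spec",
]

# structure classes
BACKGROUND, STROMA, EPITHELIUM, LUMEN, NUCLEUS = 0, 1, 2, 3, 4
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class StainProfile:
    """Per-class stain-amount weights: rows = structure classes in the
    order (background, stroma, epithelium, lumen, nucleus), columns = the
    three stain channels of the mixing matrix."""

    name: str
    weights: tuple  # (5, 3) nested tuples, hashable

    def array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


#: H&E-like appearance: cytoplasm-stain-heavy epithelium, strong nuclei.
DEFAULT_PROFILE_A = StainProfile("HE-like", (
    (0.00, 0.00, 0.00),   # background
    (0.12, 0.35, 0.00),   # stroma
    (0.55, 0.25, 0.00),   # epithelium
    (0.03, 0.02, 0.00),   # lumen
    (0.95, 0.15, 0.00),   # nucleus
))

#: IHC-like appearance: same geometry, different mix with a third stain.
DEFAULT_PROFILE_B = StainProfile("IHC-like", (
    (0.00, 0.00, 0.00),
    (0.08, 0.04, 0.10),
    (0.40, 0.05, 0.55),
    (0.02, 0.00, 0.02),
    (0.70, 0.05, 0.10),
))


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom pair.

    ``shift_xy`` is the translation in pixels *at l_low* (the level where
    the global transform lives); angle and scale are level-free.  The
    similarity regime is bounded to the method's working range:
    angle in [-20, 20] degrees, scale in [0.8, 1.25]; the local jitter
    amplitude (max displacement of the smooth deformation field, in base-
    level px) may reach 16 px so degradation protocols are expressible.
    """

    seed: int = 0
    canvas: tuple[int, int] = (4096, 4096)  # (width, height)
    n_glands: int = 12
    gland_radius: tuple[float, float] = (60.0, 140.0)
    angle_deg: float = 8.0
    scale: float = 1.05
    shift_xy: tuple[float, float] = (60.0, -40.0)
    jitter_px: float = 0.0
    noise_std: float = 2.0
    m: int = 256
    profile_a: StainProfile = DEFAULT_PROFILE_A
    profile_b: StainProfile = DEFAULT_PROFILE_B

    def __post_init__(self):
        if not -20.0 <= self.angle_deg <= 20.0:
            raise InvalidInputError("angle must be within [-20, 20] degrees")
        if not 0.8 <= self.scale <= 1.25:
            raise InvalidInputError("scale must be within [0.8, 1.25]")
        if not 0.0 <= self.jitter_px <= 16.0:
            raise InvalidInputError("jitter amplitude must be in [0, 16] px")
        if self.n_glands < 0 or self.noise_std < 0:
            raise InvalidInputError("negative gland count or noise std")


@dataclass
class PhantomGeometry:
    """Layered structure masks plus the gland centers used as landmarks."""

    classmap: np.ndarray  # (h, w) uint8 of structure classes
    gland_centers_xy: np.ndarray  # (n, 2)
    gland_radii: np.ndarray  # (n,)

    def mask(self, cls: int) -> np.ndarray:
        return self.classmap == cls


@dataclass
class PhantomGroundTruth:
    """Known transform and landmark pairs for one phantom pair.

    ``transform`` maps source coordinates to target coordinates at
    ``l_low``; landmark arrays are at the base level and satisfy the
    transform exactly when jitter is zero (within float rounding).
    """

    transform: GlobalTransform
    landmarks_target_xy: np.ndarray
    landmarks_source_xy: np.ndarray
    base_level: int
    l_low: int
    geometry: PhantomGeometry
    spec: PhantomSpec

    def landmarks_at(self, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Landmark pairs rescaled to ``level`` (factor-2 per level)."""
        s = 2.0 ** (level - self.base_level)
        return self.landmarks_target_xy * s, self.landmarks_source_xy * s


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Seeded gland-like structure masks on a stromal tissue ellipse.

    Glands are rings (epithelium) around a lumen, lined with nuclei, placed
    without lumen overlap inside a margin that keeps them on-tissue under
    the transform range.  Same spec -> identical masks.
    """
    w, h = spec.canvas
    if w <= 0 or h <= 0:
        raise InvalidInputError("canvas must be positive")
    rng = _rng(spec.seed, 0)
    r_lo, r_hi = spec.gland_radius
    margin = int(0.25 * min(w, h)) + int(r_hi)
    if 2 * margin >= min(w, h):
        raise InvalidInputError("canvas too small for gland margin")
    classmap = np.zeros((h, w), dtype=np.uint8)

    # stromal tissue ellipse
    m0 = max(32, margin - int(r_hi) - min(w, h) // 16)
    ys = (np.arange(h) - h / 2.0) / (h / 2.0 - m0)
    xs = (np.arange(w) - w / 2.0) / (w / 2.0 - m0)
    tissue = ys[:, None] ** 2 + xs[None, :] ** 2 <= 1.0
    classmap[tissue] = STROMA

    centers, radii = [], []
    for _ in range(spec.n_glands):
        for attempt in range(5000):
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            r = rng.uniform(r_lo, r_hi)
            ok = all(math.hypot(cx - px, cy - py) >= 1.25 * (r + pr)
                     for (px, py), pr in zip(centers, radii))
            if ok:
                centers.append((cx, cy))
                radii.append(r)
                break
        else:
            raise InvalidInputError("could not place glands; reduce count "
                                    "or radius for this canvas")

    for (cx, cy), r in zip(centers, radii):
        y0, y1 = int(cy - r) - 1, int(cy + r) + 2
        x0, x1 = int(cx - r) - 1, int(cx + r) + 2
        yy = np.arange(y0, y1)[:, None] - cy
        xx = np.arange(x0, x1)[None, :] - cx
        d = np.hypot(yy, xx)
        local = classmap[y0:y1, x0:x1]
        local[(d <= r) & (d >= 0.55 * r)] = EPITHELIUM
        local[d < 0.55 * r] = LUMEN

    # ring nuclei + scattered stromal nuclei
    for (cx, cy), r in zip(centers, radii):
        n_nuc = max(8, int(2 * math.pi * r / 18.0))
        rn_base = max(3.0, r / 18.0)
        for ang in rng.uniform(0.0, 2 * math.pi, n_nuc):
            rad = rng.normal(0.775 * r, 0.04 * r)
            ny, nx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            rr, cc = disk((ny, nx), rn_base * rng.uniform(0.8, 1.2),
                          shape=classmap.shape)
            classmap[rr, cc] = NUCLEUS
    for _ in range(8 * spec.n_glands):
        nx = rng.uniform(m0, w - m0)
        ny = rng.uniform(m0, h - m0)
        if classmap[int(ny), int(nx)] == STROMA:
            rr, cc = disk((ny, nx), rng.uniform(3.0, 5.0),
                          shape=classmap.shape)
            classmap[rr, cc] = NUCLEUS

    return PhantomGeometry(classmap=classmap,
                           gland_centers_xy=np.asarray(centers, float).reshape(-1, 2),
                           gland_radii=np.asarray(radii, float))


def render_stain(geometry: PhantomGeometry, profile: StainProfile,
                 M: StainMatrix | None = None) -> np.ndarray:
    """Render the geometry under one stain profile.

    Class weights mix through the stain matrix rows to per-pixel OD, then
    exponentiate to intensity (I = 255 * 10**-OD); since classes are
    discrete this reduces to a 5-entry color lookup.  Background renders
    white.
    """
    if M is None:
        M = default_stain_matrix()
    od = profile.array() @ M.rows  # (5, 3) per-class OD
    colors = 255.0 * np.power(10.0, -od)
    lut = np.clip(np.rint(colors), 0, 255).astype(np.uint8)
    return lut[geometry.classmap]


def _jitter_field(shape: tuple[int, int], amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency displacement field (2, h, w) with magnitude
    strictly below ``amplitude`` everywhere.

    Node spacing is ~512 px (sectioning deformation varies over
    millimetres, not cells).  The field is normalized so the RMS
    displacement is 0.75x the amplitude and then softly saturated
    (tanh) at the amplitude: the deformation is pervasive — typical
    displacements are a substantial fraction of the stated amplitude —
    while the amplitude remains a hard bound."""
    h, w = shape
    gh, gw = max(3, h // 512 + 1), max(3, w // 512 + 1)
    coarse = rng.standard_normal((2, gh, gw))
    coarse = ndimage.gaussian_filter(coarse, sigma=(0, 1.0, 1.0))
    fld = np.stack([
        ndimage.zoom(coarse[c], (h / gh, w / gw), order=1,
                     mode="nearest", grid_mode=True)
        for c in range(2)
    ]).astype(np.float32)
    mag = np.hypot(fld[0], fld[1])
    rms = float(np.sqrt(np.mean(mag ** 2)))
    if rms > 0:
        fld *= np.float32(0.75 * amplitude / rms)
        mag = np.hypot(fld[0], fld[1])
        factor = np.ones_like(mag)
        nz = mag > 0
        factor[nz] = amplitude * np.tanh(mag[nz] / amplitude) / mag[nz]
        fld *= factor
    return fld


def _add_noise(img: np.ndarray, std: float,
               rng: np.random.Generator) -> np.ndarray:
    """Add iid Gaussian sensor noise, quantized to integer intensities.

    Uses a 256-quantile inverse-CDF lookup so the (integer-rounded)
    marginal matches N(0, std) while drawing only one byte per sample.
    """
    from scipy import stats
    lut = np.rint(std * stats.norm.ppf((np.arange(256) + 0.5) / 256.0)
                  ).astype(np.int16)
    noise = lut[rng.integers(0, 256, size=img.shape, dtype=np.uint8)]
    return np.clip(img.astype(np.int16) + noise, 0, 255).astype(np.uint8)


def make_pair(spec: PhantomSpec, M: StainMatrix | None = None
              ) -> tuple[TilePyramid, TilePyramid, PhantomGroundTruth]:
    """Build a (target pyramid, source pyramid, ground truth) triple.

    Target = geometry rendered under profile A.  Source = geometry rendered
    under profile B, resampled so that the *forward* similarity
    (S*, R*, T*) maps source coordinates onto target coordinates, plus the
    optional jitter field and Gaussian noise.  Ground truth carries the
    transform at l_low and >= 1 landmark pair per gland at the base level.
    """
    if M is None:
        M = default_stain_matrix()
    w, h = spec.canvas
    geom = generate_geometry(spec)
    levels = compute_level_dims(w, h, spec.m)
    base = levels[-1].level
    l_low = select_low_level_for_dims(levels, spec.m)
    delta_b = base - l_low

    R = rotation_about_axis(spec.angle_deg)
    T2_low = np.array([spec.shift_xy[1], spec.shift_xy[0]], dtype=float)  # (y, x)
    T_base = T2_low * (2.0 ** delta_b)
    A = spec.scale * R[:2, :2]          # forward linear part, (y, x)
    Ainv = np.linalg.inv(A)

    target = render_stain(geom, spec.profile_a, M)

    # Source raster: pull the structure map through the forward transform
    # (nearest-neighbor resampling of the discrete class field, plus the
    # jitter displacement when requested), then apply profile B's color
    # lookup.  source[p] = render_b(F(p) [+ D(p)]).
    if spec.jitter_px > 0:
        D = _jitter_field((h, w), spec.jitter_px, _rng(spec.seed, 1))
        Y, X = np.meshgrid(np.arange(h, dtype=np.float32),
                           np.arange(w, dtype=np.float32), indexing="ij")
        cy = A[0, 0] * Y + A[0, 1] * X + np.float32(T_base[0]) + D[0]
        cx = A[1, 0] * Y + A[1, 1] * X + np.float32(T_base[1]) + D[1]
        warped_classes = ndimage.map_coordinates(
            geom.classmap, [cy, cx], order=0,
            mode="grid-constant", cval=BACKGROUND)
    else:
        D = None
        warped_classes = ndimage.affine_transform(
            geom.classmap, A, offset=T_base, order=0,
            mode="grid-constant", cval=BACKGROUND, prefilter=False)
    source = render_stain(PhantomGeometry(warped_classes,
                                          geom.gland_centers_xy,
                                          geom.gland_radii),
                          spec.profile_b, M)

    if spec.noise_std > 0:
        target = _add_noise(target, spec.noise_std, _rng(spec.seed, 2))
        source = _add_noise(source, spec.noise_std, _rng(spec.seed, 3))

    # landmark pairs: gland centers in the target; their true source
    # positions solve F(q) + D(q) = p by fixed-point iteration.
    p_xy = geom.gland_centers_xy
    p_yx = p_xy[:, ::-1]
    q_yx = (p_yx - T_base) @ Ainv.T
    if D is not None and len(q_yx):
        for _ in range(4):
            dy = ndimage.map_coordinates(D[0], q_yx.T, order=1, mode="nearest")
            dx = ndimage.map_coordinates(D[1], q_yx.T, order=1, mode="nearest")
            q_yx = (p_yx - np.stack([dy, dx], axis=1) - T_base) @ Ainv.T
    q_xy = q_yx[:, ::-1]
    keep = ((q_xy[:, 0] >= 2) & (q_xy[:, 0] <= w - 3) &
            (q_xy[:, 1] >= 2) & (q_xy[:, 1] <= h - 3))

    gt = PhantomGroundTruth(
        transform=GlobalTransform(S=spec.scale, R=R,
                                  T=np.array([T2_low[0], T2_low[1], 0.0]),
                                  l_low=l_low, m=spec.m),
        landmarks_target_xy=p_xy[keep],
        landmarks_source_xy=q_xy[keep],
        base_level=base, l_low=l_low, geometry=geom, spec=spec,
    )
    return build_pyramid(target, spec.m), build_pyramid(source, spec.m), gt


def sample_spec(
    rng: np.random.Generator | int,
    canvas: tuple[int, int] = (4096, 4096),
    angle_max: float = 15.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
    shift_max: float = 200.0,
    jitter_px: float = 0.0,
    noise_std: float = 2.0,
    **kwargs,
) -> PhantomSpec:
    """Draw a PhantomSpec from the study's similarity regime: angle uniform
    within +/-angle_max degrees, scale uniform in scale_range, per-axis
    shift uniform within +/-shift_max px at l_low."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return PhantomSpec(
        seed=int(rng.integers(2 ** 31)),
        canvas=canvas,
        angle_deg=float(rng.uniform(-angle_max, angle_max)),
        scale=float(rng.uniform(*scale_range)),
        shift_xy=(float(rng.uniform(-shift_max, shift_max)),
                  float(rng.uniform(-shift_max, shift_max))),
        jitter_px=jitter_px,
        noise_std=noise_std,
        **kwargs,
    )
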