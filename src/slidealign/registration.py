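"""Rapid global registration at the low pyramid level.

Pipeline: DoG keypoints with local descriptors on the two cytoplasm feature
maps, descriptor matching with a ratio test, RANSAC consensus under a
similarity model, then closed-form estimation of the global (S, R, T) from
the inlier correspondences:

* scale      S = sqrt( sum ||p'_k||^2 / sum ||q'_k||^2 )  over centred points
* rotation   from the SVD of the covariance C = sum q'_k p'_k^T, with the
  determinant sign fix so the result is always a proper rotation
* translation T = p_bar - R S q_bar

P are target points, Q source points; the estimated transform maps source
coordinates into the target frame.  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .errors import (DegenerateInputError, InsufficientCorrespondencesError,
                     InvalidInputError)
from .pyramid import LevelImage
from .stains import FeatureMap
from .transform import GlobalTransform, warp_similarity

__all__ = [
    "RansacConfig",
    "KeypointSet",
    "CorrespondenceSet",
    "detect_keypoints",
    "match_correspondences",
    "estimate_scale",
    "estimate_rotation",
    "estimate_translation",
    "estimate_global",
    "warp_low_level",
]


@dataclass(frozen=True)
class RansacConfig:
    """Consensus-search parameters (all conventional defaults).

    inlier_threshold : px at l_low; residual bound for consensus membership.
    max_trials       : RANSAC iterations.
    min_inliers      : below this the pair is declared unregistrable.
    ratio            : descriptor nearest/second-nearest ratio-test bound.
    """

    inlier_threshold: float = 3.0
    max_trials: int = 2000
    min_inliers: int = 8
    ratio: float = 0.8


@dataclass
class KeypointSet:
    """DoG keypoints with scales and descriptors; ``xy`` is (N, 2) (x, y)."""

    xy: np.ndarray
    scales: np.ndarray
    descriptors: np.ndarray
    level: int = 0

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class CorrespondenceSet:
    """RANSAC-consistent landmark pairs P (target) and Q (source)."""

    target_xy: np.ndarray  # P, (K, 2)
    source_xy: np.ndarray  # Q, (K, 2)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.target_xy)


def _feature_data(f) -> np.ndarray:
    data = f.data if isinstance(f, (FeatureMap, LevelImage)) else np.asarray(f)
    if data.ndim != 2:
        raise InvalidInputError("feature map must be single-channel")
    return data


def detect_keypoints(f: FeatureMap | np.ndarray) -> KeypointSet:
    """Scale-space DoG extrema with gradient-histogram descriptors.

    Deterministic for fixed input; a featureless image yields an empty set.
    """
    data = _feature_data(f)
    level = f.level if isinstance(f, FeatureMap) else 0
    det = SIFT()
    try:
        det.detect_and_extract(data.astype(np.float32) / 255.0)
    except RuntimeError:  # no extrema found (e.g. uniform image)
        return KeypointSet(xy=np.empty((0, 2)), scales=np.empty(0),
                           descriptors=np.empty((0, 128), dtype=np.uint8),
                           level=level)
    return KeypointSet(xy=det.positions[:, ::-1].astype(float),
                       scales=det.sigmas.astype(float),
                       descriptors=det.descriptors, level=level)


def _closed_form(P: np.ndarray, Q: np.ndarray):
    S = estimate_scale(P, Q)
    R = estimate_rotation(P, Q)
    T = estimate_translation(P, Q, R, S)
    return S, R, T


def _residuals(P: np.ndarray, Q: np.ndarray, S, R, T) -> np.ndarray:
    mapped = Q[:, ::-1] @ (S * R[:2, :2]).T + T[:2]
    return np.linalg.norm(mapped[:, ::-1] - P, axis=1)


def match_correspondences(
    E1: KeypointSet,
    E2: KeypointSet,
    seed: int = 0,
    config: RansacConfig = RansacConfig(),
) -> CorrespondenceSet:
    """Select geometrically consistent pairs between target (E1) and source
    (E2) keypoints: ratio-test descriptor matching, then RANSAC with a
    similarity model.  Raises InsufficientCorrespondencesError when fewer
    than ``config.min_inliers`` pairs survive.
    """
    if len(E1) == 0 or len(E2) == 0:
        raise InsufficientCorrespondencesError("a keypoint set is empty")
    matches = match_descriptors(E1.descriptors, E2.descriptors,
                                max_ratio=config.ratio, cross_check=True)
    if len(matches) < max(3, config.min_inliers):
        raise InsufficientCorrespondencesError(
            f"only {len(matches)} descriptor matches")
    P = E1.xy[matches[:, 0]]
    Q = E2.xy[matches[:, 1]]
    model, inliers = ransac(
        (Q, P), SimilarityTransform, min_samples=3,
        residual_threshold=config.inlier_threshold,
        max_trials=config.max_trials,
        rng=np.random.default_rng(seed),
    )
    if model is None or inliers is None or inliers.sum() < config.min_inliers:
        n = 0 if inliers is None else int(inliers.sum())
        raise InsufficientCorrespondencesError(
            f"only {n} RANSAC inliers (need {config.min_inliers})")
    Pi, Qi = P[inliers], Q[inliers]
    res = _residuals(Pi, Qi, *_closed_form(Pi, Qi))
    return CorrespondenceSet(target_xy=Pi, source_xy=Qi, residuals=res)


# -- closed-form similarity estimation ------------------------------------


def _centred(points_xy) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be (K, 2)")
    mean = pts.mean(axis=0)
    return pts - mean, mean


def estimate_scale(P, Q) -> float:
    """Scale as the square root of the centred-variance ratio of P to Q."""
    Pc, _ = _centred(P)
    Qc, _ = _centred(Q)
    if len(Pc) != len(Qc) or len(Pc) < 2:
        raise InvalidInputError("need matched sets with at least 2 points")
    denom = float((Qc ** 2).sum())
    if denom < 1e-24:
        raise DegenerateInputError("source points are all coincident")
    return float(np.sqrt((Pc ** 2).sum() / denom))


def estimate_rotation(P, Q) -> np.ndarray:
    """Proper rotation aligning centred Q onto centred P.

    SVD of C = sum q'_k p'_k^T on the supported (y, x) plane, with the
    diag(1, det(V U^T)) correction so reflections are never returned; the
    result is embedded in a 3x3 with an inert third axis.
    """
    Pc, _ = _centred(P)
    Qc, _ = _centred(Q)
    if len(Pc) != len(Qc) or len(Pc) < 2:
        raise InvalidInputError("need matched sets with at least 2 points")
    Pyx, Qyx = Pc[:, ::-1], Qc[:, ::-1]
    C = Qyx.T @ Pyx  # 2x2 covariance sum q' p'^T (third axis inert)
    U, s, Vh = np.linalg.svd(C)
    if s[0] < 1e-12:
        raise DegenerateInputError("degenerate point configuration")
    V = Vh.T
    d = np.sign(np.linalg.det(V @ U.T))
    if d == 0:
        raise DegenerateInputError("ambiguous rotation (rank-deficient C)")
    R2 = V @ np.diag([1.0, d]) @ U.T
    R = np.eye(3)
    R[:2, :2] = R2
    return R


def estimate_translation(P, Q, R: np.ndarray, S: float) -> np.ndarray:
    """T = p_bar - R S q_bar, returned in (y, x, 0) order."""
    _, pbar = _centred(P)
    _, qbar = _centred(Q)
    R = np.asarray(R, dtype=float)
    t2 = pbar[::-1] - S * (R[:2, :2] @ qbar[::-1])
    return np.array([t2[0], t2[1], 0.0])


def estimate_global(
    f_target: FeatureMap | np.ndarray,
    f_source: FeatureMap | np.ndarray,
    seed: int = 0,
    config: RansacConfig = RansacConfig(),
    l_low: int | None = None,
    m: int = 256,
) -> GlobalTransform:
    """Full rapid global registration on a pair of low-level feature maps.

    Returns the similarity mapping source coordinates into the target frame
    at the estimation level, with inlier count and mean residual recorded.
    """
    lt = f_target.level if isinstance(f_target, FeatureMap) else 0
    ls = f_source.level if isinstance(f_source, FeatureMap) else 0
    if isinstance(f_target, FeatureMap) and isinstance(f_source, FeatureMap) \
            and lt != ls:
        raise InvalidInputError(f"feature maps at different levels: {lt} != {ls}")
    E1 = detect_keypoints(f_target)
    E2 = detect_keypoints(f_source)
    corr = match_correspondences(E1, E2, seed=seed, config=config)
    S, R, T = _closed_form(corr.target_xy, corr.source_xy)
    return GlobalTransform(
        S=S, R=R, T=T,
        l_low=lt if l_low is None else l_low, m=m,
        inliers=len(corr),
        mean_residual=float(corr.residuals.mean()),
    )


def warp_low_level(src: LevelImage | np.ndarray, g: GlobalTransform) -> LevelImage:
    """Align the low-level source image to the target frame.

    Inverse-mapped bilinear rendering of the forward similarity; pixels
    mapping outside the source are white (slide background).  Output has
    the source's shape.
    """
    level = g.l_low
    if isinstance(src, LevelImage):
        level = src.level
        src = src.data
    out = warp_similarity(src, g.S, g.R2, g.translation_at(level),
                          out_shape=src.shape[:2])
    return LevelImage(level=level, data=out)
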