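"""Landmark-based registration accuracy.

Protocol: corresponding landmarks are annotated on the target and source
slides; source landmarks are forward-mapped by the estimated transform
(with pyramid level calibration) and a pair counts as matched when the
Euclidean distance to its target partner is within a pixel threshold
(default 5 px at the annotation's level).  The per-pair score is the
matched fraction; scores are summarized over slide pairs with mean, sample
standard deviation, standard error and a t-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .transform import GlobalTransform

__all__ = [
    "LandmarkAnnotation",
    "AccuracyReport",
    "read_landmarks",
    "write_landmarks",
    "map_landmarks",
    "landmark_accuracy",
    "summarize",
]

LANDMARK_COLUMNS = ["slide_id", "level", "x", "y", "role"]


@dataclass
class LandmarkAnnotation:
    """A set of annotated points on one slide at one pyramid level."""

    slide_id: str
    level: int
    xy: np.ndarray  # (N, 2) float, (x, y) px at `level`
    role: str = "target"  # "target" | "source"

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.role not in ("target", "source"):
            raise InvalidInputError(f"role must be target/source, got {self.role!r}")


def read_landmarks(path) -> list[LandmarkAnnotation]:
    """Read annotations from CSV with columns slide_id, level, x, y, role."""
    df = pd.read_csv(path)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"landmark CSV missing columns {missing}")
    out = []
    for (sid, level, role), grp in df.groupby(["slide_id", "level", "role"],
                                              sort=True):
        out.append(LandmarkAnnotation(slide_id=str(sid), level=int(level),
                                      xy=grp[["x", "y"]].to_numpy(float),
                                      role=str(role)))
    return out


def write_landmarks(annotations: list[LandmarkAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        for x, y in ann.xy:
            rows.append({"slide_id": ann.slide_id, "level": ann.level,
                         "x": x, "y": y, "role": ann.role})
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def map_landmarks(source_xy, g: GlobalTransform, level: int) -> np.ndarray:
    """Forward-map source landmarks into the target frame at ``level``
    (translation calibrated by 2**(level - l_low))."""
    if level < g.l_low:
        raise InvalidInputError(f"level {level} below estimation level {g.l_low}")
    return g.apply_xy(np.asarray(source_xy, dtype=float), level=level)


def landmark_accuracy(target_xy, mapped_xy, threshold: float = 5.0) -> float:
    """Fraction of landmark pairs within ``threshold`` px of each other."""
    t = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    s = np.asarray(mapped_xy, dtype=float).reshape(-1, 2)
    if len(t) != len(s) or len(t) == 0:
        raise InvalidInputError(
            f"landmark counts mismatch or empty: {len(t)} vs {len(s)}")
    d = np.linalg.norm(t - s, axis=1)
    return float(np.mean(d <= threshold))


@dataclass
class AccuracyReport:
    """Per-pair scores with summary statistics (scores and mean in [0, 1])."""

    scores: np.ndarray
    mean: float
    std: float
    sem: float
    ci95: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.ci95 if self.ci95 is not None else (np.nan, np.nan)
        return pd.DataFrame({
            "mean": [self.mean], "std": [self.std], "sem": [self.sem],
            "ci95_lower": [lo], "ci95_upper": [hi], "n": [len(self.scores)],
        })

    def __str__(self) -> str:
        s = (f"accuracy mean {self.mean:.4f}  std {self.std:.4f}  "
             f"sem {self.sem:.4f}  n={len(self.scores)}")
        if self.ci95 is not None:
            s += f"  95% CI [{self.ci95[0]:.4f}, {self.ci95[1]:.4f}]"
        return s


def summarize(scores) -> AccuracyReport:
    """Mean, sample std, standard error and t-based 95% CI of pair scores.

    With a single score the CI (and std/sem) are omitted; the t interval
    matches small-sample reporting practice.
    """
    arr = np.asarray(scores, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidInputError("no scores to summarize")
    mean = float(arr.mean())
    if arr.size < 2:
        return AccuracyReport(scores=arr, mean=mean, std=0.0, sem=0.0, ci95=None)
    std = float(arr.std(ddof=1))
    sem = std / np.sqrt(arr.size)
    if sem == 0.0:
        ci = (mean, mean)
    else:
        ci = stats.t.interval(0.95, df=arr.size - 1, loc=mean, scale=sem)
        ci = (float(ci[0]), float(ci[1]))
    return AccuracyReport(scores=arr, mean=mean, std=std, sem=float(sem), ci95=ci)
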