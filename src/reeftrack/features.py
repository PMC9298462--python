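"""Overlapping 30-min trajectory segments and their 13 descriptive features.

Each daily 1-min trajectory is cut into 30-min windows with 50% overlap.
Every segment is summarized by 13 geometric and temporal features used for
behavioral classification:

    D      net displacement between first and last point (m)
    L      path length (m)
    S      straightness D / L, in [0, 1]
    A      convex-hull area of the segment (m^2)
    MS     median per-minute displacement (m/min)
    rho    distance of the segment centroid from the global center (m),
           the global center being the coordinate-wise median of all of the
           fish's positions
    DAC5, DAC10   directional autocorrelation: mean cosine of the heading
           change across a 5- or 10-min lag
    SAC5, SAC10   Pearson autocorrelation of the per-minute speed series at
           a 5- or 10-min lag
    DP     normalized time of the segment midpoint within the daytime window
    theta  cosine of the bearing (from the east axis) of the segment
           centroid as seen from the global center
    F      focus 1 - 4A / (pi L^2): high when movement is spatially
           concentrated relative to the distance swum

Features are made unit-free for clustering by dividing each column by its
standard deviation (centering happens inside the PCA stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .prep import DayWindow, RegularTrajectory

FEATURE_NAMES = (
    "D", "L", "S", "A", "MS", "rho",
    "DAC5", "DAC10", "SAC5", "SAC10", "DP", "theta", "F",
)

#: steps shorter than this (m) carry no defined heading; displacements well
#: below the localization error scale (meters) have meaningless bearings
HEADING_EPS = 0.5
#: minimum valid heading pairs for a defined directional autocorrelation
MIN_DAC_PAIRS = 5


@dataclass
class TrajectorySegment:
    """One 30-min window of a daily trajectory at 1-min steps."""

    fish_id: str
    day: int
    start_min: float  # minutes since local midnight
    xy: np.ndarray  # (n, 2), nominally n = 31

    @property
    def duration_min(self) -> float:
        return float(len(self.xy) - 1)

    @property
    def mid_min(self) -> float:
        return self.start_min + self.duration_min / 2.0


def segment_daily(
    traj: RegularTrajectory, length_min: float = 30.0, overlap: float = 0.5
) -> list[TrajectorySegment]:
    """Cut a daily trajectory into fixed-length overlapping windows.

    Windows start every length * (1 - overlap) minutes from the first grid
    point (sunrise); a trailing partial window is discarded. A day shorter
    than one window yields an empty list.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    step = length_min * (1.0 - overlap)
    n = len(traj.times_min)
    day_len = n - 1  # minutes
    segments = []
    k = 0
    while k * step + length_min <= day_len + 1e-9:
        i0 = int(round(k * step))
        i1 = int(round(k * step + length_min))
        segments.append(
            TrajectorySegment(
                fish_id=traj.fish_id,
                day=traj.day,
                start_min=float(traj.times_min[i0]),
                xy=traj.xy[i0 : i1 + 1],
            )
        )
        k += 1
    return segments


def global_center(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise median of all of a fish's positions."""
    return np.median(np.asarray(points, dtype=float), axis=0)


def _directional_autocorr(headings: np.ndarray, valid: np.ndarray, lag: int) -> float:
    ok = valid[:-lag] & valid[lag:]
    if int(ok.sum()) < MIN_DAC_PAIRS:
        return 0.0
    dh = headings[lag:][ok] - headings[:-lag][ok]
    return float(np.mean(np.cos(dh)))


def _speed_autocorr(speeds: np.ndarray, lag: int) -> float:
    a, b = speeds[:-lag], speeds[lag:]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compute_features(
    seg: TrajectorySegment, center: np.ndarray, window: DayWindow
) -> dict[str, float]:
    """The 13 features of one segment (degenerate cases never raise).

    A motionless segment (L = 0) gets S = 0, F = 1, MS = 0: it is maximally
    non-ranging and maximally focused. Collinear or duplicate points give
    A = 0; undefined autocorrelations are imputed as 0.
    """
    xy = np.asarray(seg.xy, dtype=float)
    steps = np.diff(xy, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    d_net = float(np.linalg.norm(xy[-1] - xy[0]))
    length = float(step_len.sum())
    s = d_net / length if length > 0 else 0.0
    hull = MultiPoint(xy).convex_hull
    area = float(getattr(hull, "area", 0.0))
    ms = float(np.median(step_len))
    centroid = xy.mean(axis=0)
    rel = centroid - np.asarray(center, dtype=float)
    rho = float(np.hypot(*rel))
    valid = step_len > HEADING_EPS
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    dac5 = _directional_autocorr(headings, valid, 5)
    dac10 = _directional_autocorr(headings, valid, 10)
    sac5 = _speed_autocorr(step_len, 5)
    sac10 = _speed_autocorr(step_len, 10)
    dp = float(np.clip((seg.mid_min - window.sunrise_min) / window.length_min, 0.0, 1.0))
    theta = float(np.cos(np.arctan2(rel[1], rel[0])))
    f = 1.0 - 4.0 * area / (np.pi * length**2) if length > 0 else 1.0
    return {
        "D": d_net, "L": length, "S": s, "A": area, "MS": ms, "rho": rho,
        "DAC5": dac5, "DAC10": dac10, "SAC5": sac5, "SAC10": sac10,
        "DP": dp, "theta": theta, "F": f,
    }


def feature_table(
    segments: list[TrajectorySegment],
    center: np.ndarray,
    windows: dict[int, DayWindow],
) -> pd.DataFrame:
    """Feature matrix with one row per segment plus identifying columns."""
    rows = []
    for seg in segments:
        feats = compute_features(seg, center, windows[seg.day])
        rows.append({"fish_id": seg.fish_id, "day": seg.day, "start_min": seg.start_min, **feats})
    return pd.DataFrame(rows)


def normalize_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Scale each feature column by its standard deviation (unit-free).

    Returns the scaled table, the per-column standard deviations used, and
    the names of degenerate (zero-variance) columns, whose values are set
    to 0. Identifying columns pass through untouched.
    """
    if len(table) < 2:
        raise ValueError("at least 2 segments are required for scaling")
    out = table.copy()
    sds = {}
    degenerate = []
    for name in FEATURE_NAMES:
        col = table[name].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1))
        sds[name] = sd
        if sd == 0.0:
            out[name] = 0.0
            degenerate.append(name)
        else:
            out[name] = col / sd
    return out, pd.Series(sds), degenerate
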