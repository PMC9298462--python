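"""PCA reduction and agglomerative classification of trajectory segments.

The scaled 13-feature matrix is reduced to its first four principal
components, hierarchically clustered (Ward linkage on Euclidean distances
by default), and cut into flat behavioral classes with a merger-score rule:
merge-height increments are normalized by the total merging cost (the sum
of all merge heights) and the tree is cut at the first increment, scanning
from the bottom, that exceeds the threshold (default 1.5%). A sensitivity
report over nearby thresholds accompanies every cut. Classes are then named
by simple kinematic rules (dwelling / scanning / slow ranging / fast
ranging), with an optional reviewable list of class merges to correct
over-splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

CLASS_NAMES = ("scanning", "dwelling", "fast_ranging", "slow_ranging")
DEFAULT_THRESHOLD = 0.015
SENSITIVITY_GRID = (0.01, 0.015, 0.02, 0.03)


@dataclass
class PCAModel:
    """Loadings and explained-variance fractions of the fitted components."""

    loadings: np.ndarray  # (k, n_features)
    variance_fractions: np.ndarray  # all n_features fractions, non-increasing
    k: int
    mean: np.ndarray  # column means removed before projection

    @property
    def selected_variance(self) -> float:
        return float(self.variance_fractions[: self.k].sum())

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) @ self.loadings.T


def fit_pca(
    scaled: np.ndarray, k: int = 4, variance_target: float | None = None
) -> tuple[PCAModel, np.ndarray]:
    """PCA of the column-centered scaled feature matrix.

    Returns the model and the segment scores on the first k components
    (or the smallest k reaching ``variance_target``). The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    the whole pipeline deterministic.
    """
    x = np.asarray(scaled, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix must be finite")
    n, p = x.shape
    if k > p:
        raise ValueError(f"k={k} exceeds the number of features ({p})")
    full = PCA(n_components=min(n, p), svd_solver="full").fit(x)
    fractions = full.explained_variance_ratio_
    if variance_target is not None:
        k = int(np.searchsorted(np.cumsum(fractions), variance_target)) + 1
        k = min(k, p)
    comps = full.components_[:k].copy()
    # sign convention: largest-|loading| entry positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    model = PCAModel(loadings=comps, variance_fractions=fractions, k=k, mean=full.mean_)
    return model, model.transform(x)


def agglomerate(scores: np.ndarray, method: str = "ward") -> np.ndarray:
    """Hierarchical merge tree on Euclidean distances (scipy linkage)."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("at least 2 rows are required")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    return linkage(x, method=method, metric="euclidean")


def merger_score_classes(tree: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Number of flat classes implied by the merger-score rule.

    Merge-height increments are normalized by the sum of all merge heights;
    scanning the dendrogram bottom-up, the cut is placed at the first
    increment exceeding the threshold. No exceedance means one class.
    """
    h = np.asarray(tree[:, 2], dtype=float)
    total = h.sum()
    if total <= 0:
        return 1
    inc = np.diff(h) / total
    idx = np.nonzero(inc > threshold)[0]
    if len(idx) == 0:
        return 1
    return int(len(h) - idx[0])


@dataclass
class ClusterResult:
    """Flat classes from a linkage tree plus the cut bookkeeping."""

    tree: np.ndarray
    threshold: float
    n_classes: int
    labels: np.ndarray  # 1-based class ids per segment
    class_names: dict[int, str] = field(default_factory=dict)
    sensitivity: dict[float, int] = field(default_factory=dict)

    def named_labels(self) -> np.ndarray:
        if not self.class_names:
            return self.labels.astype(object)
        return np.array([self.class_names.get(int(c), f"class_{c}") for c in self.labels], dtype=object)


def cut_by_merger_score(
    tree: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    sensitivity_grid: tuple[float, ...] = SENSITIVITY_GRID,
) -> ClusterResult:
    """Cut a linkage tree into flat classes with the merger-score rule.

    The result carries a sensitivity report: the class count obtained at
    each threshold of the grid, to verify the cut is not knife-edged.
    """
    k = merger_score_classes(tree, threshold)
    if k == 1:
        warnings.warn("no merge increment exceeds the threshold; returning a single class")
    labels = fcluster(tree, t=k, criterion="maxclust")
    sens = {th: merger_score_classes(tree, th) for th in sensitivity_grid}
    return ClusterResult(tree=tree, threshold=threshold, n_classes=int(labels.max()), labels=labels, sensitivity=sens)


def label_classes(
    result: ClusterResult, features: pd.DataFrame
) -> ClusterResult:
    """Name classes by their kinematics.

    dwelling = lowest median speed; fast ranging = highest; of the remaining
    two, the one with larger net displacement is slow ranging and the other
    (compact, high focus) is scanning. Only a 4-class partition receives the
    full naming; other counts keep generic names.
    """
    classes = sorted(np.unique(result.labels))
    stats = features.groupby(result.labels)[["MS", "D", "F"]].mean()
    names: dict[int, str] = {}
    if len(classes) == 4:
        by_ms = list(stats["MS"].sort_values().index)
        names[int(by_ms[0])] = "dwelling"
        names[int(by_ms[-1])] = "fast_ranging"
        mid = by_ms[1:3]
        if stats.loc[mid[0], "D"] >= stats.loc[mid[1], "D"]:
            names[int(mid[0])], names[int(mid[1])] = "slow_ranging", "scanning"
        else:
            names[int(mid[0])], names[int(mid[1])] = "scanning", "slow_ranging"
    else:
        names = {int(c): f"class_{c}" for c in classes}
    result.class_names = names
    return result


def merge_classes(result: ClusterResult, merge_pairs: list[tuple[int, int]]) -> ClusterResult:
    """Apply reviewer-specified class merges (b absorbed into a).

    The underlying segment partition only coarsens; merging a nonexistent
    class raises.
    """
    labels = result.labels.copy()
    present = set(int(c) for c in np.unique(labels))
    for a, b in merge_pairs:
        if a not in present or b not in present:
            raise ValueError(f"cannot merge: class {a if a not in present else b} does not exist")
        labels[labels == b] = a
        present.discard(b)
    # compact to 1..k preserving order
    remap = {old: i + 1 for i, old in enumerate(sorted(present))}
    labels = np.array([remap[int(c)] for c in labels])
    names = {remap[c]: result.class_names.get(c, f"class_{c}") for c in present} if result.class_names else {}
    return ClusterResult(
        tree=result.tree,
        threshold=result.threshold,
        n_classes=len(present),
        labels=labels,
        class_names=names,
        sensitivity=result.sensitivity,
    )


@dataclass
class ClassOccupancy:
    """Per fish-day class fractions and their across-day-group stability."""

    fractions: pd.DataFrame  # index (fish_id, day), one column per class
    standard_error: pd.Series  # per class, across consecutive-day groups
    se_percent: pd.Series  # 100 * SE / mean fraction


def class_occupancy(
    labels: pd.DataFrame,
    windows: dict[int, "DayWindow"],
    segment_length_min: float = 30.0,
    day_group_size: int = 4,
) -> ClassOccupancy:
    """Fraction of daytime each fish spent in each class, minute-weighted.

    ``labels`` needs fish_id, day, start_min, class columns. Each daytime
    minute splits its weight equally across the (up to two, with 50%
    overlap) segments covering it, so fractions per fish-day sum to one.
    Stability is the standard error of per-class fractions across
    consecutive groups of ``day_group_size`` days.
    """
    classes = sorted(labels["class"].unique())
    recs = []
    for (fish, day), sub in labels.groupby(["fish_id", "day"]):
        w = windows[day]
        n_min = int(np.floor(w.length_min))
        grid = w.sunrise_min + np.arange(n_min) + 0.5  # minute centers
        weight = np.zeros((len(sub), n_min))
        starts = sub["start_min"].to_numpy(dtype=float)
        covers = (grid[None, :] >= starts[:, None]) & (grid[None, :] < (starts + segment_length_min)[:, None])
        n_cover = covers.sum(axis=0)
        cover_ok = n_cover > 0
        weight[:, cover_ok] = covers[:, cover_ok] / n_cover[cover_ok]
        total = weight.sum()
        row = {"fish_id": fish, "day": day}
        for cls in classes:
            m = (sub["class"] == cls).to_numpy()
            row[cls] = weight[m].sum() / total if total > 0 else 0.0
        recs.append(row)
    frac = pd.DataFrame(recs).set_index(["fish_id", "day"]).sort_index()

    # stability across consecutive-day groups, pooled over fish
    group_means = []
    for fish, sub in frac.groupby(level="fish_id"):
        days = sub.index.get_level_values("day").to_numpy()
        order = np.argsort(days)
        vals = sub.to_numpy()[order]
        for i in range(0, len(vals) - day_group_size + 1, day_group_size):
            group_means.append(vals[i : i + day_group_size].mean(axis=0))
    gm = np.asarray(group_means)
    if len(gm) >= 2:
        se = gm.std(axis=0, ddof=1) / np.sqrt(len(gm))
    else:
        se = np.zeros(len(classes))
    se_s = pd.Series(se, index=classes)
    mean_frac = frac.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_pct = 100.0 * se_s / mean_frac.replace(0.0, np.nan)
    return ClassOccupancy(fractions=frac, standard_error=se_s, se_percent=se_pct.fillna(0.0))
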