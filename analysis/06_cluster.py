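"""Classify trajectory segments into behavioral classes, per fish.

Scales the 13 features, reduces them to 4 principal components, clusters
with Ward agglomeration, cuts the tree with the 1.5% merger-score rule
(with a threshold sensitivity report), names the classes by their
kinematics, and summarizes per-day class occupancy and its stability.
"""

import argparse
from pathlib import Path

import pandas as pd

from reeftrack.cluster import (
    agglomerate,
    class_occupancy,
    cut_by_merger_score,
    fit_pca,
    label_classes,
    merge_classes,
)
from reeftrack.features import FEATURE_NAMES, normalize_features
from reeftrack.prep import DayWindow


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=4)
    ap.add_argument("--threshold", type=float, default=0.015)
    ap.add_argument("--linkage", default="ward")
    ap.add_argument("--merge", type=int, nargs=2, action="append", default=[],
                    help="absorb class B into class A (reviewable over-split correction)")
    ap.add_argument("--day-window", type=float, nargs=2, default=(360.0, 1080.0))
    args = ap.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    labels_frames, pca_rows, occ_frames = [], [], []
    for fish, table in features.groupby("fish_id"):
        table = table.reset_index(drop=True)
        scaled, _, _ = normalize_features(table)
        model, scores = fit_pca(scaled[list(FEATURE_NAMES)].to_numpy(), k=args.k)
        tree = agglomerate(scores, args.linkage)
        result = cut_by_merger_score(tree, args.threshold)
        if args.merge:
            result = merge_classes(result, [tuple(m) for m in args.merge])
        result = label_classes(result, table)
        lab = table[["fish_id", "day", "start_min"]].copy()
        lab["class"] = result.named_labels()
        labels_frames.append(lab)
        windows = {int(d): DayWindow(int(d), *args.day_window) for d in table["day"].unique()}
        occ = class_occupancy(lab, windows)
        occ_frames.append(occ.fractions.reset_index())
        for i in range(model.k):
            pca_rows.append(
                {"fish_id": fish, "component": i + 1,
                 "variance_fraction": model.variance_fractions[i],
                 **dict(zip(FEATURE_NAMES, model.loadings[i]))}
            )
        shares = lab["class"].value_counts(normalize=True).round(2).to_dict()
        print(
            f"{fish}: {result.n_classes} classes at {args.threshold:.1%} "
            f"(sensitivity {result.sensitivity}); "
            f"{100 * model.selected_variance:.0f}% variance in {model.k} PCs; "
            f"time shares {shares}; occupancy SE% {occ.se_percent.round(1).to_dict()}"
        )
    pd.concat(labels_frames, ignore_index=True).to_csv(args.results / "labels.csv", index=False)
    pd.DataFrame(pca_rows).to_csv(args.results / "pca_report.csv", index=False)
    pd.concat(occ_frames, ignore_index=True).to_csv(args.results / "class_occupancy.csv", index=False)


if __name__ == "__main__":
    main()
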