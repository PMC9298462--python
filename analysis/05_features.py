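"""Cut daily tracks into 30-min half-overlapping segments; compute the 13
geometric/temporal features of each segment."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reeftrack.features import feature_table, global_center, segment_daily
from reeftrack.prep import DayWindow, RegularTrajectory


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--length", type=float, default=30.0)
    ap.add_argument("--overlap", type=float, default=0.5)
    args = ap.parse_args()

    trajs = pd.read_csv(args.results / "trajectories.csv")
    tables = []
    for fish, sub in trajs.groupby("fish_id"):
        segments, windows = [], {}
        for day, g in sub.groupby("day"):
            rt = RegularTrajectory(
                str(fish),
                int(day),
                g["t_min"].to_numpy(dtype=float),
                g[["x_m", "y_m"]].to_numpy(dtype=float),
                g["interp_flag"].to_numpy(),
            )
            windows[int(day)] = DayWindow(int(day), rt.times_min[0], rt.times_min[-1])
            segments.extend(segment_daily(rt, args.length, args.overlap))
        center = global_center(sub[["x_m", "y_m"]].to_numpy())
        table = feature_table(segments, center, windows)
        tables.append(table)
        print(
            f"{fish}: {len(segments)} segments over {sub['day'].nunique()} days; "
            f"median speed quartiles {np.percentile(table['MS'], [25, 50, 75]).round(1)} m/min"
        )
    pd.concat(tables, ignore_index=True).to_csv(args.results / "features.csv", index=False)


if __name__ == "__main__":
    main()
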