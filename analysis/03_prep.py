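"""Quality control and 1-minute interpolation of the localized tracks.

Applies the 30-fixes-per-daytime-hour rule, keeps contiguous accepted days,
and writes the regular 1-min daytime trajectories for every fish.
"""

import argparse
from pathlib import Path

import pandas as pd

from reeftrack.config import PipelineConfig
from reeftrack.pipeline import stage_prep


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-days", type=int, default=14)
    ap.add_argument("--min-per-hour", type=int, default=30)
    args = ap.parse_args()

    fixes = pd.read_csv(args.results / "fixes.csv")
    cfg = PipelineConfig(prep={"min_per_hour": args.min_per_hour})
    prepared = stage_prep(fixes, cfg, args.n_days)
    frames = []
    for fish, per_day in prepared.trajectories.items():
        for traj in per_day.values():
            frames.append(traj.to_frame())
        print(f"{fish}: {len(per_day)}/{args.n_days} days pass QC, runs {prepared.qc_runs[fish]}")
    pd.concat(frames, ignore_index=True).to_csv(args.results / "trajectories.csv", index=False)


if __name__ == "__main__":
    main()
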