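"""Per-NGA trajectories through the PC1-PC2 morphospace and zone dynamics.

Interpolates each region's path to century spacing and summarises movement
per threshold zone and hemisphere: middle-zone movement should be upward in
PC2, right-zone movement downward, and the visited share of the bounding
grid well below one.
"""

import json
from pathlib import Path

import pandas as pd

from morphospace import trajectories as tj
from morphospace.windows import ThresholdEstimate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

scores = pd.read_csv(RESULTS / "scores.csv")
thr = json.loads((RESULTS / "thresholds.json").read_text())
est = ThresholdEstimate(thr["scale_threshold"], thr["information_threshold"],
                        tuple(thr["segment_slopes"]), thr["fit_rss"])

trajs = tj.build_trajectories(scores)
dense = [tj.interpolate_centuries(t) for t in trajs]
tj.trajectories_to_frame(dense).to_csv(RESULTS / "trajectories.csv", index=False)
print(f"{len(trajs)} NGA trajectories, "
      f"{sum(len(t) for t in dense)} century points after interpolation")

stats = tj.zone_statistics(trajs, est)
stats.to_csv(RESULTS / "zone_stats.csv", index=False)
print(stats.to_string(index=False))

frac = tj.occupancy_fraction(trajs)
print(f"occupied fraction of the PC1-PC2 bounding grid: {frac:.2f} "
      f"(societies use only a narrow band of the possible morphospace)")
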