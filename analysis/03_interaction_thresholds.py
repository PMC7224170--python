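"""The PC1-PC2 interaction: window profile, decomposition, and thresholds.

Computes the mean-PC2 profile in sliding windows along PC1, splits it into
the information-CC and scale-CC contributions, and fits the 3-segment hinge
model whose knots are the Scale and Information Thresholds.
"""

import json
from pathlib import Path

import pandas as pd

from morphospace import pca, windows
from morphospace.data_model import load_cc_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
PUBLISHED = ROOT / "data" / "seshat-cc-table.csv"

source = PUBLISHED if PUBLISHED.exists() else RESULTS / "cc_table.csv"
table = load_cc_table(source)
model = pca.PCAModel.from_json(RESULTS / "pca_model.json")
scores = pd.read_csv(RESULTS / "scores.csv")

prof = windows.sliding_window_profile(scores)
prof.to_csv(RESULTS / "windows.csv", index=False)
print(f"{len(prof)} populated windows; counts: {prof['count'].tolist()}")

decomp = windows.decompose_pc2(model, table)
wd = windows.windowed_decomposition(decomp)
wd.to_csv(RESULTS / "decomposition.csv", index=False)
resid = (decomp["info_part"] + decomp["scale_part"] - decomp["total"]).abs().max()
print(f"decomposition additivity residual: {resid:.2e}")

est = windows.detect_hinges(prof)
with open(RESULTS / "thresholds.json", "w") as fh:
    json.dump({"scale_threshold": est.scale_threshold,
               "information_threshold": est.information_threshold,
               "segment_slopes": list(est.segment_slopes),
               "fit_rss": est.fit_rss}, fh, indent=1)
print(f"Scale Threshold at PC1 = {est.scale_threshold:+.2f}, "
      f"Information Threshold at PC1 = {est.information_threshold:+.2f}")
print(f"segment slopes (fall, rise, fall): "
      f"{', '.join(f'{s:+.2f}' for s in est.segment_slopes)}")
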