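"""Fit the correlation PCA of the nine CCs and report loadings.

Uses the published table if data/seshat-cc-table.csv exists (fetch with
scripts/fetch_published_data.py), else the synthetic panel from step 01.
Writes the fitted model, the loadings report, and per-record scores.
"""

from pathlib import Path

from morphospace import pca
from morphospace.data_model import load_cc_table

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
PUBLISHED = ROOT / "data" / "seshat-cc-table.csv"

source = PUBLISHED if PUBLISHED.exists() else RESULTS / "cc_table.csv"
print(f"input: {source}")
table = load_cc_table(source)
print(f"{len(table)} records, {table.n_polities} polities, {table.n_ngas} NGAs")

model = pca.fit_pca(table)
model.to_json(RESULTS / "pca_model.json")
report = pca.loadings_report(model)
report.to_csv(RESULTS / "loadings.csv")
scores = pca.project(model, table)
scores.to_csv(RESULTS / "scores.csv", index=False)

print("\nloadings (eigenvector * sqrt(eigenvalue)) and % variance:")
print(report.to_string())
print(f"\nPC1 score range: [{scores.PC1.min():.2f}, {scores.PC1.max():.2f}]")
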