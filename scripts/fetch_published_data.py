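"""Fetch the published polity-by-century CC table (network required).

Downloads the repository published alongside the source dataset
(https://github.com/jaewshin/Holocene), locates the CSV holding the nine
Complexity Characteristics, normalises its columns to this package's
canonical schema, attaches Old/New World labels, and writes
``data/seshat-cc-table.csv``.  The data are licensed CC BY-NC-SA by the
Seshat databank and are therefore not redistributed with this package.

Usage:  python scripts/fetch_published_data.py [--url TARBALL_URL]
"""

from __future__ import annotations

import argparse
import io
import sys
import tarfile
import urllib.request
from pathlib import Path

import pandas as pd

REPO_ROOT = Path(__file__).resolve().parent.parent
OUT = REPO_ROOT / "data" / "seshat-cc-table.csv"
DEFAULT_URL = "https://github.com/jaewshin/Holocene/archive/refs/heads/master.tar.gz"

CANONICAL = ["PolPop", "PolTerr", "CapPop", "levels", "gvrnmt",
             "infrastr", "writing", "texts", "money"]

# common header variants seen in Seshat-derived tables
ALIASES = {
    "government": "gvrnmt", "Government": "gvrnmt", "gvrnmnt": "gvrnmt",
    "hierarchy": "levels", "Hierarchy": "levels",
    "infrastructure": "infrastr", "Infrastructure": "infrastr",
    "Money": "money", "Writing": "writing", "Texts": "texts",
    "NGA": "NGA", "PolID": "PolID", "PolityID": "PolID", "polity": "PolID",
    "Time": "Time", "time": "Time", "Year": "Time", "year": "Time",
}

NEW_WORLD_NGAS = ("Finger Lakes", "Cahokia", "Oaxaca", "Lowland Andes",
                  "North Colombia", "Cuzco")


def normalise(df: pd.DataFrame) -> pd.DataFrame | None:
    df = df.rename(columns=ALIASES)
    if not set(CANONICAL) <= set(df.columns):
        return None
    if "NGA" not in df.columns or "Time" not in df.columns:
        return None
    if "PolID" not in df.columns:
        return None
    if "World" not in df.columns:
        df["World"] = [
            "New" if any(frag.lower() in str(nga).lower()
                         for frag in NEW_WORLD_NGAS) else "Old"
            for nga in df["NGA"]
        ]
    return df[["NGA", "PolID", "Time", "World"] + CANONICAL]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--url", default=DEFAULT_URL)
    args = ap.parse_args()

    print(f"downloading {args.url} ...")
    blob = urllib.request.urlopen(args.url, timeout=120).read()
    candidates = []
    with tarfile.open(fileobj=io.BytesIO(blob), mode="r:gz") as tar:
        for member in tar.getmembers():
            if not member.name.endswith(".csv"):
                continue
            fh = tar.extractfile(member)
            if fh is None:
                continue
            try:
                df = pd.read_csv(fh, float_precision="round_trip")
            except Exception:
                continue
            out = normalise(df)
            if out is not None:
                candidates.append((member.name, out))
    if not candidates:
        sys.exit("no CSV with the nine CC columns found in the archive")
    # prefer the table closest to the published 414 records
    name, table = min(candidates, key=lambda kv: abs(len(kv[1]) - 414))
    OUT.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT, index=False)
    print(f"wrote {len(table)} records from {name} to {OUT}")


if __name__ == "__main__":
    main()
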