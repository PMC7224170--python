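"""Schema and I/O for polity-by-century Complexity Characteristic (CC) tables.

The unit of observation is one polity in one century, located in a Natural
Geographic Area (NGA) and labelled Old or New World.  Each record carries the
nine CC values (scale and information-processing measures condensed from the
Seshat databank) in a canonical order that every downstream module shares.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical CC column order; single source of truth for the whole package.
CC_NAMES: tuple[str, ...] = (
    "PolPop", "PolTerr", "CapPop", "levels", "gvrnmt",
    "infrastr", "writing", "texts", "money",
)

#: CCs measuring polity scale (population, territory, hierarchy depth).
SCALE_CCS: tuple[str, ...] = ("PolPop", "PolTerr", "CapPop", "levels")

#: CCs measuring information-processing / transactional capacity.
INFO_CCS: tuple[str, ...] = ("gvrnmt", "infrastr", "writing", "texts", "money")

#: Metadata columns, canonical names.
META_COLUMNS: tuple[str, ...] = ("NGA", "PolID", "Time", "World")

WORLDS = ("Old", "New")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """Table content violates a CC-table invariant."""


@dataclass
class CCTable:
    """A validated polity-by-century table of the nine CCs.

    ``df`` holds one row per (polity, century) with columns
    ``NGA, PolID, Time, World`` followed by the nine CCs in canonical order.
    ``Time`` is a signed integer calendar year (negative = BCE) at century
    resolution.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        cols = list(META_COLUMNS) + list(CC_NAMES)
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df.loc[:, cols].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_polities(self) -> int:
        return self.df["PolID"].nunique()

    @property
    def n_ngas(self) -> int:
        return self.df["NGA"].nunique()

    def cc_matrix(self) -> np.ndarray:
        """Records-by-9 array of CC values in canonical column order."""
        return self.df.loc[:, list(CC_NAMES)].to_numpy(dtype=float)


def validate(table: CCTable) -> list[str]:
    """Return a list of invariant violations (empty iff the table is valid).

    Checked rules: all nine CC cells finite; integer times; unique
    (PolID, Time) keys; strictly increasing times within each NGA record
    block; a single world label per NGA; world labels in {Old, New}.
    """
    df = table.df
    violations: list[str] = []

    cc = df.loc[:, list(CC_NAMES)]
    bad = ~np.isfinite(cc.to_numpy(dtype=float))
    for i, j in zip(*np.nonzero(bad)):
        violations.append(
            f"row {i}: non-finite value in CC '{CC_NAMES[j]}'"
        )

    times = df["Time"]
    if not np.issubdtype(times.dtype, np.integer):
        frac = times.to_numpy(dtype=float) % 1 != 0
        for i in np.nonzero(frac)[0]:
            violations.append(f"row {i}: non-integer Time {times.iloc[i]}")

    dup = df.duplicated(subset=["PolID", "Time"], keep=False)
    for i in np.nonzero(dup.to_numpy())[0]:
        violations.append(
            f"row {i}: duplicate (PolID, Time) key "
            f"({df['PolID'].iloc[i]!r}, {df['Time'].iloc[i]})"
        )

    for nga, sub in df.groupby("NGA", sort=False):
        t = sub["Time"].to_numpy()
        if np.any(np.diff(t) <= 0):
            violations.append(f"NGA {nga!r}: times not strictly increasing")
        worlds = set(sub["World"])
        if len(worlds) > 1:
            violations.append(f"NGA {nga!r}: multiple world labels {sorted(worlds)}")

    bad_world = ~df["World"].isin(WORLDS)
    for i in np.nonzero(bad_world.to_numpy())[0]:
        violations.append(f"row {i}: unknown world label {df['World'].iloc[i]!r}")

    return violations


def load_cc_table(
    path,
    schema_config: dict[str, str] | None = None,
    world_map: dict[str, str] | None = None,
    provenance: str = "",
) -> CCTable:
    """Read a CC table from CSV and validate it.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row) or file-like object.
    schema_config
        Optional mapping from the file's column names to canonical names,
        e.g. ``{"polity": "PolID"}``.
    world_map
        Optional mapping NGA -> world label, used when the file has no
        ``World`` column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema_config:
        df = df.rename(columns=dict(schema_config))

    if "World" not in df.columns and world_map is not None:
        df["World"] = df["NGA"].map(world_map)

    needed = list(META_COLUMNS) + list(CC_NAMES)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    for name in CC_NAMES:
        try:
            df[name] = pd.to_numeric(df[name], errors="raise")
        except (ValueError, TypeError) as exc:
            coerced = pd.to_numeric(df[name], errors="coerce")
            bad_rows = np.nonzero(coerced.isna().to_numpy() & df[name].notna().to_numpy())[0]
            raise SchemaError(
                f"non-numeric value in CC '{name}' at row(s) {bad_rows.tolist()}"
            ) from exc
    try:
        df["Time"] = pd.to_numeric(df["Time"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError("non-numeric Time column") from exc

    if len(df) and (df["Time"].to_numpy(dtype=float) % 1 != 0).any():
        raise SchemaError("Time column contains non-integer years")
    df["Time"] = df["Time"].astype(np.int64)

    df = df.sort_values(["NGA", "Time", "PolID"], kind="mergesort").reset_index(drop=True)
    table = CCTable(df=df, provenance=provenance or str(path))

    dup = df.duplicated(subset=["PolID", "Time"])
    if dup.any():
        raise ValidationError(
            f"duplicate (PolID, Time) keys at rows {np.nonzero(dup.to_numpy())[0].tolist()}"
        )
    problems = validate(table)
    if problems:
        raise ValidationError("; ".join(problems))

    logger.info(
        "loaded CC table: %d records, %d unique polities, %d NGAs",
        len(table), table.n_polities, table.n_ngas,
    )
    return table


def write_cc_table(table: CCTable, path) -> None:
    """Write a CC table to CSV so that a reload reproduces it exactly.

    Numeric text is written with :func:`repr`-level precision, making
    ``load(write(t))`` an identity on the values.
    """
    problems = validate(table)
    if problems:
        raise ValidationError("; ".join(problems))
    out = table.df.copy()
    table_cols = list(META_COLUMNS) + list(CC_NAMES)
    out = out.loc[:, table_cols]
    out.to_csv(path, index=False, float_format="%.17g")
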