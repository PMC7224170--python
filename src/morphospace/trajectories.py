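"""Per-NGA trajectories through the PC1-PC2 morphospace.

Each NGA's records, ordered by century, trace a path in (PC1, PC2).  Gaps of
more than one century are filled by linear interpolation at 100-year spacing,
and movement is summarised per PC1 zone (left of the Scale Threshold, between
the thresholds, right of the Information Threshold) and per hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import ThresholdEstimate

CENTURY = 100


@dataclass
class Trajectory:
    """Time-ordered (PC1, PC2) path of one NGA (or one polity)."""

    nga_id: str
    world: str
    points: pd.DataFrame  # columns: Time, PC1, PC2, observed (bool)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return self.points["Time"].to_numpy()


def build_trajectories(scores: pd.DataFrame, by: str = "NGA") -> list[Trajectory]:
    """Group score records into time-ordered trajectories.

    ``by="NGA"`` connects temporally consecutive records within an NGA even
    across polity changes (the regional view); ``by="PolID"`` yields
    per-polity paths.  Input row order is irrelevant.  Duplicate
    (unit, Time) pairs are an error.
    """
    if by not in ("NGA", "PolID"):
        raise ValueError("by must be 'NGA' or 'PolID'")
    trajs: list[Trajectory] = []
    for unit, sub in scores.groupby(by, sort=True):
        sub = sub.sort_values("Time", kind="mergesort")
        t = sub["Time"].to_numpy()
        if len(np.unique(t)) != len(t):
            dup = t[np.nonzero(np.diff(t) == 0)[0]]
            raise ValueError(f"duplicate times {dup.tolist()} in unit {unit!r}")
        pts = pd.DataFrame({
            "Time": t,
            "PC1": sub["PC1"].to_numpy(dtype=float),
            "PC2": sub["PC2"].to_numpy(dtype=float),
            "observed": True,
        })
        world = sub["World"].iloc[0]
        trajs.append(Trajectory(nga_id=str(unit), world=str(world), points=pts))
    return trajs


def interpolate_centuries(traj: Trajectory) -> Trajectory:
    """Insert linearly interpolated points so consecutive points are 100 y apart.

    Observation gaps must be positive multiples of 100 years (century
    resolution); anything else raises.  Inserted points carry
    ``observed=False`` and lie on the straight segment between their
    bracketing observations.
    """
    pts = traj.points
    if len(pts) < 2:
        return Trajectory(traj.nga_id, traj.world, pts.copy())
    t = pts["Time"].to_numpy(dtype=np.int64)
    gaps = np.diff(t)
    if np.any(gaps <= 0) or np.any(gaps % CENTURY != 0):
        bad = gaps[(gaps <= 0) | (gaps % CENTURY != 0)]
        raise ValueError(
            f"unit {traj.nga_id!r}: gaps {bad.tolist()} are not positive "
            f"multiples of {CENTURY} years"
        )
    rows = []
    xy = pts[["PC1", "PC2"]].to_numpy(dtype=float)
    obs = pts["observed"].to_numpy()
    for i in range(len(pts) - 1):
        k = int(gaps[i] // CENTURY)
        for j in range(k):
            frac = j / k
            rows.append((
                int(t[i] + j * CENTURY),
                xy[i, 0] + frac * (xy[i + 1, 0] - xy[i, 0]),
                xy[i, 1] + frac * (xy[i + 1, 1] - xy[i, 1]),
                bool(obs[i]) if j == 0 else False,
            ))
    rows.append((int(t[-1]), xy[-1, 0], xy[-1, 1], bool(obs[-1])))
    out = pd.DataFrame(rows, columns=["Time", "PC1", "PC2", "observed"])
    return Trajectory(traj.nga_id, traj.world, out)


def zone_statistics(trajs: list[Trajectory],
                    thresholds: ThresholdEstimate) -> pd.DataFrame:
    """Per-zone, per-world summary of century-step movement.

    Every trajectory is interpolated to century spacing; each century segment
    is assigned to the zone of its midpoint PC1 (boundary ties to the left
    zone).  Reported per (zone, world): mean displacement per century in PC1
    and PC2, the dispersion (sd) of PC2 over segment midpoints, and the
    number of segment-centuries.
    """
    recs = []
    for traj in trajs:
        dense = interpolate_centuries(traj)
        xy = dense.points[["PC1", "PC2"]].to_numpy(dtype=float)
        if len(xy) < 2:
            continue
        d = np.diff(xy, axis=0)
        mid = (xy[:-1] + xy[1:]) / 2.0
        for i in range(len(d)):
            zone = thresholds.zone_of(float(mid[i, 0]))
            recs.append((zone, traj.world, d[i, 0], d[i, 1], mid[i, 1]))
    df = pd.DataFrame(recs, columns=["zone", "world", "dPC1", "dPC2", "mid_pc2"])
    if df.empty:
        return pd.DataFrame(columns=["zone", "world", "mean_dpc1", "mean_dpc2",
                                     "pc2_dispersion", "n_segments"])
    out = df.groupby(["zone", "world"]).agg(
        mean_dpc1=("dPC1", "mean"),
        mean_dpc2=("dPC2", "mean"),
        pc2_dispersion=("mid_pc2", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        n_segments=("dPC1", "size"),
    ).reset_index()
    return out


def occupancy_fraction(trajs: list[Trajectory], n_cells: int = 20) -> float:
    """Fraction of the bounding-box grid of (PC1, PC2) cells ever visited.

    A value well below 1 reflects that observed societies occupy only a
    narrow band of the possible morphospace.
    """
    pts = np.concatenate([
        interpolate_centuries(t).points[["PC1", "PC2"]].to_numpy(dtype=float)
        for t in trajs if len(t) > 0
    ])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    ij = np.minimum(((pts - lo) / span * n_cells).astype(int), n_cells - 1)
    visited = len({(int(a), int(b)) for a, b in ij})
    return visited / float(n_cells * n_cells)


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a CSV-ready frame (nga, time, pc1, pc2, observed)."""
    frames = []
    for t in trajs:
        f = t.points.copy()
        f.insert(0, "NGA", t.nga_id)
        f.insert(1, "World", t.world)
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["NGA", "World", "Time", "PC1", "PC2", "observed"])
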