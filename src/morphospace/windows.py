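"""Sliding-window PC2 profile along PC1, its decomposition, and hinge fitting.

The central empirical object is the mean PC2 score inside overlapping
windows along PC1.  Its piecewise shape — falling, rising, falling — defines
two hinge points: the Scale Threshold (growth stops being scale-dominated)
and the Information Threshold (information capacity suffices for renewed
growth in scale).  The profile decomposes exactly into the contribution of
the information CCs and of the scale CCs, because a PC2 score is a linear
combination of z-scored CC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CC_NAMES, INFO_CCS, SCALE_CCS, CCTable
from .pca import PCAModel, project

#: Default CC grouping used by the PC2 decomposition.
DEFAULT_GROUPING: dict[str, str] = {
    **{name: "info" for name in INFO_CCS},
    **{name: "scale" for name in SCALE_CCS},
}


@dataclass
class WindowSpec:
    """Sliding-window geometry on the PC1 axis.

    ``width`` is the window width in PC1 units, ``step`` the spacing of
    window centers (default: width 1.0 stepped by 0.5, i.e. half-overlap).
    ``anchor`` places window centers either on the absolute multiples-of-step
    grid (``"grid"``) or on a grid anchored at the minimum observed PC1
    (``"data"``).  Windows with fewer than ``min_count`` records are dropped.
    """

    width: float = 1.0
    step: float = 0.5
    min_count: int = 1
    anchor: str = "grid"

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if not (0 < self.step <= self.width):
            raise ValueError("need 0 < step <= width")
        if self.anchor not in ("grid", "data"):
            raise ValueError("anchor must be 'grid' or 'data'")

    def centers(self, x_min: float, x_max: float) -> np.ndarray:
        """All candidate window centers whose window intersects [x_min, x_max]."""
        half = self.width / 2.0
        if self.anchor == "grid":
            k_lo = int(np.ceil((x_min - half) / self.step))
            k_hi = int(np.floor((x_max + half) / self.step))
            return np.arange(k_lo, k_hi + 1) * self.step
        n = int(np.floor((x_max + half - x_min) / self.step))
        return x_min + np.arange(0, n + 1) * self.step


def sliding_window_profile(scores: pd.DataFrame, spec: WindowSpec | None = None,
                           value_col: str = "PC2") -> pd.DataFrame:
    """Mean and standard error of PC2 in sliding windows along PC1.

    Window membership is half-open: a record with PC1 value x belongs to the
    window centered at c iff ``c - width/2 <= x < c + width/2``.  SE is the
    sample standard deviation over sqrt(count), reported as 0 for singleton
    windows.  Returns a frame with columns ``center, mean_pc2, se_pc2, count``
    restricted to windows with ``count >= min_count``.
    """
    if spec is None:
        spec = WindowSpec()
    if len(scores) == 0:
        raise ValueError("empty score table")
    x = scores["PC1"].to_numpy(dtype=float)
    y = scores[value_col].to_numpy(dtype=float)
    half = spec.width / 2.0
    rows = []
    for c in spec.centers(x.min(), x.max()):
        mask = (x >= c - half) & (x < c + half)
        n = int(mask.sum())
        if n < max(spec.min_count, 1):
            continue
        vals = y[mask]
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((float(c), float(vals.mean()), se, n))
    return pd.DataFrame(rows, columns=["center", "mean_pc2", "se_pc2", "count"])


def decompose_pc2(model: PCAModel, table: CCTable,
                  grouping: dict[str, str] | None = None,
                  scale_convention: str = "eigenvector") -> pd.DataFrame:
    """Split each record's PC2 score into information and scale parts.

    ``info_part`` is the sum over information CCs of (PC2 eigenvector
    component x z-scored CC value); ``scale_part`` likewise for scale CCs;
    the two add exactly to the PC2 score.  ``scale_convention="loading"``
    multiplies both parts (and the total) by sqrt(eigenvalue 2), matching the
    sqrt(lambda)-scaled loading convention — a constant change of scale.
    """
    grouping = dict(DEFAULT_GROUPING if grouping is None else grouping)
    missing = [c for c in CC_NAMES if c not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover CCs: {missing}")
    extra = [c for c in grouping if c not in CC_NAMES]
    if extra:
        raise ValueError(f"grouping names unknown CCs: {extra}")
    if set(grouping.values()) - {"info", "scale"}:
        raise ValueError("grouping values must be 'info' or 'scale'")

    Z = (table.cc_matrix() - model.cc_means) / model.cc_sds
    v2 = model.eigenvectors[:, 1].copy()
    if scale_convention == "loading":
        v2 = v2 * np.sqrt(model.eigenvalues[1])
    elif scale_convention != "eigenvector":
        raise ValueError("scale_convention must be 'eigenvector' or 'loading'")

    info_mask = np.array([grouping[c] == "info" for c in CC_NAMES])
    info_part = Z[:, info_mask] @ v2[info_mask]
    scale_part = Z[:, ~info_mask] @ v2[~info_mask]

    out = project(model, table).loc[:, ["NGA", "PolID", "Time", "World", "PC1"]]
    out["info_part"] = info_part
    out["scale_part"] = scale_part
    out["total"] = info_part + scale_part
    return out


def windowed_decomposition(decomp: pd.DataFrame,
                           spec: WindowSpec | None = None) -> pd.DataFrame:
    """Average the record-level PC2 parts inside the sliding windows.

    The ``total`` column of the result equals the window mean-PC2 profile
    (up to the decomposition's scale convention), since averaging is linear.
    """
    if spec is None:
        spec = WindowSpec()
    base = sliding_window_profile(decomp, spec, value_col="total")
    info = sliding_window_profile(decomp, spec, value_col="info_part")
    scale = sliding_window_profile(decomp, spec, value_col="scale_part")
    out = base.rename(columns={"mean_pc2": "total", "se_pc2": "se_total"})
    out["info_part"] = info["mean_pc2"].to_numpy()
    out["scale_part"] = scale["mean_pc2"].to_numpy()
    return out


@dataclass
class ThresholdEstimate:
    """Two hinge locations from a 3-segment continuous piecewise-linear fit."""

    scale_threshold: float
    information_threshold: float
    segment_slopes: tuple[float, float, float]
    fit_rss: float

    def zone_of(self, pc1: float) -> int:
        """Zone index: 0 left of the Scale Threshold, 1 between, 2 right.

        Boundary values go to the left zone.
        """
        if pc1 <= self.scale_threshold:
            return 0
        if pc1 <= self.information_threshold:
            return 1
        return 2


def _hinge_design(x: np.ndarray, k1: float, k2: float) -> np.ndarray:
    return np.column_stack([
        np.ones_like(x), x,
        np.clip(x - k1, 0.0, None),
        np.clip(x - k2, 0.0, None),
    ])


def detect_hinges(summary: pd.DataFrame, n_segments: int = 3,
                  grid_step: float = 0.05,
                  weighting: str = "count") -> ThresholdEstimate:
    """Fit a continuous 3-segment piecewise-linear curve to the window profile.

    The two knots are found by exhaustive search over a regular grid of
    candidate positions (spacing ``grid_step``) spanning the window centers;
    for each knot pair the weighted least-squares fit of the continuous
    hinge basis {1, x, (x-k1)+, (x-k2)+} is solved and the pair minimising
    the weighted residual sum of squares wins.  Deterministic given the grid
    (ties broken by scan order: smaller k1, then smaller k2).

    ``weighting`` is ``"count"`` (windows weighted by record count),
    ``"se"`` (inverse squared standard error) or ``"none"``.
    """
    if n_segments != 3:
        raise NotImplementedError("only the 3-segment (two hinge) fit is provided")
    if len(summary) < n_segments + 2:
        raise ValueError(f"need at least {n_segments + 2} windows, got {len(summary)}")
    x = summary["center"].to_numpy(dtype=float)
    y = summary["mean_pc2"].to_numpy(dtype=float)
    if weighting == "count":
        w = summary["count"].to_numpy(dtype=float)
    elif weighting == "se":
        se = summary["se_pc2"].to_numpy(dtype=float)
        w = 1.0 / np.maximum(se, 1e-12) ** 2
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError("weighting must be 'count', 'se' or 'none'")
    sw = np.sqrt(w)

    lo = np.ceil(x.min() / grid_step) * grid_step
    hi = np.floor(x.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    # Interior knots only: each outer segment must contain at least one center.
    grid = grid[(grid > x.min()) & (grid < x.max())]

    best = None
    for i, k1 in enumerate(grid):
        for k2 in grid[i + 1:]:
            A = _hinge_design(x, k1, k2) * sw[:, None]
            coef, _, rank, _ = np.linalg.lstsq(A, y * sw, rcond=None)
            if rank < 4:
                continue
            rss = float(np.sum((A @ coef - y * sw) ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, k1, k2, coef)
    if best is None:
        raise ValueError("no admissible knot pair on the grid")
    rss, k1, k2, coef = best
    slopes = (float(coef[1]),
              float(coef[1] + coef[2]),
              float(coef[1] + coef[2] + coef[3]))
    return ThresholdEstimate(
        scale_threshold=float(k1),
        information_threshold=float(k2),
        segment_slopes=slopes,
        fit_rss=rss,
    )
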