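"""Undersampling corrections: within-region interpolation and density weights.

If the two clusters seen in pooled PC1 scores were a selection artifact —
centuries in the middle of the range simply coded less often — then filling
temporal gaps within each region, or down-weighting records from
densely-sampled neighbourhoods, should dissolve them.  These corrections
feed the weighted mixture fits and the weighted parametric bootstrap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mixtures
from .trajectories import Trajectory, build_trajectories, interpolate_centuries


def interpolate_missing(scores: pd.DataFrame) -> pd.DataFrame:
    """Fill missing centuries within each NGA by linear (PC1, PC2) interpolation.

    Added records are flagged ``interpolated=True`` and never extrapolate
    beyond the NGA's observed span.  Metadata of an interpolated record is
    inherited from the preceding observed record.
    """
    out_frames = []
    for traj in build_trajectories(scores, by="NGA"):
        dense = interpolate_centuries(traj).points
        sub = scores[scores["NGA"] == traj.nga_id].sort_values("Time")
        polid = pd.merge_asof(dense[["Time"]].astype({"Time": "int64"}),
                              sub[["Time", "PolID"]].astype({"Time": "int64"}),
                              on="Time", direction="backward")["PolID"]
        f = dense.copy()
        f.insert(0, "NGA", traj.nga_id)
        f.insert(1, "PolID", polid.to_numpy())
        f.insert(3, "World", traj.world)
        f["interpolated"] = ~f.pop("observed")
        out_frames.append(f)
    return pd.concat(out_frames, ignore_index=True)


def density_weights(scores: pd.DataFrame, radius: float = 0.5,
                    max_weight: float | None = 5.0) -> np.ndarray:
    """Inverse local-density weights along PC1, computed within each region.

    The raw weight of record i is one over the number of records of the same
    NGA whose PC1 lies within ``radius`` of record i (itself included); the
    weights are then normalised to sum to the record count.  Sparse
    neighbourhoods get large weights, densely sampled ones small weights.

    Records at the extremes of a region's PC1 range have half-empty
    neighbourhoods and would receive outsize weights on that artifact alone,
    so normalised weights are winsorised at ``max_weight`` (and renormalised);
    pass ``None`` to disable the cap.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    n = len(scores)
    raw = np.empty(n)
    pc1 = scores["PC1"].to_numpy(dtype=float)
    nga = scores["NGA"].to_numpy()
    for region in np.unique(nga):
        idx = np.nonzero(nga == region)[0]
        x = pc1[idx]
        counts = (np.abs(x[:, None] - x[None, :]) <= radius).sum(axis=1)
        raw[idx] = 1.0 / counts
    w = raw * (n / raw.sum())
    if max_weight is not None:
        for _ in range(50):
            clipped = np.minimum(w, max_weight)
            if np.allclose(clipped.sum(), n, rtol=1e-12):
                break
            w = clipped * (n / clipped.sum())
        w = np.minimum(w, max_weight)
    return w


def weighted_bimodality(scores: pd.DataFrame, weights: np.ndarray,
                        B: int = 999, seed: int = 0) -> mixtures.BootstrapResult:
    """Weighted parametric-bootstrap two-cluster test on PC1 scores.

    Observed fits maximise the weighted log-likelihood.  Null replicates
    reproduce the whole observation design: points are drawn from the
    weighted single-Gaussian fit, thinned by the selection function implied
    by the weights (acceptance proportional to 1/weight at that PC1
    position), given interpolated weights, and refit — so the null
    distribution of the statistic carries the same sparse-and-reweighted
    structure as the data.  With uniform weights this reduces exactly to the
    unweighted :func:`morphospace.mixtures.bootstrap_lrt` (same seed, same
    replicate draws).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(scores) or np.any(w <= 0):
        raise ValueError("need one positive weight per record")
    if not np.isclose(w.sum(), len(scores), rtol=1e-9):
        raise ValueError("weights must be normalised to sum to the record count")
    x = scores["PC1"].to_numpy(dtype=float)
    if np.allclose(w, 1.0):
        return mixtures.bootstrap_lrt(x, B=B, seed=seed)
    if B < 99:
        raise ValueError("B must be at least 99")

    n = len(x)
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(n_random_inits=1, tol=1e-5, max_iter=200)

    def lrt(xs, ws):
        _, mu1, sd1, l1, _ = mixtures._fit_1d_batch(xs, ws, 1, rng)
        _, _, _, l2, _ = mixtures._fit_1d_batch(xs, ws, 2, rng, **fit_kwargs)
        return mu1, sd1, 2.0 * (l2 - l1)

    mu1, sd1, obs = lrt(x.reshape(1, n), w.reshape(1, n))
    observed = float(obs[0])

    order = np.argsort(x)
    xs_obs, ws_obs = x[order], w[order]
    w_of = lambda v: np.interp(v, xs_obs, ws_obs)
    accept_scale = ws_obs.min()
    sims = np.empty((B, n))
    simw = np.empty((B, n))
    for b in range(B):
        got: list[float] = []
        while len(got) < n:
            cand = rng.normal(mu1[0, 0], sd1[0, 0], size=4 * n)
            u = rng.random(4 * n)
            keep = cand[u < accept_scale / w_of(cand)]
            got.extend(keep[: n - len(got)].tolist())
        sims[b] = got
        wv = w_of(sims[b])
        simw[b] = wv * (n / wv.sum())
    _, _, null_stats = lrt(sims, simw)

    p = (1.0 + float((null_stats >= observed).sum())) / (B + 1.0)
    return mixtures.BootstrapResult(observed_stat=observed, null_stats=null_stats,
                                    p_value=p, B=B, seed=seed)
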