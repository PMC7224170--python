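"""Seeded generators for Seshat-like CC panels, the sinusoid toy, and chain data.

Every pipeline stage is testable without any download because the generators
produce data with *known* ground truth:

* :func:`generate_cc_dataset` emulates the structure of the real CC panel —
  regions entering the record at staggered times, century-resolution series
  of nine correlated CCs driven by one latent development state, and
  three-phase growth: scale CCs rise throughout, information CCs stay nearly
  flat below a first latent threshold, rise steeply between the thresholds,
  and plateau beyond the second.  New World regions keep the suppressed
  information growth throughout.
* :func:`generate_sinusoid` is the 2-D toy (x = t, y = sin(freq t)) showing
  that a dominant first component can coexist with rich PC1-PC2 structure.
* :func:`generate_chain_dataset` turns Markov-chain runs into a CC table with
  one dominant dimension, for the clustering-artifact experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CC_NAMES, INFO_CCS, SCALE_CCS, CCTable

CENTURY = 100

# Per-CC response slopes to the latent state (fixed, mildly heterogeneous so
# no two CCs are exact duplicates).
_SCALE_SLOPES = {"PolPop": 1.00, "PolTerr": 0.90, "CapPop": 1.05, "levels": 0.95}
_INFO_SLOPES = {"gvrnmt": 0.95, "infrastr": 0.90, "writing": 1.10,
                "texts": 1.05, "money": 1.00}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic CC-panel generator (defaults = study conditions).

    ``theta1 < theta2`` are the latent thresholds bounding the
    information-growth phase; ``info_lag`` is the factor suppressing
    information-CC growth outside it (and everywhere for New World regions).
    ``drift`` is latent development per century and ``latent_sd`` the random
    walk's step noise.  Durations are drawn uniformly (in centuries) from
    ``duration_range``.
    """

    n_nga: int = 30
    entry_time_range: tuple[int, int] = (-9600, 1400)
    duration_range: tuple[int, int] = (10, 40)
    drift: float = 0.25
    latent_sd: float = 0.08
    noise_sd: float = 0.25
    theta1: float = 3.0
    theta2: float = 6.0
    info_lag: float = 0.1
    rate_mid: float = 1.6
    rate_high: float = 0.25
    scale_mid: float = 0.3
    new_world_stall: float = 0.15
    new_world_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.theta1 < self.theta2:
            raise ValueError("theta1 must be < theta2")
        if self.noise_sd < 0 or self.latent_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 <= self.new_world_fraction <= 1:
            raise ValueError("new_world_fraction must be in [0, 1]")
        if self.n_nga < 1 or self.duration_range[0] < 1:
            raise ValueError("need at least one NGA and positive durations")


@dataclass
class GroundTruth:
    """What the generator actually did: latent paths, phases, thresholds."""

    config: GeneratorConfig
    latent: pd.DataFrame        # NGA, Time, s, phase
    worlds: dict                # NGA -> Old/New

    def info_curve(self, s: np.ndarray) -> np.ndarray:
        """Latent -> information-CC base level (Old World response).

        Nearly flat below theta1 (rate ``info_lag * rate_mid``), steep
        between the thresholds, slow plateau growth above theta2.
        """
        c = self.config
        r_lag = c.info_lag * c.rate_mid
        s = np.asarray(s, dtype=float)
        seg1 = np.minimum(s, c.theta1) * r_lag
        seg2 = np.clip(s - c.theta1, 0, c.theta2 - c.theta1) * c.rate_mid
        seg3 = np.clip(s - c.theta2, 0, None) * c.rate_high
        return seg1 + seg2 + seg3

    def scale_curve(self, s: np.ndarray, world: str = "Old") -> np.ndarray:
        """Latent -> scale-CC base level.

        Full-rate growth below theta1, slowed (``scale_mid``) in the
        information-dominated middle band, full rate again above theta2.
        New World regions, never crossing the information bottleneck, stay
        at the slowed rate beyond theta1.
        """
        c = self.config
        s = np.asarray(s, dtype=float)
        seg1 = np.minimum(s, c.theta1)
        seg2 = np.clip(s - c.theta1, 0, c.theta2 - c.theta1) * c.scale_mid
        seg3 = np.clip(s - c.theta2, 0, None)
        if world == "New":
            return seg1 + c.scale_mid * np.clip(s - c.theta1, 0, None)
        return seg1 + seg2 + seg3

    def noiseless_cc(self, s: np.ndarray, world: str = "Old") -> np.ndarray:
        """Noise-free CC vectors for latent states ``s`` (n, 9)."""
        c = self.config
        s = np.asarray(s, dtype=float)
        if world == "New":
            base_info = c.info_lag * c.rate_mid * s
        else:
            base_info = self.info_curve(s)
        base_scale = self.scale_curve(s, world=world)
        out = np.empty((s.size, len(CC_NAMES)))
        for j, name in enumerate(CC_NAMES):
            if name in _SCALE_SLOPES:
                out[:, j] = _SCALE_SLOPES[name] * base_scale
            else:
                out[:, j] = _INFO_SLOPES[name] * base_info
        return out

    def pc1_thresholds(self, pca_model) -> tuple[float, float]:
        """Generating thresholds mapped to the fitted PC1 axis.

        Projects the noise-free Old-World CC vector at each latent threshold
        through the fitted PCA; this is the PC1 position where the phase
        change is expected to appear.
        """
        cc = self.noiseless_cc(np.array([self.config.theta1, self.config.theta2]))
        z = (cc - pca_model.cc_means) / pca_model.cc_sds
        pc1 = z @ pca_model.eigenvectors[:, 0]
        return float(pc1[0]), float(pc1[1])


def generate_cc_dataset(config: GeneratorConfig | None = None
                        ) -> tuple[CCTable, GroundTruth]:
    """Generate a synthetic CC panel plus its ground truth (seed-reproducible)."""
    c = config or GeneratorConfig()
    rng = np.random.default_rng(c.seed)

    n_new = int(round(c.new_world_fraction * c.n_nga))
    worlds = {}
    rows = []
    latent_rows = []
    t_lo, t_hi = c.entry_time_range
    gt = GroundTruth(config=c, latent=pd.DataFrame(), worlds=worlds)
    for i in range(c.n_nga):
        nga = f"NGA{i:03d}"
        world = "New" if i < n_new else "Old"
        worlds[nga] = world
        entry = int(rng.integers(t_lo // CENTURY, t_hi // CENTURY + 1)) * CENTURY
        dur = int(rng.integers(c.duration_range[0], c.duration_range[1] + 1))
        s = max(0.0, float(rng.uniform(0.0, 0.5)))
        for k in range(dur):
            t = entry + k * CENTURY
            phase = 0 if s < c.theta1 else (1 if s < c.theta2 else 2)
            cc = gt.noiseless_cc(np.array([s]), world=world)[0]
            cc = cc + rng.normal(0.0, c.noise_sd, size=len(CC_NAMES))
            # polity turnover roughly every 8 centuries
            pol = f"{nga}_p{k // 8}"
            rows.append((nga, pol, t, world, *cc))
            latent_rows.append((nga, t, s, phase))
            # New World development stalls once the scale bottleneck is
            # reached: without information capacity, little further growth.
            rate = c.drift * (c.new_world_stall
                              if world == "New" and s >= c.theta1 else 1.0)
            s = max(0.0, s + rate + rng.normal(0.0, c.latent_sd))

    df = pd.DataFrame(rows, columns=["NGA", "PolID", "Time", "World", *CC_NAMES])
    df = df.sort_values(["NGA", "Time"], kind="mergesort").reset_index(drop=True)
    table = CCTable(df=df, provenance=f"synthetic seed={c.seed}")
    truth = GroundTruth(
        config=c,
        latent=pd.DataFrame(latent_rows, columns=["NGA", "Time", "s", "phase"]),
        worlds=worlds,
    )
    return table, truth


def generate_sinusoid(t_min: float = -7.0, t_max: float = 7.0,
                      n_points: int = 1000, frequency: float = 2.0) -> pd.DataFrame:
    """Uniformly sampled (x, y) = (t, sin(frequency * t)) toy dataset."""
    if n_points < 3:
        raise ValueError("need at least 3 points")
    t = np.linspace(t_min, t_max, n_points)
    return pd.DataFrame({"x": t, "y": np.sin(frequency * t)})


def generate_undersampled_scores(n: int = 500, seed: int = 21, *,
                                 sd: float = 2.0, gap_half_width: float = 2.4,
                                 keep_prob: float = 0.2, n_regions: int = 4,
                                 bimodal_truth: bool = False) -> pd.DataFrame:
    """Score-like records with a known sampling confound along PC1.

    With ``bimodal_truth=False`` the true PC1 law is a single Gaussian
    N(0, sd) but the wide middle band (|PC1| < ``gap_half_width``) is
    undersampled: each middle record survives with probability
    ``keep_prob``, manufacturing two apparent clusters out of a unimodal
    truth.  With ``bimodal_truth=True`` the truth is a genuine
    moderate-separation two-component mixture (modes at -1.8 and +1.8, unit
    sds) and no thinning is applied.  Records are assigned round-robin to
    ``n_regions`` regions so density weights can be computed within each.

    The deliberately modest sample size keeps the exercise realistic: with a
    few hundred records, reweighting genuinely restores a selection-thinned
    unimodal law below detectability, while real clusters stay blatant.
    """
    rng = np.random.default_rng(seed)
    if bimodal_truth:
        # each region sits in one cluster, as a real region would
        per = n // n_regions
        parts, regions = [], []
        for r in range(n_regions):
            center = -1.8 if r % 2 == 0 else 1.8
            parts.append(rng.normal(center, 1.0, per))
            regions.extend([f"R{r}"] * per)
        x = np.concatenate(parts)
        return pd.DataFrame({
            "NGA": regions,
            "PolID": [f"{g}_p{i}" for i, g in enumerate(regions)],
            "Time": np.arange(len(x)) * 100,
            "World": "Old",
            "PC1": x,
            "PC2": np.zeros(len(x)),
        })
    else:
        x0 = rng.normal(0.0, sd, n)
        keep = (np.abs(x0) > gap_half_width) | (rng.random(n) < keep_prob)
        x = x0[keep]
    return pd.DataFrame({
        "NGA": [f"R{i % n_regions}" for i in range(len(x))],
        "PolID": [f"R{i % n_regions}_p{i}" for i in range(len(x))],
        "Time": np.arange(len(x)) * 100,
        "World": "Old",
        "PC1": x,
        "PC2": np.zeros(len(x)),
    })


def generate_chain_dataset(transition_matrix: np.ndarray,
                           entry_bin_probs: np.ndarray,
                           n_runs: int, seed: int = 0, *,
                           duration_range: tuple[int, int] = (10, 30),
                           entry_time_range: tuple[int, int] = (0, 0),
                           bin_values: np.ndarray | None = None,
                           value_jitter: float = 0.0) -> CCTable:
    """Map Markov-chain runs onto a CC table with one dominant dimension.

    Each run is one NGA/polity; its bin path is converted to a latent value
    (``bin_values``, default the bin index) and every CC is that value times
    a fixed positive slope, so PC1 of the result recovers the chain state up
    to affine scale.  ``value_jitter`` adds uniform within-bin spread.
    """
    T = np.asarray(transition_matrix, dtype=float)
    B = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    vals = np.arange(B, dtype=float) if bin_values is None else np.asarray(bin_values)
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    slopes = np.array([{**_SCALE_SLOPES, **_INFO_SLOPES}[n] for n in CC_NAMES])
    rows = []
    for r in range(n_runs):
        b = int(rng.choice(B, p=entry_bin_probs))
        entry = int(rng.integers(entry_time_range[0] // CENTURY,
                                 entry_time_range[1] // CENTURY + 1)) * CENTURY
        dur = int(rng.integers(duration_range[0], duration_range[1] + 1))
        nga = f"RUN{r:04d}"
        for k in range(dur):
            v = vals[b]
            if value_jitter > 0:
                v = v + rng.uniform(-value_jitter, value_jitter)
            cc = slopes * v
            rows.append((nga, nga, entry + k * CENTURY, "Old", *cc))
            b = int(np.searchsorted(cum[b], rng.random(), side="right"))
            b = min(b, B - 1)
    df = pd.DataFrame(rows, columns=["NGA", "PolID", "Time", "World", *CC_NAMES])
    return CCTable(df=df, provenance=f"chain synthetic seed={seed}")
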