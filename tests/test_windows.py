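import numpy as np
import pandas as pd
import pytest

from morphospace import windows
from morphospace.data_model import CC_NAMES, INFO_CCS, SCALE_CCS
from morphospace.windows import (DEFAULT_GROUPING, ThresholdEstimate,
                                 WindowSpec, decompose_pc2, detect_hinges,
                                 sliding_window_profile,
                                 windowed_decomposition)


def scores_from(pc1, pc2=None):
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.zeros_like(pc1) if pc2 is None else np.asarray(pc2, dtype=float)
    return pd.DataFrame({"PC1": pc1, "PC2": pc2})


# ---------------------------------------------------------------- window profile

def test_hand_placed_points_match_hand_computed_windows():
    # PC1 positions chosen so membership can be enumerated by hand
    pc1 = [-0.9, -0.6, -0.4, 0.0, 0.1, 0.4, 0.9]
    pc2 = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    prof = sliding_window_profile(scores_from(pc1, pc2), WindowSpec())
    got = {row.center: (row.mean_pc2, row.se_pc2, row["count"])
           for _, row in prof.iterrows()}
    # window [-1.5, -0.5): members -0.9, -0.6 -> mean 1.5, sd sqrt(0.5)
    assert got[-1.0][2] == 2 and got[-1.0][0] == pytest.approx(1.5)
    assert got[-1.0][1] == pytest.approx(np.sqrt(0.5) / np.sqrt(2))
    # window [-1.0, 0.0): members -0.9, -0.6, -0.4 -> mean 2
    assert got[-0.5][2] == 3 and got[-0.5][0] == pytest.approx(2.0)
    # window [-0.5, 0.5): members -0.4, 0.0, 0.1, 0.4 -> mean 4.5
    assert got[0.0][2] == 4 and got[0.0][0] == pytest.approx(4.5)
    # window [0.0, 1.0): members 0.0, 0.1, 0.4, 0.9 -> mean 5.5
    assert got[0.5][2] == 4 and got[0.5][0] == pytest.approx(5.5)
    # window [0.5, 1.5): member 0.9 alone -> SE reported as 0
    assert got[1.0][2] == 1 and got[1.0][1] == 0.0


def test_single_record_covered_with_zero_se():
    prof = sliding_window_profile(scores_from([0.2], [3.3]))
    assert (prof["count"] == 1).all()
    assert (prof["mean_pc2"] == 3.3).all()
    assert (prof["se_pc2"] == 0.0).all()


def test_every_record_counted_exactly_twice_on_the_half_step_grid():
    rng = np.random.default_rng(8)
    pc1 = rng.uniform(-4, 4, 500)
    prof = sliding_window_profile(scores_from(pc1), WindowSpec(width=1.0, step=0.5))
    assert prof["count"].sum() == 2 * len(pc1)


def test_min_count_drops_sparse_windows():
    prof = sliding_window_profile(scores_from([-3.0, 0.0, 0.1, 0.2]),
                                  WindowSpec(min_count=2))
    assert (prof["count"] >= 2).all()
    assert prof["center"].min() > -3.0


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(width=0.0)
    with pytest.raises(ValueError):
        WindowSpec(step=2.0, width=1.0)
    with pytest.raises(ValueError):
        WindowSpec(anchor="elsewhere")
    with pytest.raises(ValueError):
        sliding_window_profile(scores_from([]))


# ---------------------------------------------------------------- decomposition

def test_decomposition_adds_exactly_to_pc2(default_dataset, default_model, default_scores):
    table, _ = default_dataset
    decomp = decompose_pc2(default_model, table)
    assert np.allclose(decomp["info_part"] + decomp["scale_part"],
                       decomp["total"], atol=1e-15)
    assert np.max(np.abs(decomp["total"].to_numpy()
                         - default_scores["PC2"].to_numpy())) < 1e-12


def test_default_grouping_matches_cc_semantics():
    assert {c for c, g in DEFAULT_GROUPING.items() if g == "info"} == set(INFO_CCS)
    assert {c for c, g in DEFAULT_GROUPING.items() if g == "scale"} == set(SCALE_CCS)


def test_decomposition_parts_match_hand_computation(default_dataset, default_model):
    table, _ = default_dataset
    decomp = decompose_pc2(default_model, table)
    Z = (table.cc_matrix() - default_model.cc_means) / default_model.cc_sds
    v2 = default_model.eigenvectors[:, 1]
    info_idx = [CC_NAMES.index(c) for c in INFO_CCS]
    hand = Z[:, info_idx] @ v2[info_idx]
    assert np.allclose(decomp["info_part"].to_numpy(), hand, atol=1e-12)


def test_loading_scale_convention_is_constant_multiple(default_dataset, default_model):
    table, _ = default_dataset
    a = decompose_pc2(default_model, table, scale_convention="eigenvector")
    b = decompose_pc2(default_model, table, scale_convention="loading")
    factor = np.sqrt(default_model.eigenvalues[1])
    assert np.allclose(b["total"], factor * a["total"], atol=1e-12)


def test_incomplete_grouping_rejected(default_dataset, default_model):
    table, _ = default_dataset
    bad = dict(DEFAULT_GROUPING)
    bad.pop("money")
    with pytest.raises(ValueError, match="money"):
        decompose_pc2(default_model, table, grouping=bad)


def test_windowed_total_equals_window_profile(default_dataset, default_model,
                                              default_scores):
    table, _ = default_dataset
    decomp = decompose_pc2(default_model, table)
    wd = windowed_decomposition(decomp)
    prof = sliding_window_profile(default_scores)
    assert np.allclose(wd["total"].to_numpy(), prof["mean_pc2"].to_numpy(), atol=1e-12)
    assert np.allclose(wd["info_part"] + wd["scale_part"], wd["total"], atol=1e-12)


# ---------------------------------------------------------------- hinge detection

def piecewise(x, k1, k2, b0, s1, s2, s3):
    y = b0 + s1 * np.minimum(x, k1)
    y = y + s2 * np.clip(x - k1, 0, k2 - k1)
    return y + s3 * np.clip(x - k2, 0, None)


def test_noiseless_hinges_recovered_exactly():
    centers = np.arange(-4.0, 2.01, 0.5)
    y = piecewise(centers, -2.5, -0.5, 0.0, -1.0, 1.0, -0.5)
    summary = pd.DataFrame({"center": centers, "mean_pc2": y,
                            "se_pc2": 0.0, "count": 10})
    est = detect_hinges(summary)
    assert est.scale_threshold == pytest.approx(-2.5, abs=1e-9)
    assert est.information_threshold == pytest.approx(-0.5, abs=1e-9)
    assert est.fit_rss == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(est.segment_slopes, [-1.0, 1.0, -0.5], atol=1e-9)


def brute_force_hinges(summary, grid_step=0.05):
    """Independent exhaustive search oracle (naive loops, explicit algebra)."""
    x = summary["center"].to_numpy(dtype=float)
    y = summary["mean_pc2"].to_numpy(dtype=float)
    w = summary["count"].to_numpy(dtype=float)
    lo = np.ceil(x.min() / grid_step) * grid_step
    hi = np.floor(x.max() / grid_step) * grid_step
    grid = [g for g in np.arange(lo, hi + grid_step / 2, grid_step)
            if x.min() < g < x.max()]
    best = None
    for i, k1 in enumerate(grid):
        for k2 in grid[i + 1:]:
            A = np.column_stack([np.ones_like(x), x,
                                 np.clip(x - k1, 0, None),
                                 np.clip(x - k2, 0, None)])
            Aw = A * np.sqrt(w)[:, None]
            coef, _, rank, _ = np.linalg.lstsq(Aw, y * np.sqrt(w), rcond=None)
            if rank < 4:
                continue
            rss = float(((Aw @ coef - y * np.sqrt(w)) ** 2).sum())
            if best is None or rss < best[0] - 1e-15:
                best = (rss, k1, k2)
    return best[1], best[2]


def test_estimator_equals_brute_force_on_noisy_profile():
    rng = np.random.default_rng(17)
    centers = np.arange(-4.0, 3.01, 0.5)
    y = piecewise(centers, -2.2, -0.3, 0.5, -0.8, 0.9, -0.4) + rng.normal(0, 0.05, centers.size)
    summary = pd.DataFrame({"center": centers, "mean_pc2": y, "se_pc2": 0.05,
                            "count": rng.integers(5, 100, centers.size)})
    est = detect_hinges(summary)
    k1, k2 = brute_force_hinges(summary)
    assert est.scale_threshold == pytest.approx(k1, abs=1e-12)
    assert est.information_threshold == pytest.approx(k2, abs=1e-12)
    assert est.scale_threshold < est.information_threshold


def test_too_few_windows_rejected():
    summary = pd.DataFrame({"center": [0.0, 0.5, 1.0, 1.5],
                            "mean_pc2": [0, 1, 0, 1],
                            "se_pc2": 0.0, "count": 1})
    with pytest.raises(ValueError, match="windows"):
        detect_hinges(summary)


def test_zone_assignment_boundaries():
    est = ThresholdEstimate(-2.5, -0.5, (0, 0, 0), 0.0)
    assert est.zone_of(-3.0) == 0
    assert est.zone_of(-2.5) == 0          # boundary goes left
    assert est.zone_of(-1.0) == 1
    assert est.zone_of(-0.5) == 1
    assert est.zone_of(2.0) == 2
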