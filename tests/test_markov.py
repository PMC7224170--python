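import numpy as np
import pandas as pd
import pytest

from morphospace import markov, mixtures, pca, synthetic
from morphospace.markov import (MarkovModel, artifact_experiment,
                                development_chain, drift_chain,
                                estimate_markov, make_chain_model,
                                saturation_experiment, simulate_ensemble)

FIVE_BIN = np.array([
    [0.6, 0.4, 0.0, 0.0, 0.0],
    [0.1, 0.5, 0.4, 0.0, 0.0],
    [0.0, 0.1, 0.5, 0.4, 0.0],
    [0.0, 0.0, 0.1, 0.5, 0.4],
    [0.0, 0.0, 0.0, 0.2, 0.8],
])
FIVE_ENTRY = np.array([0.4, 0.3, 0.2, 0.1, 0.0])


def score_frame(rows):
    return pd.DataFrame(rows, columns=["NGA", "PolID", "Time", "World", "PC1"])


# ---------------------------------------------------------------- estimation

def test_hand_counted_transitions():
    rows = [("A", "p", 0, "Old", 0.5), ("A", "p", 100, "Old", 1.5),
            ("A", "p", 200, "Old", 2.5)]
    m = estimate_markov(score_frame(rows), bin_edges=np.arange(0.0, 4.0), min_pairs=1)
    expect = np.eye(3)
    expect[0] = [0, 1, 0]
    expect[1] = [0, 0, 1]
    assert np.allclose(m.transition_matrix, expect)
    assert m.entry_bin_probs[0] == 1.0
    assert m.duration_probs == {3: 1.0}


def test_static_units_give_the_identity_matrix():
    rows = []
    for g in "ABCDE":
        for k in range(12):
            rows.append((g, g, k * 100, "Old", ord(g) % 5 + 0.5))
    m = estimate_markov(score_frame(rows), bin_edges=np.arange(0.0, 6.0), min_pairs=1)
    assert np.allclose(m.transition_matrix, np.eye(5))


def test_gap_pairs_are_excluded_from_estimation():
    rows = [("A", "p", 0, "Old", 0.5), ("A", "p", 300, "Old", 2.5),
            ("A", "p", 400, "Old", 2.5)]
    m = estimate_markov(score_frame(rows), bin_edges=np.arange(0.0, 4.0), min_pairs=1)
    # only the 300->400 pair counts; the 3-century gap contributes nothing
    assert m.transition_matrix[2, 2] == 1.0
    assert np.allclose(m.transition_matrix[0], [1, 0, 0])


def test_too_few_pairs_is_an_error():
    rows = [("A", "p", 0, "Old", 0.5), ("A", "p", 100, "Old", 1.5)]
    with pytest.raises(ValueError, match="pairs"):
        estimate_markov(score_frame(rows), n_bins=3)


def test_rows_remain_stochastic_with_smoothing():
    rows = [("A", "p", k * 100, "Old", 0.5 + 0.2 * k) for k in range(30)]
    m = estimate_markov(score_frame(rows), n_bins=4, laplace=1.0, min_pairs=1)
    assert np.allclose(m.transition_matrix.sum(axis=1), 1.0, atol=1e-9)


def test_five_bin_chain_recovered_through_the_full_pipeline():
    table = synthetic.generate_chain_dataset(FIVE_BIN, FIVE_ENTRY, n_runs=200,
                                             seed=9, duration_range=(15, 25))
    model = pca.fit_pca(table)
    scores = pca.project(model, table)
    m = estimate_markov(scores, n_bins=5)
    assert np.abs(m.transition_matrix - FIVE_BIN).max() < 0.05


def test_model_json_roundtrip(tmp_path):
    m = make_chain_model(FIVE_BIN, FIVE_ENTRY, (0, 500), {10: 0.5, 20: 0.5})
    path = tmp_path / "markov.json"
    m.to_json(path)
    back = MarkovModel.from_json(path)
    assert np.allclose(back.transition_matrix, m.transition_matrix)
    assert back.duration_probs == m.duration_probs


def test_invalid_matrices_rejected():
    bad = FIVE_BIN.copy()
    bad[0, 0] += 0.1
    with pytest.raises(ValueError, match="sum to 1"):
        make_chain_model(bad, FIVE_ENTRY)


# ---------------------------------------------------------------- simulation

def test_identity_chain_keeps_every_run_at_its_entry_bin():
    m = make_chain_model(np.eye(4), np.array([0.25, 0.25, 0.25, 0.25]),
                         (0, 0), {20: 1.0})
    snap = simulate_ensemble(m, n_runs=50, horizon=10 ** 6, seed=1)
    per_run = snap.records.groupby("run")["bin"].nunique()
    assert (per_run == 1).all()
    entry_counts = snap.records.groupby("run")["bin"].first().value_counts()
    hist_runs = np.zeros(4)
    hist_runs[entry_counts.index] = entry_counts.to_numpy()
    assert np.allclose(snap.histogram, hist_runs * 20)


def test_two_state_long_run_occupancy_matches_stationary_law():
    # up 0.1, down 0.05 -> stationary (1/3, 2/3)
    T = np.array([[0.9, 0.1], [0.05, 0.95]])
    m = make_chain_model(T, np.array([1.0, 0.0]), (0, 0), {2000: 1.0})
    snap = simulate_ensemble(m, n_runs=5, horizon=10 ** 9, seed=7)
    occ = snap.histogram / snap.histogram.sum()
    assert occ[1] == pytest.approx(2.0 / 3.0, abs=0.05)


def test_ensemble_cross_section_matches_matrix_power():
    k_steps = 5
    m = make_chain_model(FIVE_BIN, np.array([1.0, 0, 0, 0, 0]), (0, 0),
                         {k_steps + 1: 1.0})
    n_runs = 10000
    snap = simulate_ensemble(m, n_runs=n_runs, horizon=k_steps * 100, seed=3,
                             record_window=1)
    occ = snap.histogram / snap.histogram.sum()
    expect = np.linalg.matrix_power(FIVE_BIN, k_steps)[0]
    mc_sd = np.sqrt(expect * (1 - expect) / n_runs)
    assert np.all(np.abs(occ - expect) <= 3 * mc_sd + 1e-12)


def test_pooled_finite_runs_look_clustered_but_one_long_run_does_not():
    T, entry = development_chain()
    m = make_chain_model(T, entry)
    m.entry_times = np.array([-30000.0, 0.0])
    pooled = simulate_ensemble(m, n_runs=150, horizon=0, seed=3)
    rng = np.random.default_rng(3)
    vals = rng.choice(pooled.values(m, jitter_rng=rng), 600, replace=False)
    assert mixtures.bimodality_verdict(vals, seed=1)["bimodal"]

    single = simulate_ensemble(m, n_runs=1, horizon=10 ** 9, seed=5,
                               entry_times=np.array([0.0]),
                               durations=np.array([5000]))
    rng = np.random.default_rng(5)
    svals = rng.choice(single.values(m, jitter_rng=rng), 600, replace=False)
    assert not mixtures.bimodality_verdict(svals, seed=1)["bimodal"]


# ---------------------------------------------------------------- experiments

def test_staggered_entries_fake_two_clusters_but_common_entry_does_not():
    T, entry = development_chain()
    m = make_chain_model(T, entry)
    res = artifact_experiment(m, n_runs=120, horizon=30000, seed=0,
                              record_window=15, entry_span=300)
    assert res["staggered"]["p_value"] <= 0.01
    assert res["common"]["p_value"] > 0.01
    assert res["artifact_reproduced"]


def test_absorbing_bound_piles_the_upper_mode_at_the_boundary():
    T = drift_chain(10, p_up=0.15, p_down=0.03)
    entry = np.zeros(10)
    entry[:3] = [0.5, 0.3, 0.2]
    m = make_chain_model(T, entry, duration_probs={40: 0.5, 80: 0.5})
    res = saturation_experiment(m, seed=4, mode="absorbing")
    assert res["mode_at_bound"]
    assert res["upper_mode_bin"] == res["bound_bin"]


def test_reflected_symmetric_walk_has_no_boundary_mode():
    T = drift_chain(10, p_up=0.25, p_down=0.25)
    m = make_chain_model(T, np.full(10, 0.1), duration_probs={200: 1.0})
    res = saturation_experiment(m, seed=4, mode="reflecting", n_runs=200)
    h = np.asarray(res["histogram"])
    h = h / h.sum()
    assert h.max() / h.min() < 1.3, "occupancy approximately uniform"
    assert not res["mode_at_bound"] or h[-1] <= h.max() * 1.01
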