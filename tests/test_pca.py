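import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

from morphospace import pca
from morphospace.data_model import CC_NAMES, CCTable
from morphospace.pca import (DegenerateInputError, PCAModel, fit_pca,
                             loadings_report, principal_axes, project)

from conftest import make_cc_frame


# ---------------------------------------------------------------- 2-variable closed forms

def test_uncorrelated_two_variables_split_variance_evenly():
    # four points with exactly zero sample correlation
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    _, _, _, evals = principal_axes(X, standardize=True)
    assert np.allclose(evals, [1.0, 1.0])


def test_correlated_pair_matches_closed_form():
    rng = np.random.default_rng(3)
    z = rng.normal(size=(200, 2))
    X = np.column_stack([z[:, 0], 0.6 * z[:, 0] + 0.8 * z[:, 1]])
    r = np.corrcoef(X, rowvar=False)[0, 1]
    _, _, evecs, evals = principal_axes(X, standardize=True)
    # eigenvalues of a 2x2 correlation matrix are 1 +/- |r|
    assert np.allclose(evals, [1 + abs(r), 1 - abs(r)], atol=1e-12)
    assert evals[0] / evals.sum() == pytest.approx((1 + abs(r)) / 2, abs=1e-12)
    # loadings of PC1 are both sqrt((1+r)/2) up to sign
    loading = evecs[:, 0] * np.sqrt(evals[0])
    assert np.allclose(np.abs(loading), np.sqrt((1 + abs(r)) / 2), atol=1e-12)


# ---------------------------------------------------------------- model invariants

def test_model_invariants_on_synthetic_panel(default_model):
    m = default_model
    assert m.eigenvalues.sum() == pytest.approx(9.0, abs=1e-9)
    assert np.allclose(m.eigenvectors.T @ m.eigenvectors, np.eye(9), atol=1e-9)
    assert np.all(np.diff(m.eigenvalues) <= 1e-12)
    L = m.loadings
    assert np.all(L[:, 0] > 0), "every CC loads positively on PC1"
    for name in ("writing", "texts", "money"):
        assert L[CC_NAMES.index(name), 1] > 0
    for name in ("PolPop", "PolTerr", "CapPop"):
        assert L[CC_NAMES.index(name), 1] < 0
    # loadings reconstruct the correlation matrix
    assert np.allclose(L @ L.T, np.corrcoef(_z(default_model), rowvar=False), atol=1e-9)


def _z(model):
    # reconstruct z-scores used in the fit via the session dataset
    from conftest import make_cc_frame  # noqa: F401  (import side-effect free)
    import morphospace.synthetic as synthetic
    table, _ = synthetic.generate_cc_dataset(synthetic.GeneratorConfig(seed=0))
    return (table.cc_matrix() - model.cc_means) / model.cc_sds


def test_score_moments_match_eigenvalues(default_dataset, default_model, default_scores):
    S = default_scores[[f"PC{j}" for j in range(1, 10)]].to_numpy()
    assert np.allclose(S.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(S.var(axis=0, ddof=1), default_model.eigenvalues, atol=1e-9)


def test_fit_is_invariant_to_row_order(default_dataset, default_model):
    table, _ = default_dataset
    shuffled = CCTable(df=table.df.sample(frac=1.0, random_state=5).reset_index(drop=True))
    m2 = fit_pca(shuffled)
    assert np.allclose(m2.eigenvectors, default_model.eigenvectors, atol=1e-9)
    assert np.allclose(m2.eigenvalues, default_model.eigenvalues, atol=1e-9)


def test_eigenvalues_match_brute_force_and_sklearn():
    rng = np.random.default_rng(11)
    base = rng.normal(size=(50, 3))
    X = base @ rng.normal(size=(3, 9)) + 0.3 * rng.normal(size=(50, 9))
    _, _, _, evals = principal_axes(X, standardize=True)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    brute = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    assert np.allclose(evals, brute, atol=1e-8)
    sk = SkPCA(n_components=9).fit(Z)
    assert np.allclose(evals / 9, sk.explained_variance_ratio_, atol=1e-8)


# ---------------------------------------------------------------- projection

def test_record_at_the_mean_scores_zero(default_dataset, default_model):
    table, _ = default_dataset
    df = table.df.iloc[:1].copy()
    df.loc[:, list(CC_NAMES)] = default_model.cc_means
    scores = project(default_model, CCTable(df=df))
    assert np.allclose(scores[[f"PC{j}" for j in range(1, 10)]].to_numpy(), 0.0,
                       atol=1e-12)


def test_projection_equals_hand_computed_matrix_product(default_model, tiny_table):
    m = default_model
    Z = (tiny_table.cc_matrix() - m.cc_means) / m.cc_sds
    expected = Z @ m.eigenvectors
    got = project(m, tiny_table)[[f"PC{j}" for j in range(1, 10)]].to_numpy()
    assert np.allclose(got, expected, atol=1e-12)


def test_projection_schema_mismatch():
    m = PCAModel(cc_means=np.zeros(3), cc_sds=np.ones(3),
                 eigenvectors=np.eye(3), eigenvalues=np.ones(3))
    df = make_cc_frame([("A", "p", 0, "Old", *([1.0] * 9))])
    with pytest.raises(ValueError, match="schema"):
        project(m, CCTable(df=df))


# ---------------------------------------------------------------- errors & misc

def test_zero_variance_cc_is_named():
    rows = [("A", f"p{i}", i * 100, "Old", 5.0, *np.random.default_rng(i).uniform(1, 2, 8))
            for i in range(12)]
    with pytest.raises(DegenerateInputError, match="PolPop"):
        fit_pca(CCTable(df=make_cc_frame(rows)))


def test_too_few_records_rejected(tiny_table):
    with pytest.raises(DegenerateInputError, match="10"):
        fit_pca(tiny_table)


def test_loadings_report_layout(default_model):
    rep = loadings_report(default_model)
    assert list(rep.index) == ["PC1", "PC2"]
    assert list(rep.columns) == list(CC_NAMES) + ["%Var"]
    L = default_model.loadings
    assert rep.loc["PC1", "PolPop"] == pytest.approx(round(float(L[0, 0]), 2))
    assert rep.loc["PC2", "%Var"] == pytest.approx(
        round(float(default_model.var_fraction[1]), 1))


def test_model_json_roundtrip(default_model, tmp_path):
    path = tmp_path / "model.json"
    default_model.to_json(path)
    back = PCAModel.from_json(path)
    assert np.allclose(back.eigenvectors, default_model.eigenvectors)
    assert np.allclose(back.eigenvalues, default_model.eigenvalues)
    assert np.allclose(back.cc_means, default_model.cc_means)
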