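"""Correlation-matrix PCA of the nine CCs with deterministic sign conventions.

The morphospace axes used throughout the package are principal components of
the z-scored CC table.  Scores are projections onto unit eigenvectors, so the
variance of PC j equals its eigenvalue; loadings are eigenvectors scaled by
sqrt(eigenvalue), i.e. correlations between each CC and each component.

Sign conventions (eigenvector signs are arbitrary and are fixed after the
eigendecomposition):

* PC1 points in the direction where every CC loads positively (overall
  sociopolitical complexity increases to the right);
* PC2 points in the direction where the information CCs (writing, texts,
  money) load positively and the scale CCs negatively;
* every further component is oriented so its largest-magnitude loading is
  positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CC_NAMES, INFO_CCS, CCTable


class DegenerateInputError(ValueError):
    """PCA input has a zero-variance column or too few rows."""


@dataclass
class PCAModel:
    """Fitted correlation-matrix PCA of the nine CCs."""

    cc_means: np.ndarray          # (9,)
    cc_sds: np.ndarray            # (9,) sample sd, n-1 denominator
    eigenvectors: np.ndarray      # (9, 9), columns = components
    eigenvalues: np.ndarray       # (9,), non-increasing

    @property
    def loadings(self) -> np.ndarray:
        """Eigenvector columns scaled by sqrt(eigenvalue)."""
        return self.eigenvectors * np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def var_fraction(self) -> np.ndarray:
        """Percent of total variance per component (eigenvalue / p * 100)."""
        return self.eigenvalues / self.eigenvalues.size * 100.0

    def to_json(self, path) -> None:
        doc = {
            "cc_names": list(CC_NAMES),
            "cc_means": self.cc_means.tolist(),
            "cc_sds": self.cc_sds.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            cc_means=np.asarray(doc["cc_means"], dtype=float),
            cc_sds=np.asarray(doc["cc_sds"], dtype=float),
            eigenvectors=np.asarray(doc["eigenvectors"], dtype=float),
            eigenvalues=np.asarray(doc["eigenvalues"], dtype=float),
        )


def principal_axes(X: np.ndarray, standardize: bool = True):
    """Eigendecomposition of the covariance or correlation matrix of ``X``.

    Returns ``(means, sds, eigenvectors, eigenvalues)`` with eigenvalues in
    non-increasing order and no sign convention applied.  With
    ``standardize=False`` the sds returned are all 1 and the decomposition is
    of the covariance matrix (used by the sinusoid demonstration, where the
    raw geometry of the two coordinates is the point).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("need a 2-D array with at least 2 rows")
    means = X.mean(axis=0)
    if standardize:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0):
            j = int(np.nonzero(sds == 0)[0][0])
            raise DegenerateInputError(f"zero-variance column index {j}")
        Z = (X - means) / sds
        C = np.corrcoef(Z, rowvar=False)
    else:
        sds = np.ones(X.shape[1])
        C = np.cov(X, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return means, sds, evecs[:, order], evals[order]


def _apply_sign_convention(evecs: np.ndarray) -> np.ndarray:
    """Orient component columns deterministically (see module docstring)."""
    V = evecs.copy()
    # PC1: all-positive loadings; flip so the column sum is positive.
    if V[:, 0].sum() < 0:
        V[:, 0] = -V[:, 0]
    # PC2: information CCs load positively.
    info_idx = [CC_NAMES.index(c) for c in ("writing", "texts", "money")]
    if V[info_idx, 1].sum() < 0:
        V[:, 1] = -V[:, 1]
    # Remaining components: largest-magnitude loading positive.
    for j in range(2, V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def fit_pca(table: CCTable) -> PCAModel:
    """Fit the correlation-matrix PCA of the nine CCs.

    Requires at least 10 records and nonzero variance in every CC.
    """
    X = table.cc_matrix()
    if X.shape[0] < 10:
        raise DegenerateInputError(f"need >= 10 records, got {X.shape[0]}")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        name = CC_NAMES[int(np.nonzero(sds == 0)[0][0])]
        raise DegenerateInputError(f"CC '{name}' has zero variance")
    means, sds, evecs, evals = principal_axes(X, standardize=True)
    evecs = _apply_sign_convention(evecs)
    return PCAModel(cc_means=means, cc_sds=sds,
                    eigenvectors=evecs, eigenvalues=evals)


def project(model: PCAModel, table: CCTable) -> pd.DataFrame:
    """Project records onto all nine components.

    Returns a score table: the record metadata (NGA, PolID, Time, World)
    plus columns ``PC1`` ... ``PC9``.  Scores are ``V.T @ z`` where ``z`` is
    the z-scored CC vector, so score variances equal the eigenvalues on the
    fitting data.
    """
    X = table.cc_matrix()
    if X.shape[1] != model.cc_means.size:
        raise ValueError("schema mismatch between model and table")
    Z = (X - model.cc_means) / model.cc_sds
    S = Z @ model.eigenvectors
    out = table.df.loc[:, ["NGA", "PolID", "Time", "World"]].copy()
    for j in range(S.shape[1]):
        out[f"PC{j + 1}"] = S[:, j]
    return out


def loadings_report(model: PCAModel) -> pd.DataFrame:
    """Loadings of each CC on PC1/PC2 plus percent variance, 2-dp rounded.

    Mirrors the standard published layout: one row per component, one column
    per CC, and a final ``%Var`` column.  Raw (unrounded) values live on the
    model itself.
    """
    L = model.loadings
    rows = {}
    for j, pc in enumerate(("PC1", "PC2")):
        rows[pc] = {name: round(float(L[i, j]), 2) for i, name in enumerate(CC_NAMES)}
        rows[pc]["%Var"] = round(float(model.var_fraction[j]), 1)
    return pd.DataFrame.from_dict(rows, orient="index")
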