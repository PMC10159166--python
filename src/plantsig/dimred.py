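"""PCA on the normalized feature table and scree-threshold selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class PCAModel:
    """Fitted principal-component basis of a feature table.

    ``loadings`` columns are orthonormal eigenvectors of the sample
    covariance of the (min-max-scaled) features, ordered by decreasing
    explained variance; the sign convention makes the largest-magnitude
    element of each loading positive.
    """

    center: np.ndarray
    loadings: np.ndarray          # (p, p), columns are components
    explained_variance_ratio: np.ndarray
    feature_names: tuple[str, ...]

    def cumulative_ratio(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in FEATURE_NAMES if c in table.columns]
    if not cols:  # plain numeric matrix (e.g. reduced scores refit)
        cols = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)
                and c != "block_id"]
    return table[cols].to_numpy(float), cols


def fit_pca(table: pd.DataFrame | np.ndarray) -> PCAModel:
    """Full-rank PCA of the feature columns.

    Requires more rows than features and finite values throughout.
    Rank-deficient covariances are allowed (trailing ratios are 0).
    """
    if isinstance(table, pd.DataFrame):
        x, cols = _feature_matrix(table)
    else:
        x = np.asarray(table, float)
        cols = [f"x{i}" for i in range(x.shape[1])]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in feature matrix")
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than features ({p})")
    pca = PCA(n_components=p, svd_solver="full").fit(x)
    loadings = pca.components_.T.copy()
    # sign convention: largest-|.| element of each component positive
    for j in range(p):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    return PCAModel(
        center=pca.mean_,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=tuple(cols),
    )


def select_components(model: PCAModel, threshold: float = 0.90) -> int:
    """Smallest k whose cumulative explained-variance ratio >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = model.cumulative_ratio()
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def transform(model: PCAModel, table: pd.DataFrame | np.ndarray,
              k: int) -> pd.DataFrame | np.ndarray:
    """Project onto the first k components; labels carried through.

    For a DataFrame input, the result keeps block_id/stimulus/species
    columns and replaces the feature columns with scores pc1..pck.
    """
    p = model.loadings.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in 1..{p}")
    if isinstance(table, pd.DataFrame):
        x, _ = _feature_matrix(table)
    else:
        x = np.asarray(table, float)
    if x.shape[1] != p:
        raise ValueError("feature dimension mismatch with fitted model")
    scores = (x - model.center) @ model.loadings[:, :k]
    if not isinstance(table, pd.DataFrame):
        return scores
    keep = [c for c in ("block_id", "stimulus", "species") if c in table.columns]
    out = table[keep].copy()
    for j in range(k):
        out[f"pc{j + 1}"] = scores[:, j]
    return out
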