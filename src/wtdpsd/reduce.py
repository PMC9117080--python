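"""PCA reduction of the 49-feature table to its leading components.

The descriptor stage mixes log-scale and ratio-scale values, so features
are z-scored by default before the eigendecomposition.  Seven components
are retained by default; the scree (eigenvalue spectrum) and cumulative
explained-variance curve are exposed for reporting.  Component signs are
fixed by making the largest-magnitude loading of each component positive,
so fits are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, ShapeError
from .tdpsd import FeatureVector


@dataclass
class PCAModel:
    """A fitted, sign-fixed principal-component model.

    ``eigenvalues`` are the sample variances (ddof=1) along the retained
    components, descending; ``full_eigenvalues`` keeps the whole spectrum
    for scree plots.  ``scale_vector`` is None when ``standardized`` is
    False.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), descending
    n_components: int
    standardized: bool
    scale_vector: Optional[np.ndarray] = None
    full_eigenvalues: Optional[np.ndarray] = None
    flags: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        total = float(np.sum(self.full_eigenvalues))
        return np.asarray(self.full_eigenvalues) / total

    def save(self, prefix: Union[str, Path]) -> None:
        """Persist as a documented JSON + compressed-array pair."""
        prefix = Path(prefix)
        meta = {
            "n_components": self.n_components,
            "standardized": self.standardized,
            "flags": self.flags,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        arrays = {
            "mean_vector": self.mean_vector,
            "loadings": self.loadings,
            "eigenvalues": self.eigenvalues,
            "full_eigenvalues": self.full_eigenvalues,
        }
        if self.scale_vector is not None:
            arrays["scale_vector"] = self.scale_vector
        np.savez_compressed(prefix.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, prefix: Union[str, Path]) -> "PCAModel":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        arrays = np.load(prefix.with_suffix(".npz"))
        return cls(
            mean_vector=arrays["mean_vector"],
            loadings=arrays["loadings"],
            eigenvalues=arrays["eigenvalues"],
            n_components=meta["n_components"],
            standardized=meta["standardized"],
            scale_vector=arrays["scale_vector"] if "scale_vector" in arrays else None,
            full_eigenvalues=arrays["full_eigenvalues"],
            flags=meta["flags"],
        )


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureVector):
        return features.values[None, :]
    arr = np.asarray(features, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def fit_pca(
    feature_matrix, n_components: int = 7, standardize: bool = True
) -> PCAModel:
    """Fit a PCA model on the training feature matrix.

    Constant columns under ``standardize`` get a unit-variance substitute
    (flagged).  ``n_components`` may not exceed the rank of the centered
    (scaled) matrix.
    """
    X = _as_matrix(feature_matrix)
    if X.shape[0] < 2:
        raise ConfigurationError(f"need >= 2 samples to fit PCA, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")

    flags: list[str] = []
    mean = X.mean(axis=0)
    scale = None
    if standardize:
        scale = X.std(axis=0, ddof=0)
        const = scale == 0
        if np.any(const):
            scale = scale.copy()
            scale[const] = 1.0
            flags.append(f"constant_columns:{np.flatnonzero(const).tolist()}")
        Xw = (X - mean) / scale
    else:
        Xw = X - mean

    rank = np.linalg.matrix_rank(Xw)
    if n_components > rank:
        raise ConfigurationError(
            f"n_components={n_components} exceeds data rank {rank}"
        )

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Xw)  # already centered; PCA's internal recentering is a no-op
    full_eigenvalues = pca.explained_variance_

    loadings = pca.components_[:n_components].T.copy()  # (p, k)
    # sign convention: largest-magnitude loading of each component positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]

    return PCAModel(
        mean_vector=mean,
        loadings=loadings,
        eigenvalues=full_eigenvalues[:n_components].copy(),
        n_components=n_components,
        standardized=standardize,
        scale_vector=scale,
        full_eigenvalues=full_eigenvalues,
        flags=flags,
    )


def transform(features, model: PCAModel) -> np.ndarray:
    """Project feature rows onto the retained components (n x k)."""
    X = _as_matrix(features)
    if X.shape[1] != model.n_features:
        raise ShapeError(
            f"feature width {X.shape[1]} != model width {model.n_features}"
        )
    Xw = X - model.mean_vector
    if model.standardized:
        Xw = Xw / model.scale_vector
    return Xw @ model.loadings


def inverse_transform(reduced: np.ndarray, model: PCAModel) -> np.ndarray:
    """Map component scores back to (approximate) feature space."""
    Z = np.asarray(reduced, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != model.loadings.shape[1]:
        raise ShapeError(
            f"score width {Z.shape[1]} != n_components {model.loadings.shape[1]}"
        )
    Xw = Z @ model.loadings.T
    if model.standardized:
        Xw = Xw * model.scale_vector
    return Xw + model.mean_vector


def scree_table(model: PCAModel) -> pd.DataFrame:
    """Eigenvalue spectrum and cumulative explained-variance for plotting."""
    ratio = model.explained_variance_ratio()
    return pd.DataFrame(
        {
            "component": np.arange(1, len(ratio) + 1),
            "eigenvalue": model.full_eigenvalues,
            "explained_variance_ratio": ratio,
            "cumulative_ratio": np.cumsum(ratio),
        }
    )
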