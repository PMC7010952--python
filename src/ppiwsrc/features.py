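"""Per-protein feature assembly and PCA reconstruction.

A protein sequence maps to a 440-dimensional raw feature (40-d unit-circle
F-vector followed by the 400-d CT descriptor).  A :class:`PcaModel` learned
on a training set projects raw features to ``k`` dimensions (default 30);
two projected proteins concatenate into a 2k-dimensional pair vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .ct import ct_vector
from .fvector import f_vector

__all__ = [
    "RAW_DIM",
    "PcaModel",
    "raw_feature",
    "raw_feature_matrix",
    "fit_pca",
    "project",
    "pair_vector",
]

RAW_DIM = 440


def raw_feature(seq: str, L: int = 4) -> np.ndarray:
    """Concatenated per-protein descriptor: F-vector (40) then CT (20*L*5)."""
    return np.concatenate([f_vector(seq), ct_vector(seq, L=L)])


def raw_feature_matrix(seqs, L: int = 4) -> np.ndarray:
    """Stack :func:`raw_feature` of each sequence into an (m, 440) matrix."""
    return np.array([raw_feature(s, L=L) for s in seqs])


@dataclass
class PcaModel:
    """Fitted PCA projection with a deterministic sign convention.

    ``components`` rows are orthonormal principal axes sorted by decreasing
    explained variance; the largest-magnitude coefficient of each axis is
    made positive so repeated fits are bit-identical.  When ``scale`` is set
    features were divided by their per-feature standard deviation before
    centering and the same scaling is applied at projection time.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_ratio: np.ndarray
    k: int
    scale: np.ndarray | None = field(default=None)

    def save(self, path) -> None:
        payload = {
            "k": self.k,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_ratio": self.explained_ratio.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "PcaModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_ratio=np.asarray(d["explained_ratio"], dtype=float),
            k=int(d["k"]),
            scale=None if d["scale"] is None else np.asarray(d["scale"], dtype=float),
        )


def fit_pca(features: np.ndarray, k: int, scale: bool = False) -> PcaModel:
    """Fit a k-component PCA on an (m, d) raw-feature matrix.

    Requires ``m >= 2`` and ``1 <= k <= min(d, m - 1)`` (centering removes
    one degree of freedom).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    m, d = X.shape
    if not 1 <= k <= min(d, m - 1):
        raise ValueError(f"k={k} out of range [1, {min(d, m - 1)}]")
    sigma = None
    if scale:
        sigma = X.std(axis=0)
        sigma[sigma == 0] = 1.0
        X = X / sigma
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PcaModel(
        mean=pca.mean_,
        components=components,
        explained_ratio=pca.explained_variance_ratio_.copy(),
        k=k,
        scale=sigma,
    )


def project(model: PcaModel, feat: np.ndarray) -> np.ndarray:
    """Project one raw feature (d,) or a matrix (m, d) onto the model axes."""
    X = np.asarray(feat, dtype=float)
    if X.shape[-1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[-1]} != model dimension {model.mean.shape[0]}"
        )
    if model.scale is not None:
        X = X / model.scale
    return (X - model.mean) @ model.components.T


def pair_vector(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Concatenate the projected features of two partner proteins, A then B."""
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError("partner feature vectors must be 1-D and equal length")
    return np.concatenate([va, vb])
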