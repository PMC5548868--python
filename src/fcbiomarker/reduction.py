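"""Principal-component reduction of cohort FC matrices.

The FC feature space (R(R-1)/2 edges, often near 10,000) is far larger than
any cohort, so the pipeline projects FC vectors onto all principal
components of the training cohort — reducing dimensionality to at most
n_train − 1 while keeping every direction of variance and decorrelating the
features.  Edges already share the correlation scale, so the PCA centers
but does not rescale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

__all__ = ["PcaModel", "fit_pca", "transform"]


@dataclass
class PcaModel:
    """Centered PCA: mean vector plus orthonormal component rows.

    ``components`` is (n_components × n_edges) with rows ordered by
    decreasing explained variance; scores are z = V (x − mean).
    """

    mean_: np.ndarray
    components_: np.ndarray
    explained_variance_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]

    @property
    def n_edges(self) -> int:
        return self.components_.shape[1]

    def content_hash(self) -> str:
        """SHA-256 of the model arrays; used to verify frozen artifacts."""
        h = hashlib.sha256()
        for arr in (self.mean_, self.components_, self.explained_variance_):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {
            "schema": "pca-model/1",
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance": self.explained_variance_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        if d.get("schema") != "pca-model/1":
            raise ValueError(f"unsupported PCA model schema: {d.get('schema')!r}")
        return cls(
            mean_=np.asarray(d["mean"], dtype=float),
            components_=np.asarray(d["components"], dtype=float),
            explained_variance_=np.asarray(d["explained_variance"], dtype=float),
        )


def fit_pca(X: np.ndarray) -> PcaModel:
    """Fit centered PCA by SVD, keeping all min(n−1, p) components.

    The sign of each component is fixed deterministically: the loading of
    largest magnitude (first such index on ties) is made positive, so that
    downstream sparse selections are reproducible across platforms.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (participants × edges)")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"PCA needs at least 3 participants, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n - 1, p)
    s, vt = s[:k], vt[:k]
    # deterministic sign convention
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    explained = s**2 / (n - 1)
    return PcaModel(mean_=mean, components_=vt, explained_variance_=explained)


def transform(model: PcaModel, fc: np.ndarray) -> np.ndarray:
    """Project FC vector(s) onto the model's components: z = V (x − mean).

    Accepts a single vector of length n_edges or an (n × n_edges) matrix;
    external participants use the training transform unchanged.
    """
    fc = np.asarray(fc, dtype=float)
    single = fc.ndim == 1
    if single:
        fc = fc[None, :]
    if fc.shape[1] != model.n_edges:
        raise ValueError(
            f"FC vector length {fc.shape[1]} != model edge count {model.n_edges}"
        )
    z = (fc - model.mean_) @ model.components_.T
    return z[0] if single else z
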