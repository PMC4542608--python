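"""Principal component analysis of spectral datasets.

Centered, unscaled PCA via singular value decomposition, fit pooled
(over all sites) for the RadViz embedding and per analysis class for
spectral-marker inspection. The autofluorescence background is left in
the data, so the first components are typically baseline-dominated and
the sharp Raman markers surface in later loadings.

Loading signs are fixed by the largest-magnitude-element-positive
convention so fits are reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import SpectralDataset


class SpectralPCA(BaseEstimator, TransformerMixin):
    """Centered PCA with deterministic loading signs.

    Attributes (after ``fit``)
    --------------------------
    mean_spectrum_ : (n_channels,) mean of the training spectra
    loadings_ : (n_components, n_channels) orthonormal loading vectors
    scores_ : (n_spectra, n_components) projections of the training data
    explained_variance_fraction_ : (n_components,) nonincreasing, sums <= 1
    """

    def __init__(self, n_components: int = 7):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_spectra, n_channels)")
        n, p = X.shape
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > min(n - 1, p):
            raise ValueError(
                f"n_components={k} exceeds min(n_spectra-1, n_channels)="
                f"{min(n - 1, p)}"
            )
        self.n_features_in_ = p
        self.mean_spectrum_ = X.mean(axis=0)
        Xc = X - self.mean_spectrum_
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        loadings = vt[:k]
        # sign convention: largest-|element| of each loading positive
        flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
        flip[flip == 0] = 1.0
        self.loadings_ = loadings * flip[:, None]
        total_var = float(np.sum(s**2))
        self.explained_variance_fraction_ = (
            s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
        )
        self.scores_ = Xc @ self.loadings_.T
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError("channel count does not match the fitted model")
        return (X - self.mean_spectrum_) @ self.loadings_.T

    def inverse_transform(self, scores):
        return np.asarray(scores) @ self.loadings_ + self.mean_spectrum_


def pca_fit(dataset: SpectralDataset, n_components: int = 7) -> SpectralPCA:
    """Fit a pooled PCA on every spectrum of a dataset."""
    return SpectralPCA(n_components).fit(dataset.intensities)


def per_class_pca(
    dataset: SpectralDataset,
    labels,
    n_components: int = 7,
) -> dict[str, SpectralPCA]:
    """One PCA per assigned class; every class needs > n_components spectra.

    ``labels`` is the per-spectrum class vector (dataset row order), e.g.
    from :func:`otoraman.screen.assigned_labels`.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dataset.n_spectra:
        raise ValueError("labels must align with dataset rows")
    models: dict[str, SpectralPCA] = {}
    for cls in np.unique(labels):
        mask = labels == cls
        if mask.sum() <= n_components:
            raise ValueError(
                f"class {cls!r} has only {int(mask.sum())} spectra; "
                f"> {n_components} required"
            )
        models[str(cls)] = SpectralPCA(n_components).fit(dataset.intensities[mask])
    return models


def loading_band_maxima(
    model: SpectralPCA, wavenumbers: np.ndarray, center: float, halfwidth: float = 4.0
) -> bool:
    """Whether any fitted loading has an |loading| local maximum at
    ``center`` +/- ``halfwidth`` cm^-1 — the marker-band recovery check."""
    x = np.asarray(wavenumbers, dtype=float)
    for v in np.abs(model.loadings_):
        interior = np.arange(1, v.size - 1)
        is_max = (v[interior] >= v[interior - 1]) & (v[interior] >= v[interior + 1])
        centers = x[interior[is_max]]
        if np.any(np.abs(centers - center) <= halfwidth):
            return True
    return False
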