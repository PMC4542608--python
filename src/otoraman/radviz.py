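"""Radial-coordinates (RadViz) embedding of PC scores.

Each selected principal component is a dimension anchor placed at an
equally spaced position on the unit circle. Scores are min-max
standardized to [0, 1] per dimension, and each site maps to the
standardized-score-weighted mean of the anchor positions:

    p_i = sum_j u_ij a_j / sum_j u_ij,   a_j = (cos t_j, sin t_j),
    t_j = 2 pi j / K + rotation.

All points therefore lie in the convex hull of the anchors (inside the
unit disk); a site with equal standardized scores on every anchor maps to
the origin, as does the degenerate all-zero row (0/0 by convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .decomposition import SpectralPCA


@dataclass
class RadVizEmbedding:
    anchor_labels: list[str]
    anchor_angles: np.ndarray  # radians
    points: np.ndarray  # (n_sites, 2)
    normalized_scores: np.ndarray  # (n_sites, K) in [0, 1]


class RadVizEmbedder(BaseEstimator, TransformerMixin):
    """sklearn-style transformer from K-dim scores to the unit disk.

    ``fit`` learns per-dimension min/max for the [0, 1] standardization;
    ``transform`` applies the weighted-anchor-mean formula. Dimensions
    with zero range map to constant 0 with a warning.
    """

    def __init__(self, rotation: float = np.pi / 2.0):
        self.rotation = rotation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("RadViz needs at least 2 dimensions")
        self.n_features_in_ = X.shape[1]
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        degenerate = self.max_ <= self.min_
        if np.any(degenerate):
            warnings.warn(
                f"{int(degenerate.sum())} dimension(s) have zero range and map "
                "to constant 0",
                stacklevel=2,
            )
        k = X.shape[1]
        self.anchor_angles_ = 2.0 * np.pi * np.arange(k) / k + self.rotation
        self.anchors_ = np.column_stack(
            [np.cos(self.anchor_angles_), np.sin(self.anchor_angles_)]
        )
        return self

    def standardize(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rng = self.max_ - self.min_
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(rng > 0, (X - self.min_) / np.where(rng > 0, rng, 1.0), 0.0)
        return np.clip(u, 0.0, 1.0)

    def transform(self, X):
        u = self.standardize(X)
        total = u.sum(axis=1, keepdims=True)
        num = u @ self.anchors_
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, num / np.where(total > 0, total, 1.0), 0.0)
        return p


def radviz_embed(scores, anchor_labels=None, rotation: float = np.pi / 2.0) -> RadVizEmbedding:
    """Embed per-site score vectors onto the unit disk."""
    scores = np.asarray(scores, dtype=float)
    emb = RadVizEmbedder(rotation).fit(scores)
    if anchor_labels is None:
        anchor_labels = [f"PC{j + 1}" for j in range(scores.shape[1])]
    if len(anchor_labels) != scores.shape[1]:
        raise ValueError("one anchor label per score dimension required")
    return RadVizEmbedding(
        anchor_labels=list(map(str, anchor_labels)),
        anchor_angles=emb.anchor_angles_,
        points=emb.transform(scores),
        normalized_scores=emb.standardize(scores),
    )


def class_separation_ratio(scores, labels) -> np.ndarray:
    """Per-dimension between-class / within-class variance ratio.

    A one-way variance decomposition of each score dimension: the
    spectrum-count-weighted variance of class means over the pooled
    within-class variance. Dimensions on which the classes separate score
    high; degenerate zero-within dimensions score inf when the means
    differ, 0 otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("at least two classes required")
    grand = scores.mean(axis=0)
    between = np.zeros(scores.shape[1])
    within = np.zeros(scores.shape[1])
    for cls in classes:
        sub = scores[labels == cls]
        between += sub.shape[0] * (sub.mean(axis=0) - grand) ** 2
        within += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(within > 0, between / np.where(within > 0, within, 1.0),
                         np.where(between > 0, np.inf, 0.0))
    return ratio


def select_anchor_pcs(model: SpectralPCA, labels, k_select: int = 7) -> list[int]:
    """Indices (0-based, ascending) of the PCs whose pooled scores best
    separate the classes by the variance-ratio statistic; ties broken by
    ascending PC index."""
    ratio = class_separation_ratio(model.scores_, labels)
    k = ratio.size
    if k_select > k:
        raise ValueError(f"k_select={k_select} exceeds the {k} fitted components")
    order = sorted(range(k), key=lambda j: (-ratio[j], j))[:k_select]
    return sorted(order)
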