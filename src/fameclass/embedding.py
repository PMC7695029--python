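"""Linear (PCA) and non-linear (t-SNE) 2-D views of profile data.

PCA on standardized features by default (correlation-based): although all
17 features share the % unit, their magnitudes span two orders, and an
unstandardized PCA is dominated by the three or four most abundant acids;
``standardize=False`` gives the covariance-based alternative.  t-SNE
likewise standardizes its inputs by default.  t-SNE serves two roles: visualization,
and a transductive feature-mapping stage whose 2-D coordinates feed the
classifiers.  "Transductive" means the embedding is fitted on all instances
jointly, train and test together, before any splitting — this matches the
pipeline being reproduced but leaks test-set geometry into the features; an
inductive variant (fit on train, embed test points at their nearest train
neighbor's coordinates) is available for honest comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .data_model import LabeledDataset


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D (or k-D) scores with method provenance."""

    coordinates: np.ndarray                  # (n, k), input order preserved
    explained_variance: tuple[float, ...] | None  # PCA only, fractions
    method: str
    features: tuple[str, ...]
    params: dict

    def __post_init__(self):
        if self.explained_variance is not None:
            ev = np.asarray(self.explained_variance)
            if (ev < -1e-12).any() or (ev > 1 + 1e-12).any():
                raise ValueError("explained variance fractions must lie in [0,1]")
            if np.any(np.diff(ev) > 1e-12):
                raise ValueError("explained variance must be non-increasing")


def _canonicalize_signs(scores: np.ndarray, components: np.ndarray):
    """Flip each component so its largest-magnitude loading is positive."""
    for j in range(components.shape[0]):
        i = np.argmax(np.abs(components[j]))
        if components[j, i] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return scores, components


def pca_project(dataset: LabeledDataset,
                features: Sequence[str] | None = None,
                n_components: int = 2,
                standardize: bool = True) -> EmbeddingResult:
    """Principal-component scores of the (by default standardized) profiles.

    Deterministic up to component sign, which is canonicalized
    (largest-magnitude loading positive).
    """
    feats = tuple(features) if features is not None else dataset.feature_names
    X = dataset.X(feats)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 instances")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature count")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    scores, _ = _canonicalize_signs(scores, pca.components_)
    return EmbeddingResult(
        scores, tuple(float(v) for v in pca.explained_variance_ratio_),
        method="pca", features=feats,
        params={"n_components": n_components, "standardize": standardize})


@dataclass(frozen=True)
class TsneConfig:
    """t-SNE hyperparameters (held fixed for reproducibility)."""

    perplexity: float = 30.0
    n_iter: int = 1000
    seed: int = 0
    init: str = "pca"
    standardize: bool = True


def _effective_perplexity(n: int, perplexity: float) -> float:
    # t-SNE needs roughly 3*perplexity neighbors per point
    limit = max((n - 1) / 3.0, 2.0)
    if perplexity > limit:
        warnings.warn(f"perplexity {perplexity} too large for n={n}; "
                      f"shrinking to {limit:.1f}")
        return limit
    return perplexity


def tsne_map(dataset: LabeledDataset,
             features: Sequence[str] | None = None,
             config: TsneConfig | None = None) -> EmbeddingResult:
    """Joint 2-D t-SNE embedding of all instances, reproducible from seed."""
    feats = tuple(features) if features is not None else dataset.feature_names
    config = config or TsneConfig()
    X = dataset.X(feats)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all profiles identical")
    if config.standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    perp = _effective_perplexity(X.shape[0], config.perplexity)
    tsne = TSNE(n_components=2, perplexity=perp, max_iter=config.n_iter,
                init=config.init, random_state=config.seed,
                method="barnes_hut")
    coords = np.asarray(tsne.fit_transform(X), dtype=float)
    return EmbeddingResult(coords, None, method="tsne", features=feats,
                           params={"perplexity": perp, "n_iter": config.n_iter,
                                   "seed": config.seed, "init": config.init})


def tsne_feature_stage(dataset: LabeledDataset,
                       features: Sequence[str],
                       config: TsneConfig | None = None,
                       ) -> LabeledDataset:
    """Replace the feature block with the 2-D t-SNE coordinates.

    Returns a derived dataset whose two features are the embedding
    coordinates; labels, sample blocks and instance count are untouched.
    Downstream train/test splitting happens *after* this mapping
    (transductive pipeline — see module docstring for the caveat).
    """
    emb = tsne_map(dataset, features=features, config=config)
    return dataset.with_features(emb.coordinates, ("tsne1", "tsne2"))


def inductive_tsne_features(train: LabeledDataset, test: LabeledDataset,
                            features: Sequence[str],
                            config: TsneConfig | None = None,
                            ) -> tuple[LabeledDataset, LabeledDataset]:
    """Leakage-free alternative to the transductive stage.

    Fits t-SNE on the training instances only; each test instance inherits
    the embedded coordinates of its nearest training neighbor in the input
    feature space.  Cruder than the joint embedding, but the test set never
    shapes the map — use this to measure how much the transductive default
    flatters the classifiers.
    """
    emb = tsne_map(train, features=features, config=config)
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=1).fit(train.X(features))
    _, idx = nn.kneighbors(test.X(features))
    test_coords = emb.coordinates[idx[:, 0]]
    return (train.with_features(emb.coordinates, ("tsne1", "tsne2")),
            test.with_features(test_coords, ("tsne1", "tsne2")))


def plot_embedding(result: EmbeddingResult, labels: np.ndarray, ax=None,
                   title: str | None = None):
    """Scatter an embedding colored by class code (0-3)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for code in np.unique(labels):
        m = labels == code
        ax.scatter(result.coordinates[m, 0], result.coordinates[m, 1],
                   s=12, label=str(int(code)), alpha=0.8)
    ax.legend(title="class")
    if result.method == "pca" and result.explained_variance:
        ev = result.explained_variance
        ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    else:
        ax.set_xlabel("dim 1")
        ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    return ax
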