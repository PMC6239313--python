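"""Group survey images into clusters of similar seabed background.

One background model is trained per cluster, so the clustering only has to
capture *global* image appearance.  Each image is mapped to a feature vector
combining principal-component projection coordinates of a small grayscale
thumbnail with the Shannon entropy of its intensity histogram; k-means then
partitions the images.  The concrete feature recipe (thumbnail size, number
of components, entropy bins) is a package choice and is exposed as
parameters so alternatives can be swapped in.
"""

from __future__ import annotations

import json
import os
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .image_store import ImageDataset

__all__ = ["image_feature_vector", "thumbnail_features", "histogram_entropy",
           "BackgroundClusterer", "cluster_dataset"]


def histogram_entropy(gray: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram of a [0,1] image."""
    hist, _ = np.histogram(gray, bins=bins, range=(0.0, 1.0))
    p = hist[hist > 0] / gray.size
    return float(-(p * np.log2(p)).sum())


def thumbnail_features(pixels: np.ndarray, thumb: int = 32) -> np.ndarray:
    """Grayscale ``thumb``x``thumb`` thumbnail of an RGB [0,1] image, flattened."""
    gray = pixels.mean(axis=2)
    small = resize(gray, (thumb, thumb), anti_aliasing=True, preserve_range=True)
    return small.reshape(-1).astype(np.float64)


def image_feature_vector(pixels: np.ndarray, thumb: int = 32,
                         entropy_bins: int = 256) -> np.ndarray:
    """Raw (pre-PCA) feature vector: thumbnail pixels plus histogram entropy."""
    t = thumbnail_features(pixels, thumb)
    e = histogram_entropy(pixels.mean(axis=2), bins=entropy_bins)
    return np.concatenate([t, [e]])


class BackgroundClusterer(BaseEstimator, ClusterMixin):
    """K-means clustering of images by global background appearance.

    Parameters
    ----------
    n_clusters : int
        Number of image clusters K (one background model each).
    n_components : int
        PCA components kept from the thumbnail block (capped by data size).
    thumb : int
        Thumbnail edge length in pixels.
    entropy_bins : int
        Histogram bins for the entropy feature.
    n_init : int
        k-means restarts.
    random_state : int
        Seed for PCA/k-means.

    The estimator is fit on a list of RGB pixel arrays (or an
    :class:`ImageDataset`); ``labels_`` holds the cluster assignment.
    PCA is fit on the dataset's thumbnails; the projection coordinates and
    the entropy are z-scored before k-means.
    """

    def __init__(self, n_clusters: int = 5, n_components: int = 8,
                 thumb: int = 32, entropy_bins: int = 256, n_init: int = 10,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.thumb = thumb
        self.entropy_bins = entropy_bins
        self.n_init = n_init
        self.random_state = random_state

    # -- internals ----------------------------------------------------

    def _raw_features(self, images: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        thumbs = np.stack([thumbnail_features(im, self.thumb) for im in images])
        ent = np.array([histogram_entropy(im.mean(axis=2), self.entropy_bins)
                        for im in images])
        return thumbs, ent

    def _project(self, thumbs: np.ndarray, ent: np.ndarray) -> np.ndarray:
        coords = self.pca_.transform(thumbs)
        feats = np.column_stack([coords, ent])
        return (feats - self.feature_mean_) / self.feature_scale_

    # -- sklearn API --------------------------------------------------

    def fit(self, X: Sequence[np.ndarray] | ImageDataset, y=None) -> "BackgroundClusterer":
        images = [X.pixels(r.id) for r in X] if isinstance(X, ImageDataset) else list(X)
        n = len(images)
        if n == 0:
            raise ValueError("cannot cluster an empty image set")
        if self.n_clusters > n:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds number of images {n}")
        thumbs, ent = self._raw_features(images)
        d = min(self.n_components, n, thumbs.shape[1])
        self.pca_ = PCA(n_components=d, random_state=self.random_state).fit(thumbs)
        coords = self.pca_.transform(thumbs)
        feats = np.column_stack([coords, ent])
        self.feature_mean_ = feats.mean(axis=0)
        # one shared scale for the PCA block (keeps the variance ordering of
        # the components, so the separating direction is not drowned by
        # noise components), plus an individual scale for the entropy
        pca_scale = coords.std() or 1.0
        ent_scale = ent.std() or 1.0
        self.feature_scale_ = np.array([pca_scale] * d + [ent_scale])
        z = (feats - self.feature_mean_) / self.feature_scale_
        self.kmeans_ = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                              random_state=self.random_state).fit(z)
        self.labels_ = self.kmeans_.labels_.astype(int)
        self.cluster_centers_ = self.kmeans_.cluster_centers_
        return self

    def predict(self, X: Sequence[np.ndarray] | ImageDataset) -> np.ndarray:
        check_is_fitted(self, "kmeans_")
        images = [X.pixels(r.id) for r in X] if isinstance(X, ImageDataset) else list(X)
        thumbs, ent = self._raw_features(images)
        return self.kmeans_.predict(self._project(thumbs, ent)).astype(int)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    # -- persistence --------------------------------------------------

    def to_json(self, path: str | os.PathLike) -> None:
        check_is_fitted(self, "kmeans_")
        payload = {
            "params": self.get_params(),
            "pca_mean": self.pca_.mean_.tolist(),
            "pca_components": self.pca_.components_.tolist(),
            "pca_explained_variance": self.pca_.explained_variance_.tolist(),
            "feature_mean": self.feature_mean_.tolist(),
            "feature_scale": self.feature_scale_.tolist(),
            "cluster_centers": self.cluster_centers_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "BackgroundClusterer":
        with open(path) as fh:
            payload = json.load(fh)
        est = cls(**payload["params"])
        pca = PCA(n_components=len(payload["pca_components"]))
        pca.mean_ = np.asarray(payload["pca_mean"])
        pca.components_ = np.asarray(payload["pca_components"])
        pca.explained_variance_ = np.asarray(payload["pca_explained_variance"])
        est.pca_ = pca
        est.feature_mean_ = np.asarray(payload["feature_mean"])
        est.feature_scale_ = np.asarray(payload["feature_scale"])
        centers = np.asarray(payload["cluster_centers"])
        km = KMeans(n_clusters=centers.shape[0], n_init=1)
        km.cluster_centers_ = centers
        km._n_threads = 1
        est.kmeans_ = km
        est.cluster_centers_ = centers
        return est


def cluster_dataset(dataset: ImageDataset, n_clusters: int = 5, seed: int = 0,
                    **kwargs) -> BackgroundClusterer:
    """Fit a :class:`BackgroundClusterer` on a dataset and write the
    assignments back into its records."""
    est = BackgroundClusterer(n_clusters=n_clusters, random_state=seed, **kwargs)
    labels = est.fit_predict(dataset)
    for rec, lab in zip(dataset.records, labels):
        rec.cluster_id = int(lab)
    return est
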