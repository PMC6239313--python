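"""Patch autoencoder: the data-driven background model (DBM).

A three-layer fully connected autoencoder maps a flattened RGB patch
``x ∈ R^r`` (``r = 3·r_e²`` for a square patch of edge ``r_e``) through a
latent layer ``l = σ(Wx + b)`` of size ``s = round(s_c · r)`` back to a
reconstruction ``x' = σ(W'l + b')``, with the softplus transfer
``σ(x) = log(1 + e^x)``.  Training minimises the minibatch-mean
reconstruction error ``F(x, x') = Σ (x − x')²`` with Adam at a fixed
learning rate and Xavier-initialised weights.  Trained on patches sampled
from one cluster of similar-background images, the reconstruction error of
a new patch scores how *novel* (un-background-like) it is.

The network is small and dense, so it is implemented directly on NumPy
(float32 GEMMs, hand-derived gradients); training is deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .image_store import ImageDataset, ImageRecord, sample_random_patches

__all__ = ["softplus", "AENConfig", "PatchAutoencoder", "DBM",
           "encode", "decode", "reconstruction_error", "train_dbm",
           "save_dbm", "load_dbm"]


def softplus(x):
    """Numerically stable ``log(1 + e^x)``, elementwise.

    Computed as ``max(x, 0) + log1p(e^{-|x|})``: no overflow for large
    positive ``x`` and positive (≈ ``e^x``) down to the smallest subnormal
    for large negative ``x``.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if x.ndim == 0:
        return float(np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))))
    out = np.exp(-np.abs(x))
    np.log1p(out, out=out)
    out += np.maximum(x, 0.0)
    return out


def reconstruction_error(x: np.ndarray, x_prime: np.ndarray) -> float | np.ndarray:
    """Sum of squared componentwise differences.

    Accepts single vectors (returns a scalar) or ``(n, r)`` batches
    (returns a length-``n`` array).
    """
    x = np.asarray(x)
    x_prime = np.asarray(x_prime)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    d = (x - x_prime).astype(np.float64)
    if d.ndim == 1:
        return float((d * d).sum())
    return (d * d).sum(axis=-1)


@dataclass(frozen=True)
class AENConfig:
    """Hyper-parameters of the background autoencoder.

    ``patch_edge`` must be odd; the latent size is ``round(compression · r)``
    with ``r = 3 · patch_edge²``.
    """

    patch_edge: int = 39
    compression: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 100
    minibatch: int = 128
    n_train_patches: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.patch_edge < 3 or self.patch_edge % 2 == 0:
            raise ValueError(f"patch_edge must be odd and >= 3, got {self.patch_edge}")
        if not 0.0 < self.compression < 1.0:
            raise ValueError(f"compression must lie in (0, 1), got {self.compression}")
        if self.latent_size < 1:
            raise ValueError("latent size rounds to zero; increase compression")

    @property
    def input_size(self) -> int:
        return 3 * self.patch_edge**2

    @property
    def latent_size(self) -> int:
        # round-half-up, as in ordinary arithmetic rounding
        return int(np.floor(self.compression * self.input_size + 0.5))


class PatchAutoencoder(BaseEstimator):
    """Softplus autoencoder over flattened patches, sklearn-style.

    ``fit(X)`` trains on an ``(n, r)`` matrix of patch vectors;
    ``score_samples(X)`` returns the per-patch reconstruction error F
    (high = novel).  Fitted attributes: ``W_``, ``b_``, ``W_out_``,
    ``b_out_``, ``loss_curve_``.
    """

    def __init__(self, latent_size: int = 456, learning_rate: float = 1e-3,
                 epochs: int = 100, minibatch: int = 128, random_state: int = 0):
        self.latent_size = latent_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.minibatch = minibatch
        self.random_state = random_state

    def _init_weights(self, r: int, s: int, rng: np.random.Generator) -> None:
        # Xavier/Glorot uniform on both dense layers, zero biases
        lim1 = np.sqrt(6.0 / (r + s))
        lim2 = np.sqrt(6.0 / (s + r))
        self.W_ = rng.uniform(-lim1, lim1, size=(s, r)).astype(np.float32)
        self.b_ = np.zeros(s, dtype=np.float32)
        self.W_out_ = rng.uniform(-lim2, lim2, size=(r, s)).astype(np.float32)
        self.b_out_ = np.zeros(r, dtype=np.float32)

    def fit(self, X: np.ndarray, y=None) -> "PatchAutoencoder":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_patches, r) matrix")
        n, r = X.shape
        s = int(self.latent_size)
        if not 1 <= s < r:
            raise ValueError(f"latent_size must satisfy 1 <= s < r={r}, got {s}")
        rng = np.random.default_rng(self.random_state)
        self._init_weights(r, s, rng)

        # Adam state
        lr = np.float32(self.learning_rate)
        beta1, beta2, eps = np.float32(0.9), np.float32(0.999), np.float32(1e-8)
        params = [self.W_, self.b_, self.W_out_, self.b_out_]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0

        self.loss_curve_ = []
        bs = int(self.minibatch)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, bs):
                batch = X[order[start : start + bs]]
                B = batch.shape[0]
                z1 = batch @ self.W_.T + self.b_
                l = softplus(z1).astype(np.float32)
                z2 = l @ self.W_out_.T + self.b_out_
                x_prime = softplus(z2).astype(np.float32)
                diff = x_prime - batch
                # loss: minibatch mean of F = sum of squared differences
                loss = float((diff.astype(np.float64) ** 2).sum() / B)
                epoch_loss += loss * B
                d2 = (2.0 * diff * expit(z2)).astype(np.float32)  # (B, r)
                gW2 = d2.T @ l / B
                gb2 = d2.mean(axis=0)
                d1 = ((d2 @ self.W_out_) * expit(z1)).astype(np.float32)  # (B, s)
                gW1 = d1.T @ batch / B
                gb1 = d1.mean(axis=0)
                t += 1
                for p, g, mi, vi in zip(params, [gW1, gb1, gW2, gb2], m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            mean_loss = epoch_loss / n
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            self.loss_curve_.append(mean_loss)
        self.n_features_in_ = r
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        squeeze = X.ndim == 1
        X2 = np.atleast_2d(X)
        if X2.shape[1] != self.W_.shape[1]:
            raise ValueError(
                f"input length {X2.shape[1]} != expected r={self.W_.shape[1]}")
        l = softplus(X2 @ self.W_.T + self.b_).astype(np.float32)
        return l[0] if squeeze else l

    def decode(self, L: np.ndarray) -> np.ndarray:
        L = np.asarray(L, dtype=np.float32)
        squeeze = L.ndim == 1
        L2 = np.atleast_2d(L)
        if L2.shape[1] != self.W_out_.shape[1]:
            raise ValueError(
                f"latent length {L2.shape[1]} != expected s={self.W_out_.shape[1]}")
        x = softplus(L2 @ self.W_out_.T + self.b_out_).astype(np.float32)
        return x[0] if squeeze else x

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Per-patch reconstruction error F (novelty score)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        return np.asarray(reconstruction_error(X, self.reconstruct(X)))


@dataclass
class DBM:
    """A trained data-driven background model for one image cluster."""

    cluster_id: int
    model: PatchAutoencoder
    config: AENConfig

    @property
    def patch_edge(self) -> int:
        return self.config.patch_edge


def encode(x: np.ndarray, dbm: DBM) -> np.ndarray:
    return dbm.model.encode(x)


def decode(l: np.ndarray, dbm: DBM) -> np.ndarray:
    return dbm.model.decode(l)


def train_dbm(cluster: Sequence[ImageRecord], config: AENConfig,
              cluster_id: int = 0, dataset: ImageDataset | None = None,
              pixels_by_id: dict[str, np.ndarray] | None = None) -> DBM:
    """Train one background model on random patches from a cluster's images."""
    records = list(cluster)
    if not records:
        raise ValueError("cluster is empty")
    patches = sample_random_patches(records, config.n_train_patches,
                                    config.patch_edge, seed=config.seed,
                                    dataset=dataset, pixels_by_id=pixels_by_id)
    X = np.stack([p.values for p in patches])
    model = PatchAutoencoder(latent_size=config.latent_size,
                             learning_rate=config.learning_rate,
                             epochs=config.epochs, minibatch=config.minibatch,
                             random_state=config.seed)
    model.fit(X)
    return DBM(cluster_id=cluster_id, model=model, config=config)


def save_dbm(dbm: DBM, path: str | os.PathLike) -> None:
    """Persist a DBM as a single .npz archive with JSON metadata."""
    meta = {"cluster_id": dbm.cluster_id, "config": asdict(dbm.config)}
    np.savez(path, W=dbm.model.W_, b=dbm.model.b_,
             W_out=dbm.model.W_out_, b_out=dbm.model.b_out_,
             meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_dbm(path: str | os.PathLike) -> DBM:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        config = AENConfig(**meta["config"])
        model = PatchAutoencoder(latent_size=config.latent_size,
                                 learning_rate=config.learning_rate,
                                 epochs=config.epochs,
                                 minibatch=config.minibatch,
                                 random_state=config.seed)
        model.W_ = z["W"]
        model.b_ = z["b"]
        model.W_out_ = z["W_out"]
        model.b_out_ = z["b_out"]
        model.n_features_in_ = model.W_.shape[1]
    return DBM(cluster_id=meta["cluster_id"], model=model, config=config)
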