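"""Pipeline configuration: one validated record of every tunable parameter.

Defaults are the published operating point of the method: K=5 background
clusters, 39-px patches, 0.1 latent compression, 10⁴ training patches for
100 epochs at minibatch 128 with Adam at 10⁻³, stride-2 convolutional
application, dilation kernel equal to the patch size, 99th-percentile
thresholding, 30-px minimum proposal boxes, a 600-per-class filter limit,
500×500 training crops, and the benchmark time-model rates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .aen import AENConfig
from .evaluation import TimeModelParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # clustering
    n_clusters: int = 5
    pca_components: int = 8
    thumb: int = 32
    entropy_bins: int = 256
    # background model
    patch_edge: int = 39
    compression: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 100
    minibatch: int = 128
    n_train_patches: int = 10_000
    # novelty map
    stride: int = 2
    slice_rows: int = 16
    dilation_kernel: int | None = None  # None -> patch_edge
    percentile: float = 99.0
    # proposals
    min_box_edge: int = 30
    # review / training samples
    per_class_limit: int = 600
    crop_size: int = 500
    # time model
    review_rate: float = 18.34
    setup_cost: float = 12327.0
    trad_rate: float = 89.27
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.patch_edge % 2 == 0 or self.patch_edge < 3:
            raise ValueError("patch_edge must be odd and >= 3")
        if not 0 < self.compression < 1:
            raise ValueError("compression must lie in (0, 1)")
        k = self.dilation_kernel
        if k is not None and (k < 1 or k % 2 == 0):
            raise ValueError("dilation_kernel must be odd")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")

    @property
    def kernel_edge(self) -> int:
        return self.dilation_kernel if self.dilation_kernel else self.patch_edge

    def aen_config(self, seed: int | None = None) -> AENConfig:
        return AENConfig(patch_edge=self.patch_edge, compression=self.compression,
                         learning_rate=self.learning_rate, epochs=self.epochs,
                         minibatch=self.minibatch,
                         n_train_patches=self.n_train_patches,
                         seed=self.seed if seed is None else seed)

    def time_params(self) -> TimeModelParams:
        return TimeModelParams(review_rate=self.review_rate,
                               setup_cost=self.setup_cost,
                               trad_rate=self.trad_rate)

    # -- I/O ----------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**data)
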