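"""Image loading, dataset manifests and square-patch access.

Images are held as ``float32`` RGB arrays scaled to ``[0, 1]``.  Patches are
square with an odd edge length ``e`` and are addressed by their centre pixel:
a patch centred at ``(cx, cy)`` spans ``[cx - (e-1)//2, cx + (e-1)//2]`` in x
(and likewise in y), fully inside the image.  Coordinates are 0-based,
x to the right, y down.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageRecord",
    "ImageDataset",
    "Patch",
    "load_image",
    "load_pixels",
    "extract_patch",
    "embed_patch",
    "sample_random_patches",
    "iter_patch_grid",
    "grid_shape",
]

MANIFEST_COLUMNS = ["id", "path", "width", "height", "cluster_id"]


@dataclass
class ImageRecord:
    """One image of a survey dataset."""

    id: str
    path: str
    width: int
    height: int
    cluster_id: int | None = None


@dataclass
class Patch:
    """A flattened square RGB patch.

    ``values`` follows pixel-major order ``(p1_r, p1_g, p1_b, p2_r, ...)``,
    i.e. the row-major flattening of the ``(e, e, 3)`` crop, and has length
    ``3 * edge**2``.
    """

    image_id: str
    cx: int
    cy: int
    edge: int
    values: np.ndarray = field(repr=False)


def _check_edge(edge: int) -> None:
    if edge < 1 or edge % 2 == 0:
        raise ValueError(f"patch edge must be odd and >= 1, got {edge}")


def load_pixels(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as a float32 RGB array in [0, 1].

    8- and 16-bit inputs are rescaled by their dtype maximum; grayscale is
    promoted to three identical channels.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0 or arr.ndim < 2:
        raise ValueError(f"zero-sized or non-2D image: {path}")
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float32) / scale
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.shape[2] != 3:
        raise ValueError(f"unsupported channel count {arr.shape[2]}: {path}")
    return np.ascontiguousarray(arr)


def load_image(path: str | os.PathLike, image_id: str | None = None) -> tuple[ImageRecord, np.ndarray]:
    """Load an image file into an :class:`ImageRecord` plus its pixel array."""
    pixels = load_pixels(path)
    h, w = pixels.shape[:2]
    rec = ImageRecord(id=image_id or Path(path).stem, path=str(path), width=w, height=h)
    return rec, pixels


@dataclass
class ImageDataset:
    """A manifest of :class:`ImageRecord` with cached pixel access."""

    records: list[ImageRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids in dataset")
        self._by_id = {r.id: r for r in self.records}
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def get(self, image_id: str) -> ImageRecord:
        return self._by_id[image_id]

    def pixels(self, image_id: str, cache: bool = True) -> np.ndarray:
        if image_id in self._cache:
            return self._cache[image_id]
        arr = load_pixels(self._by_id[image_id].path)
        if cache:
            self._cache[image_id] = arr
        return arr

    def cluster(self, cluster_id: int) -> list[ImageRecord]:
        return [r for r in self.records if r.cluster_id == cluster_id]

    def cluster_ids(self) -> list[int]:
        seen = sorted({r.cluster_id for r in self.records if r.cluster_id is not None})
        return seen

    # -- manifest I/O -------------------------------------------------

    @classmethod
    def from_manifest(cls, path: str | os.PathLike) -> "ImageDataset":
        df = pd.read_csv(path)
        missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            cid = getattr(row, "cluster_id", None)
            cid = None if cid is None or (isinstance(cid, float) and np.isnan(cid)) else int(cid)
            records.append(
                ImageRecord(id=str(row.id), path=str(row.path), width=int(row.width),
                            height=int(row.height), cluster_id=cid)
            )
        return cls(records)

    def to_manifest(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(
            [
                {
                    "id": r.id,
                    "path": r.path,
                    "width": r.width,
                    "height": r.height,
                    "cluster_id": "" if r.cluster_id is None else r.cluster_id,
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )
        df.to_csv(path, index=False)


def extract_patch(pixels: np.ndarray, cx: int, cy: int, edge: int, image_id: str = "") -> Patch:
    """Crop the square patch centred at ``(cx, cy)`` and flatten it."""
    _check_edge(edge)
    half = (edge - 1) // 2
    h, w = pixels.shape[:2]
    if cx - half < 0 or cy - half < 0 or cx + half >= w or cy + half >= h:
        raise ValueError(
            f"patch edge={edge} at ({cx},{cy}) exceeds image bounds {w}x{h}"
        )
    crop = pixels[cy - half : cy + half + 1, cx - half : cx + half + 1, :]
    return Patch(image_id=image_id, cx=cx, cy=cy, edge=edge,
                 values=np.ascontiguousarray(crop, dtype=np.float32).reshape(-1))


def embed_patch(pixels: np.ndarray, patch: Patch) -> None:
    """Write a patch's values back into an image at its centre (in place)."""
    half = (patch.edge - 1) // 2
    crop = patch.values.reshape(patch.edge, patch.edge, 3)
    pixels[patch.cy - half : patch.cy + half + 1,
           patch.cx - half : patch.cx + half + 1, :] = crop


def sample_random_patches(
    images: Sequence[ImageRecord],
    n: int,
    edge: int,
    seed: int,
    dataset: ImageDataset | None = None,
    pixels_by_id: dict[str, np.ndarray] | None = None,
) -> list[Patch]:
    """Sample ``n`` patches uniformly: image chosen uniformly (with
    replacement), centre uniform over valid positions.

    Deterministic for a fixed seed.  Pixel data is looked up through either
    ``dataset`` or an explicit ``pixels_by_id`` mapping.
    """
    _check_edge(edge)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    records = list(images)
    if not records:
        raise ValueError("cannot sample patches from an empty image set")
    too_small = [r.id for r in records if r.width < edge or r.height < edge]
    if too_small:
        raise ValueError(f"images smaller than patch edge {edge}: {too_small}")

    def _pixels(image_id: str) -> np.ndarray:
        if pixels_by_id is not None:
            return pixels_by_id[image_id]
        if dataset is not None:
            return dataset.pixels(image_id)
        raise ValueError("need dataset or pixels_by_id to read pixels")

    rng = np.random.default_rng(seed)
    half = (edge - 1) // 2
    out: list[Patch] = []
    img_idx = rng.integers(0, len(records), size=n)
    for i in img_idx:
        rec = records[int(i)]
        cx = int(rng.integers(half, rec.width - half))
        cy = int(rng.integers(half, rec.height - half))
        out.append(extract_patch(_pixels(rec.id), cx, cy, edge, image_id=rec.id))
    return out


def grid_shape(width: int, height: int, edge: int, stride: int) -> tuple[int, int]:
    """Number of (rows, cols) of valid patch centres for a stride grid."""
    ny = max(0, (height - edge) // stride + 1)
    nx = max(0, (width - edge) // stride + 1)
    return ny, nx


def iter_patch_grid(width: int, height: int, edge: int, stride: int) -> Iterator[tuple[int, int]]:
    """Row-major centres ``(cx, cy)`` of every patch fully inside the image,
    stepping by ``stride`` in x and y starting at offset 0."""
    _check_edge(edge)
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    half = (edge - 1) // 2
    for y0 in range(0, height - edge + 1, stride):
        for x0 in range(0, width - edge + 1, stride):
            yield (x0 + half, y0 + half)
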