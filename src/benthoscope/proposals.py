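"""Thresholding of novelty maps and extraction of ranked training proposals.

Per image cluster, the segmentation threshold is the mean of the 99th
percentiles of the cluster's (dilated) novelty maps.  Pixels strictly above
the threshold form "interesting" 8-connected regions; each region becomes
one square training proposal — the minimum square bounding box, enforced to
an edge of at least 30 px and shifted inward so the crop stays inside the
image — scored by the region's cumulated novelty η.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .novelty import NoveltyMap

__all__ = ["TrainingProposal", "ClusterThreshold", "compute_threshold",
           "percentile99", "segment_novelty_map", "extract_regions",
           "region_to_proposal", "proposals_from_map", "rank_proposals",
           "write_proposals_csv", "read_proposals_csv", "MIN_BOX_EDGE"]

MIN_BOX_EDGE = 30


@dataclass
class TrainingProposal:
    """Square candidate region offered to a human for filtering."""

    image_id: str
    x: int  # top-left corner
    y: int
    edge: int
    score: float  # cumulated region novelty η
    region_id: int

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + (self.edge - 1) / 2.0, self.y + (self.edge - 1) / 2.0)


@dataclass
class ClusterThreshold:
    cluster_id: int
    t_k: float


def percentile99(values: np.ndarray) -> float:
    """99th percentile with linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, dtype=np.float64), 99.0,
                               method="linear"))


def compute_threshold(novelty_maps: Sequence[NoveltyMap],
                      cluster_id: int = 0) -> ClusterThreshold:
    """Mean of the per-map 99th percentiles over one cluster."""
    maps = list(novelty_maps)
    if not maps:
        raise ValueError("cluster has no novelty maps")
    t_k = float(np.mean([percentile99(m.values) for m in maps]))
    return ClusterThreshold(cluster_id=cluster_id, t_k=t_k)


def segment_novelty_map(nm: NoveltyMap, t_k: float) -> np.ndarray:
    """Binary mask of pixels strictly above the cluster threshold."""
    return nm.values > t_k


def extract_regions(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a binary mask.

    Each region is an ``(n, 2)`` integer array of ``(y, x)`` pixel
    coordinates; regions are ordered by row-major discovery of their first
    pixel, which is deterministic.
    """
    lab = cc_label(mask, connectivity=2)
    n = lab.max()
    regions: list[np.ndarray] = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lab == k)
        regions.append(np.column_stack([ys, xs]))
    # skimage labels in raster-scan discovery order already; keep stable
    return regions


def region_to_proposal(region: np.ndarray, nm: NoveltyMap,
                       region_id: int = 0,
                       min_edge: int = MIN_BOX_EDGE) -> TrainingProposal:
    """Minimum square bounding box of a region, at least ``min_edge`` wide.

    The square is centred on the tight bounding box's centre, expanded to
    ``max(min_edge, tight width, tight height)`` and shifted inward where it
    would overflow the image, so every proposal crop is exactly square
    (shrunk only if the image itself is smaller than the edge).
    """
    if len(region) == 0:
        raise ValueError("region is empty")
    ys, xs = region[:, 0], region[:, 1]
    h_img, w_img = nm.values.shape
    x0, x1 = int(xs.min()), int(xs.max())
    y0, y1 = int(ys.min()), int(ys.max())
    tight_w, tight_h = x1 - x0 + 1, y1 - y0 + 1
    edge = max(min_edge, tight_w, tight_h)
    edge = min(edge, w_img, h_img)  # degenerate small images
    cx = (x0 + x1) / 2.0
    cy = (y0 + y1) / 2.0
    bx = int(round(cx - (edge - 1) / 2.0))
    by = int(round(cy - (edge - 1) / 2.0))
    bx = min(max(bx, 0), w_img - edge)
    by = min(max(by, 0), h_img - edge)
    score = float(nm.values[ys, xs].sum())
    return TrainingProposal(image_id=nm.image_id, x=bx, y=by, edge=edge,
                            score=score, region_id=region_id)


def proposals_from_map(nm: NoveltyMap, t_k: float,
                       min_edge: int = MIN_BOX_EDGE) -> list[TrainingProposal]:
    """Segment one dilated novelty map and emit one proposal per region."""
    mask = segment_novelty_map(nm, t_k)
    return [region_to_proposal(reg, nm, region_id=i, min_edge=min_edge)
            for i, reg in enumerate(extract_regions(mask))]


def rank_proposals(proposals: Sequence[TrainingProposal]) -> list[TrainingProposal]:
    """Stable sort by descending novelty score; ties keep input order via
    the (image_id, region_id) key."""
    return sorted(proposals, key=lambda p: (-p.score, p.image_id, p.region_id))


PROPOSAL_COLUMNS = ["image_id", "x", "y", "edge", "score", "region_id"]


def write_proposals_csv(proposals: Sequence[TrainingProposal],
                        path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [{"image_id": p.image_id, "x": p.x, "y": p.y, "edge": p.edge,
          "score": repr(p.score), "region_id": p.region_id} for p in proposals],
        columns=PROPOSAL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_proposals_csv(path: str | os.PathLike) -> list[TrainingProposal]:
    df = pd.read_csv(path)
    return [TrainingProposal(image_id=str(r.image_id), x=int(r.x), y=int(r.y),
                             edge=int(r.edge), score=float(r.score),
                             region_id=int(r.region_id))
            for r in df.itertuples(index=False)]


def write_proposals_coco(proposals: Sequence[TrainingProposal],
                         path: str | os.PathLike) -> None:
    """COCO-style detection JSON: one entry per proposal with an
    ``[x, y, w, h]`` box and the novelty score."""
    import json

    image_ids = {p.image_id for p in proposals}
    id_map = {img: i + 1 for i, img in enumerate(sorted(image_ids))}
    payload = {
        "images": [{"id": i, "file_name": img} for img, i in id_map.items()],
        "annotations": [
            {"id": k + 1, "image_id": id_map[p.image_id], "category_id": 1,
             "bbox": [p.x, p.y, p.edge, p.edge], "score": p.score,
             "area": p.edge * p.edge, "iscrowd": 0}
            for k, p in enumerate(proposals)
        ],
        "categories": [{"id": 1, "name": "interesting"}],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def export_proposal_crops(ranked: Sequence[TrainingProposal], pixels_by_id,
                          out_dir: str | os.PathLike) -> list[str]:
    """Write each proposal's square crop as a PNG named by its rank, for a
    grid-review tool.  Returns the written paths."""
    from pathlib import Path

    import numpy as np
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rank, p in enumerate(ranked):
        img = pixels_by_id[p.image_id]
        crop = img[p.y : p.y + p.edge, p.x : p.x + p.edge]
        path = out / f"rank{rank:05d}_{p.image_id}_r{p.region_id}.png"
        Image.fromarray((np.asarray(crop) * 255 + 0.5).astype("uint8")).save(path)
        paths.append(str(path))
    return paths
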