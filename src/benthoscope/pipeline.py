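"""End-to-end orchestration of the unsupervised proposal stage.

``run_stage1`` chains clustering → per-cluster background-model training →
convolutional novelty mapping with dilation → per-cluster thresholding →
region extraction into a single ranked proposal list.  It exists so the
CLI, the parameter-search harness and the tests all run the identical code
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aen import DBM, train_dbm
from .clustering import cluster_dataset
from .config import PipelineConfig
from .image_store import ImageDataset
from .novelty import NoveltyMap, apply_dbm, dilate_novelty_map
from .proposals import (ClusterThreshold, TrainingProposal, compute_threshold,
                        proposals_from_map, rank_proposals)

__all__ = ["Stage1Result", "run_stage1", "novelty_maps_for_cluster"]


@dataclass
class Stage1Result:
    proposals: list[TrainingProposal]
    thresholds: dict[int, ClusterThreshold]
    dbms: dict[int, DBM]
    maps: dict[str, NoveltyMap] = field(default_factory=dict)


def novelty_maps_for_cluster(dataset: ImageDataset, dbm: DBM,
                             config: PipelineConfig) -> list[NoveltyMap]:
    maps = []
    for rec in dataset.cluster(dbm.cluster_id):
        nm = apply_dbm(dataset.pixels(rec.id), dbm, stride=config.stride,
                       image_id=rec.id, slice_rows=config.slice_rows)
        maps.append(dilate_novelty_map(nm, config.kernel_edge))
    return maps


def run_stage1(dataset: ImageDataset, config: PipelineConfig | None = None,
               keep_maps: bool = False, recluster: bool = True) -> Stage1Result:
    """Produce the ranked training-proposal list for a dataset.

    Images are clustered (unless ``recluster`` is false and assignments
    already exist), one background model is trained per cluster with a
    seed derived from the shared config seed, and each cluster's dilated
    novelty maps are thresholded at the mean of their 99th percentiles.
    """
    config = config or PipelineConfig()
    if recluster or not dataset.cluster_ids():
        cluster_dataset(dataset, n_clusters=config.n_clusters, seed=config.seed,
                        n_components=config.pca_components, thumb=config.thumb,
                        entropy_bins=config.entropy_bins)

    all_proposals: list[TrainingProposal] = []
    thresholds: dict[int, ClusterThreshold] = {}
    dbms: dict[int, DBM] = {}
    kept: dict[str, NoveltyMap] = {}
    for cid in dataset.cluster_ids():
        records = dataset.cluster(cid)
        dbm = train_dbm(records, config.aen_config(seed=config.seed + cid),
                        cluster_id=cid, dataset=dataset)
        dbms[cid] = dbm
        maps = novelty_maps_for_cluster(dataset, dbm, config)
        thr = compute_threshold(maps, cluster_id=cid)
        thresholds[cid] = thr
        for nm in maps:
            all_proposals.extend(
                proposals_from_map(nm, thr.t_k, min_edge=config.min_box_edge))
            if keep_maps:
                kept[nm.image_id] = nm
    return Stage1Result(proposals=rank_proposals(all_proposals),
                        thresholds=thresholds, dbms=dbms, maps=kept)
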