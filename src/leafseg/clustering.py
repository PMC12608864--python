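"""Decode embeddings + semantic logits into instance labels.

Points predicted "leaf" by the semantic head are clustered in embedding
space with flat-kernel mean shift; surviving modes become leaf instances.
The default bandwidth sits midway between the training margins
(δv + (δd − δv)/2): the discriminative loss shapes clusters of radius ≤ δv
with centers ≥ δd apart, so any bandwidth strictly between the margins
separates compliant embeddings.  Stem-predicted points are optionally
grouped into one stem instance per plant so stem-level scores can be
computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .cloud import LEAF, STEM, LabeledCloud

__all__ = ["InstancePrediction", "semantic_filter", "mean_shift",
           "assign_instances", "decode_instances", "connected_component_instances"]


@dataclass
class InstancePrediction:
    instance_ids: np.ndarray     # N ints; −1 = unassigned / non-instance
    cluster_centers: np.ndarray  # K × D_e
    confidences: np.ndarray      # K floats
    semantic_pred: np.ndarray    # N ints in {0, 1, 2}
    stem_instance_id: Optional[int] = None

    def summary(self) -> dict:
        ids = self.instance_ids
        k = int(ids.max()) + 1 if ids.size and ids.max() >= 0 else 0
        return {
            "K": k,
            "sizes": [int((ids == i).sum()) for i in range(k)],
            "confidences": [float(c) for c in self.confidences],
            "stem_instance_id": self.stem_instance_id,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), **kwargs)


def semantic_filter(semantic_logits: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-point argmax class (ties → lower index) and the leaf mask."""
    logits = np.asarray(semantic_logits, dtype=np.float64)
    if logits.ndim != 2 or logits.shape[1] != 3:
        raise ValueError("semantic logits must be N×3")
    semantic_pred = np.argmax(logits, axis=1).astype(np.int32)  # argmax takes first tie
    return semantic_pred == LEAF, semantic_pred


def mean_shift(embeddings: np.ndarray, bandwidth: float, max_iter: int = 300,
               tol_factor: float = 1e-4) -> Tuple[np.ndarray, np.ndarray]:
    """Flat-kernel mean shift over all points as seeds.

    Every seed iterates to its mode (shift < tol_factor × bandwidth or
    `max_iter` sweeps); modes closer than bandwidth/2 are merged in order of
    descending support count (ties by first-seen index) and each point is
    assigned to the nearest surviving mode.  Returns (cluster ids, centers).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n == 0:
        return np.zeros(0, dtype=np.int32), np.zeros((0, x.shape[1] if x.ndim > 1 else 1))
    seeds = x.copy()
    active = np.ones(n, dtype=bool)
    tol = tol_factor * bandwidth
    for _ in range(max_iter):
        if not active.any():
            break
        act = np.flatnonzero(active)
        within = cdist(seeds[act], x, "sqeuclidean") <= bandwidth * bandwidth
        counts = within.sum(axis=1)
        new = (within @ x) / counts[:, None]
        shift = np.linalg.norm(new - seeds[act], axis=1)
        seeds[act] = new
        active[act] = shift >= tol
    # support of each converged mode = points within one bandwidth
    support = (cdist(seeds, x, "sqeuclidean") <= bandwidth * bandwidth).sum(axis=1)
    order = np.lexsort((np.arange(n), -support))  # descending support, first-seen ties
    kept: list[int] = []
    merge_r2 = (bandwidth / 2.0) ** 2
    for i in order:
        if all(((seeds[i] - seeds[j]) ** 2).sum() >= merge_r2 for j in kept):
            kept.append(i)
    centers = seeds[np.array(kept, dtype=np.intp)]
    ids = np.argmin(cdist(x, centers, "sqeuclidean"), axis=1).astype(np.int32)
    return ids, centers


def assign_instances(cloud: LabeledCloud, mask: np.ndarray, cluster_ids: np.ndarray,
                     centers: np.ndarray, semantic_pred: np.ndarray,
                     min_cluster_size: int = 20, stem_as_instance: bool = True
                     ) -> InstancePrediction:
    """Dissolve small clusters, renumber survivors by size, emit predictions.

    Surviving clusters are renumbered 0..K−1 by descending size (ties by
    lexicographic center order); confidence = cluster size / masked count.
    Non-leaf points get −1, except that with `stem_as_instance` all
    stem-predicted points form one extra instance.
    """
    n = len(cloud)
    instance_ids = np.full(n, -1, dtype=np.int32)
    masked_idx = np.flatnonzero(mask)
    n_masked = len(masked_idx)
    kept_centers: list[np.ndarray] = []
    confidences: list[float] = []
    if n_masked and len(centers):
        sizes = np.bincount(cluster_ids, minlength=len(centers))
        surviving = [k for k in range(len(centers)) if sizes[k] >= min_cluster_size]
        surviving.sort(key=lambda k: (-sizes[k], tuple(centers[k])))
        for new_id, k in enumerate(surviving):
            instance_ids[masked_idx[cluster_ids == k]] = new_id
            kept_centers.append(centers[k])
            confidences.append(sizes[k] / n_masked)
    stem_id = None
    if stem_as_instance:
        stem_mask = semantic_pred == STEM
        if stem_mask.any():
            stem_id = len(kept_centers)
            instance_ids[stem_mask] = stem_id
            confidences.append(float(stem_mask.sum()) / n)
            kept_centers.append(np.full(centers.shape[1] if len(centers) else 1, np.nan))
    return InstancePrediction(
        instance_ids=instance_ids,
        cluster_centers=np.array(kept_centers) if kept_centers else np.zeros((0, 1)),
        confidences=np.asarray(confidences, dtype=np.float64),
        semantic_pred=np.asarray(semantic_pred, dtype=np.int32),
        stem_instance_id=stem_id,
    )


def decode_instances(cloud: LabeledCloud, embeddings: np.ndarray,
                     semantic_logits: np.ndarray, bandwidth: float = 1.0,
                     min_cluster_size: int = 20, stem_as_instance: bool = True,
                     semantic_filtering: bool = True) -> InstancePrediction:
    """Full decode: filter → mean shift → instance assignment.

    With `semantic_filtering` off (the no-semantic-filter ablation), all
    points are clustered and each surviving cluster's class is the majority
    semantic prediction of its members; majority-leaf clusters become leaf
    instances.
    """
    mask, semantic_pred = semantic_filter(semantic_logits)
    if not semantic_filtering:
        mask = np.ones(len(cloud), dtype=bool)
    ids, centers = mean_shift(np.asarray(embeddings)[mask], bandwidth)
    if not semantic_filtering and len(centers):
        # keep only majority-leaf clusters as leaf instances
        keep = np.zeros(len(centers), dtype=bool)
        masked_sem = semantic_pred[mask]
        for k in range(len(centers)):
            members = masked_sem[ids == k]
            if len(members) and np.bincount(members, minlength=3).argmax() == LEAF:
                keep[k] = True
        remap = np.full(len(centers), -1, dtype=np.int32)
        remap[keep] = np.arange(int(keep.sum()), dtype=np.int32)
        new_mask = np.zeros(len(cloud), dtype=bool)
        sel = remap[ids] >= 0
        new_mask[np.flatnonzero(mask)[sel]] = True
        ids = remap[ids][sel]
        centers = centers[keep]
        mask = new_mask
    return assign_instances(cloud, mask, ids, centers, semantic_pred,
                            min_cluster_size=min_cluster_size,
                            stem_as_instance=stem_as_instance)


def connected_component_instances(cloud: LabeledCloud, mask: np.ndarray,
                                  semantic_pred: np.ndarray, radius: float,
                                  min_cluster_size: int = 20,
                                  stem_as_instance: bool = True) -> InstancePrediction:
    """Euclidean connected components on masked points (no-embedding decode)."""
    from scipy.sparse.csgraph import connected_components
    from sklearn.neighbors import radius_neighbors_graph

    masked_idx = np.flatnonzero(mask)
    if len(masked_idx) == 0:
        return assign_instances(cloud, mask, np.zeros(0, np.int32), np.zeros((0, 3)),
                                semantic_pred, min_cluster_size, stem_as_instance)
    graph = radius_neighbors_graph(cloud.points[masked_idx], radius, mode="connectivity")
    _, labels = connected_components(graph, directed=False)
    centers = np.stack([cloud.points[masked_idx][labels == k].mean(axis=0)
                        for k in range(labels.max() + 1)])
    return assign_instances(cloud, mask, labels.astype(np.int32), centers,
                            semantic_pred, min_cluster_size, stem_as_instance)
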