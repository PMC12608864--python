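"""Instance-embedding and semantic heads with the discriminative loss.

Each point's fused feature is mapped in parallel to a low-dimensional
instance embedding e_i and to 3-class semantic logits (background / stem /
leaf).  Training shapes the embedding space with three hinged terms:

* variance loss — points are pulled within margin δv of their instance's
  embedding centroid μ_S: mean over instances of the per-instance mean of
  max(0, ‖μ_S − e_i‖ − δv)²;
* distance loss — centroids are pushed beyond margin δd (> δv) of each
  other: (2 / C(C−1)) Σ over ordered pairs of max(0, δd − ‖μ_S − μ_T‖)²;
* regularization — centroid norms are drawn to the origin: mean ‖μ_S‖.

The weighted sum α·L_var + β·L_dist + γ·L_reg (defaults 0.5, 0.3, 0.2) plus
a standard cross-entropy on the semantic logits is the training objective.
Only leaf instances (instance id ≥ 0) enter the embedding terms; background
and stem points participate through cross-entropy alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._autodiff import Tensor
from .nn import Linear, Module
from .slicing import PointFeatureSet

__all__ = ["LossConfig", "LossBreakdown", "EmbeddingOutput", "SegmentationHeads",
           "variance_loss", "distance_loss", "reg_loss", "composite_loss",
           "cross_entropy_loss"]

@dataclass
class LossConfig:
    delta_v: float = 0.5
    delta_d: float = 1.5
    alpha: float = 0.5
    beta: float = 0.3
    gamma: float = 0.2
    ce_weight: float = 1.0

    def __post_init__(self):
        if not (self.delta_d > self.delta_v > 0):
            raise ValueError("margins must satisfy delta_d > delta_v > 0")
        if min(self.alpha, self.beta, self.gamma, self.ce_weight) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossBreakdown:
    l_var: float
    l_dist: float
    l_reg: float
    l_embed: float
    l_ce: float
    total: float
    cluster_centers: np.ndarray
    total_tensor: Optional[Tensor] = None  # for backprop; dropped in logs


@dataclass
class EmbeddingOutput:
    embeddings: Tensor      # N × D_e
    semantic_logits: Tensor  # N × 3

    def __post_init__(self):
        if self.embeddings.shape[0] != self.semantic_logits.shape[0]:
            raise ValueError("embedding/logit row counts differ")


class SegmentationHeads(Module):
    """Parallel per-point maps: instance embedding and 3-class logits."""

    def __init__(self, model_dim: int, d_embed: int, rng: np.random.Generator):
        self.emb1 = Linear(model_dim, model_dim, rng)
        self.emb2 = Linear(model_dim, d_embed, rng)
        self.sem1 = Linear(model_dim, 32, rng)
        self.sem2 = Linear(32, 3, rng)

    def __call__(self, fused: PointFeatureSet) -> EmbeddingOutput:
        f = fused.features if isinstance(fused.features, Tensor) else Tensor(fused.features)
        emb = self.emb2(self.emb1(f).relu())
        logits = self.sem2(self.sem1(f).relu())
        return EmbeddingOutput(emb, logits)


def _row_norms(x: Tensor) -> Tensor:
    return x.rownorm()


def instance_centers(embeddings: Tensor, instance_labels: np.ndarray
                     ) -> Tuple[Optional[Tensor], np.ndarray, np.ndarray]:
    """Per-instance embedding centroids over points with instance id ≥ 0.

    Returns (centers C×D tensor or None, dense per-point instance index with
    −1 for unlabeled, instance sizes).
    """
    labels = np.asarray(instance_labels)
    mask = labels >= 0
    if not mask.any():
        return None, np.full(len(labels), -1, dtype=np.intp), np.zeros(0, dtype=np.intp)
    uniq, dense = np.unique(labels[mask], return_inverse=True)
    sizes = np.bincount(dense, minlength=len(uniq))
    full_dense = np.full(len(labels), -1, dtype=np.intp)
    full_dense[mask] = dense
    masked = embeddings.gather(np.flatnonzero(mask))
    centers = masked.segment_sum(dense, len(uniq)) * (1.0 / sizes[:, None])
    return centers, full_dense, sizes


def variance_loss(embeddings: Tensor, instance_labels: np.ndarray, delta_v: float
                  ) -> Tuple[Tensor, Optional[Tensor]]:
    """Intra-instance pull toward each centroid, hinged at margin δv."""
    centers, dense, sizes = instance_centers(embeddings, instance_labels)
    if centers is None:
        return Tensor(0.0), None
    mask_idx = np.flatnonzero(dense >= 0)
    seg = dense[mask_idx]
    diff = centers.gather(seg) - embeddings.gather(mask_idx)
    hinge = (_row_norms(diff) - delta_v).relu().pow(2.0)
    per_instance = hinge.segment_sum(seg, len(sizes)) * (1.0 / sizes)
    return per_instance.mean(), centers


def distance_loss(centers: Optional[Tensor], delta_d: float) -> Tensor:
    """Inter-centroid push beyond margin δd, over ordered pairs."""
    if centers is None:
        return Tensor(0.0)
    c = centers.shape[0]
    if c <= 1:
        return Tensor(0.0)
    iu, ju = np.triu_indices(c, k=1)
    diff = centers.gather(iu) - centers.gather(ju)
    hinge = (delta_d - _row_norms(diff)).relu().pow(2.0)
    # each unordered pair appears twice in the ordered double sum
    return hinge.sum() * (2.0 * 2.0 / (c * (c - 1)))


def reg_loss(centers: Optional[Tensor]) -> Tensor:
    """Mean centroid norm; keeps the embedding space bounded."""
    if centers is None or centers.shape[0] == 0:
        return Tensor(0.0)
    return _row_norms(centers).mean()


def cross_entropy_loss(logits: Tensor, semantic_labels: np.ndarray) -> Tensor:
    labels = np.asarray(semantic_labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) > 2:
        raise ValueError("semantic labels must lie in {0, 1, 2}")
    logp = logits.log_softmax(axis=1)
    n = len(labels)
    onehot = np.zeros((n, 3))
    onehot[np.arange(n), labels] = 1.0
    return -(logp * onehot).sum() * (1.0 / max(1, n))


def composite_loss(embeddings: Tensor, instance_labels: np.ndarray,
                   semantic_logits: Tensor, semantic_labels: np.ndarray,
                   cfg: LossConfig) -> LossBreakdown:
    """Full training objective and its per-term breakdown."""
    l_var, centers = variance_loss(embeddings, instance_labels, cfg.delta_v)
    l_dist = distance_loss(centers, cfg.delta_d)
    l_reg = reg_loss(centers)
    l_embed = cfg.alpha * l_var + cfg.beta * l_dist + cfg.gamma * l_reg
    l_ce = cross_entropy_loss(semantic_logits, semantic_labels)
    total = l_embed + cfg.ce_weight * l_ce
    return LossBreakdown(
        l_var=float(l_var.data), l_dist=float(l_dist.data), l_reg=float(l_reg.data),
        l_embed=float(l_embed.data), l_ce=float(l_ce.data), total=float(total.data),
        cluster_centers=centers.data.copy() if centers is not None else np.zeros((0,)),
        total_tensor=total,
    )
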