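"""End-to-end leaf instance segmentation as a scikit-learn-style estimator.

:class:`LeafSegmenter` wires the pipeline together: multi-scale recursive
slicing → per-slab encoding → backtracked per-point path features on a
three-level pyramid → attention-based context fusion → instance-embedding
and semantic heads, trained with the hinged discriminative loss plus
cross-entropy, and decoded at inference with semantic filtering and
mean-shift clustering.

Ablation switches mirror the architecture ladder: ``use_slicing`` swaps the
slicing features for a plain set-abstraction baseline encoder, ``use_fusion``
bypasses attention/pyramid fusion (level-0 aligned features go straight to
the heads), ``use_embedding`` drops the embedding head and decodes by
Euclidean connected components on predicted-leaf points, and
``use_semantic_filter`` controls the leaf-only clustering gate.

The default hyperparameters follow the full-scale training recipe (Adam,
learning rate 0.001, batch size 8, 150 epochs); :func:`desk_preset` returns
a configuration small enough to train on a laptop CPU in minutes.
"""

from __future__ import annotations

import json
import time
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Tensor, concat
from .cloud import LabeledCloud, estimate_normals
from .clustering import (InstancePrediction, connected_component_instances,
                         decode_instances, semantic_filter)
from .fusion import AttentionConfig, ContextFusionModule
from .heads import LossConfig, SegmentationHeads, composite_loss, cross_entropy_loss
from .nn import Adam, Linear, Module
from .slicing import (SCALES, PointFeatureSet, ScaleConfig, SliceEncoder,
                      compute_scale_thicknesses, farthest_point_sample,
                      path_features, recursive_slice, tree_encoder_batch)

__all__ = ["LeafSegmenter", "desk_preset", "save_checkpoint", "load_checkpoint"]

_N_EXTRA = 9  # positional channels: normalized xyz, normal, sin/cos azimuth, radius


class _BaselineEncoder(Module):
    """Plain set-abstraction encoder used when recursive slicing is off.

    Per-point MLP on the positional channels plus a cloud-wide max-pooled
    context vector concatenated to every point.
    """

    def __init__(self, d_slice: int, rng: np.random.Generator):
        self.d_slice = d_slice
        self.fc1 = Linear(_N_EXTRA, 32, rng)
        self.fc2 = Linear(32, 64, rng)
        self.fc3 = Linear(64, d_slice, rng)

    def __call__(self, rows: np.ndarray) -> Tensor:
        h = self.fc3(self.fc2(self.fc1(Tensor(rows)).relu()).relu()).relu()
        global_ctx = h.max(axis=0, keepdims=True)
        ones = np.ones((rows.shape[0], 1))
        return concat([h, Tensor(ones) @ global_ctx], axis=1)


class _Network(Module):
    """All trainable parameters of one configuration."""

    def __init__(self, scale_cfg: ScaleConfig, attn_cfg: AttentionConfig,
                 d_slice: int, d_embed: int, use_slicing: bool, use_fusion: bool,
                 use_embedding: bool, rng: np.random.Generator):
        self.use_slicing = use_slicing
        self.use_fusion = use_fusion
        self.use_embedding = use_embedding
        if use_slicing:
            self.encoders = [SliceEncoder(d_slice, rng) for _ in SCALES]
            width = (scale_cfg.max_depth + 1) * d_slice + _N_EXTRA
        else:
            self.baseline = _BaselineEncoder(d_slice, rng)
            width = 2 * d_slice + _N_EXTRA
        self.fusion = ContextFusionModule([width] * 3, attn_cfg, rng)
        self.heads = SegmentationHeads(attn_cfg.model_dim, d_embed, rng)


class _PlantGraph:
    """Static per-cloud structures reused across epochs."""

    def __init__(self, cloud: LabeledCloud, scale_cfg: ScaleConfig, use_slicing: bool,
                 fps_ratios=(0.25, 0.0625)):
        if cloud.normals is None:
            cloud = estimate_normals(cloud, k=min(16, max(3, len(cloud) - 1)))
        self.cloud = cloud
        n = len(cloud)
        center = cloud.points.mean(axis=0)
        extent = float(np.linalg.norm(cloud.points.max(axis=0) - cloud.points.min(axis=0)))
        self.xyz_norm = (cloud.points - center) / (extent if extent > 0 else 1.0)
        # cylindrical coordinates about the (gravity-aligned) plant axis:
        # leaves subtend distinct azimuth sectors, a strong instance cue
        xy = self.xyz_norm[:, :2]
        azimuth = np.arctan2(xy[:, 1], xy[:, 0])
        radial = np.linalg.norm(xy, axis=1)
        self.extras = np.hstack([self.xyz_norm, cloud.normals,
                                 np.sin(azimuth)[:, None], np.cos(azimuth)[:, None],
                                 radial[:, None]])
        self.thicknesses = compute_scale_thicknesses(cloud, scale_cfg) if n >= 2 else None
        self.batches = {}
        if use_slicing and n:
            for s in SCALES:
                tree = recursive_slice(cloud, s, scale_cfg, self.thicknesses[s])
                self.batches[s] = tree_encoder_batch(cloud, tree)
        self.idx1 = farthest_point_sample(cloud.points, max(1, int(round(fps_ratios[0] * n))))
        self.idx2 = farthest_point_sample(cloud.points, max(1, int(round(fps_ratios[1] * n))))


def _forward(net: _Network, graph: _PlantGraph, scale_cfg: ScaleConfig):
    """Per-point embeddings and semantic logits for one plant."""
    n = len(graph.cloud)
    all_idx = np.arange(n)
    if net.use_slicing:
        feats = {}
        for s, enc in zip(SCALES, net.encoders):
            rows, seg, n_nodes, depth_maps = graph.batches[s]
            feats[s] = path_features(enc, rows, seg, n_nodes, depth_maps, n,
                                     scale_cfg.max_depth)
        base = {"fine": feats["fine"], "medium": feats["medium"], "coarse": feats["coarse"]}
    else:
        h = net.baseline(graph.extras)
        base = {"fine": h, "medium": h, "coarse": h}

    def level(feat: Tensor, idx: np.ndarray, lv) -> PointFeatureSet:
        f = feat if len(idx) == n else feat.gather(idx)
        f = concat([f, Tensor(graph.extras[idx])], axis=1)
        return PointFeatureSet(lv, graph.cloud.points[idx], f, idx)

    l0 = level(base["fine"], all_idx, 0)
    if net.use_fusion:
        l1 = level(base["medium"], graph.idx1, 1)
        l2 = level(base["coarse"], graph.idx2, 2)
        fused = net.fusion(l0, l1, l2)
    else:
        fused = PointFeatureSet("fused", l0.positions,
                                net.fusion.aligners[0](l0.features), l0.point_indices)
    return net.heads(fused)


def desk_preset(**overrides) -> "LeafSegmenter":
    """Small configuration that trains in minutes on one CPU core."""
    params = dict(d_slice=32, model_dim=64, d_embed=16, n_blocks=1,
                  epochs=30, min_points=24)
    params.update(overrides)
    return LeafSegmenter(**params)


class LeafSegmenter(BaseEstimator):
    """Instance segmentation of leaves in potted-plant point clouds.

    Parameters follow the pipeline stages; see the package documentation for
    the science.  ``fit`` expects a list of :class:`LabeledCloud` carrying
    semantic and instance labels; ``predict`` returns one
    :class:`InstancePrediction` per cloud.
    """

    def __init__(self, d_slice: int = 64, model_dim: int = 256, d_embed: int = 32,
                 n_blocks: int = 2, coarse_fraction: float = 0.08,
                 medium_thickness: Optional[float] = None,
                 fine_multiplier: float = 4.0, min_points: int = 32,
                 normal_var_threshold: float = 0.01, max_depth: int = 3,
                 expected_leaf_count: int = 6, delta_v: float = 0.5,
                 delta_d: float = 1.5, alpha: float = 0.5, beta: float = 0.3,
                 gamma: float = 0.2, ce_weight: float = 1.0,
                 bandwidth: Optional[float] = None, min_cluster_size: int = 20,
                 stem_as_instance: bool = True, learning_rate: float = 0.001,
                 batch_size: int = 8, epochs: int = 150, seed: int = 0,
                 use_slicing: bool = True, use_fusion: bool = True,
                 use_embedding: bool = True, use_semantic_filter: bool = True):
        self.d_slice = d_slice
        self.model_dim = model_dim
        self.d_embed = d_embed
        self.n_blocks = n_blocks
        self.coarse_fraction = coarse_fraction
        self.medium_thickness = medium_thickness
        self.fine_multiplier = fine_multiplier
        self.min_points = min_points
        self.normal_var_threshold = normal_var_threshold
        self.max_depth = max_depth
        self.expected_leaf_count = expected_leaf_count
        self.delta_v = delta_v
        self.delta_d = delta_d
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.ce_weight = ce_weight
        self.bandwidth = bandwidth
        self.min_cluster_size = min_cluster_size
        self.stem_as_instance = stem_as_instance
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.use_slicing = use_slicing
        self.use_fusion = use_fusion
        self.use_embedding = use_embedding
        self.use_semantic_filter = use_semantic_filter

    # -- config plumbing --------------------------------------------------
    def _scale_cfg(self) -> ScaleConfig:
        return ScaleConfig(coarse_fraction=self.coarse_fraction,
                           medium_thickness=self.medium_thickness,
                           expected_leaf_count=self.expected_leaf_count,
                           fine_multiplier=self.fine_multiplier,
                           min_points=self.min_points,
                           normal_var_threshold=self.normal_var_threshold,
                           max_depth=self.max_depth)

    def _attn_cfg(self) -> AttentionConfig:
        return AttentionConfig(model_dim=self.model_dim, n_blocks=self.n_blocks)

    def _loss_cfg(self) -> LossConfig:
        return LossConfig(delta_v=self.delta_v, delta_d=self.delta_d,
                          alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                          ce_weight=self.ce_weight)

    def _bandwidth(self) -> float:
        # just above the compliant cluster radius delta_v: wide enough to
        # cover one embedding cluster, narrow enough that a seed on a
        # cluster's edge cannot capture a neighboring cluster (which starts
        # once the bandwidth exceeds delta_d - 2*delta_v)
        if self.bandwidth is not None:
            return self.bandwidth
        return 1.2 * self.delta_v

    def _build_network(self) -> _Network:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed,
                                                           spawn_key=(0,)))
        return _Network(self._scale_cfg(), self._attn_cfg(), self.d_slice,
                        self.d_embed, self.use_slicing, self.use_fusion,
                        self.use_embedding, rng)

    def _graph(self, cloud: LabeledCloud) -> _PlantGraph:
        return _PlantGraph(cloud, self._scale_cfg(), self.use_slicing)

    # -- training ---------------------------------------------------------
    def fit(self, X: Sequence[LabeledCloud], y=None, verbose: bool = False):
        """Train on labeled clouds; ground truth lives inside each cloud."""
        clouds = list(X)
        if not clouds:
            raise ValueError("no training clouds")
        for c in clouds:
            if c.semantic is None or c.instance is None:
                raise ValueError("training clouds need semantic and instance labels")
        self.network_ = self._build_network()
        scale_cfg = self._scale_cfg()
        loss_cfg = self._loss_cfg()
        graphs = [self._graph(c) for c in clouds]
        params = self.network_.parameters()
        opt = Adam(params, lr=self.learning_rate)
        order_rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed,
                                                                 spawn_key=(1,)))
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = order_rng.permutation(len(graphs))
            sums: Dict[str, float] = {k: 0.0 for k in
                                      ("l_var", "l_dist", "l_reg", "l_embed", "l_ce", "total")}
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                opt.zero_grad()
                for gi in batch:
                    graph = graphs[gi]
                    out = _forward(self.network_, graph, scale_cfg)
                    if self.use_embedding:
                        loss = composite_loss(out.embeddings, graph.cloud.instance,
                                              out.semantic_logits, graph.cloud.semantic,
                                              loss_cfg)
                        total_t = loss.total_tensor
                        comp = {k: getattr(loss, k) for k in sums}
                    else:
                        total_t = cross_entropy_loss(out.semantic_logits,
                                                     graph.cloud.semantic)
                        comp = {k: 0.0 for k in sums}
                        comp["l_ce"] = comp["total"] = float(total_t.data)
                    if not np.isfinite(total_t.data):
                        raise RuntimeError(
                            f"training diverged: non-finite loss at epoch {epoch}, "
                            f"plant {gi} (components: {comp})")
                    total_t.backward(np.asarray(1.0 / len(batch)))
                    for k in sums:
                        sums[k] += comp[k]
                opt.step()
            record = {"epoch": epoch, **{k: v / len(graphs) for k, v in sums.items()}}
            self.loss_history_.append(record)
            if verbose:
                print(json.dumps(record))
        self.n_features_in_ = 3
        return self

    # -- inference --------------------------------------------------------
    def predict_one(self, cloud: LabeledCloud, return_timings: bool = False):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        timings: Dict[str, float] = {}
        if len(cloud) == 0:
            empty = InstancePrediction(np.zeros(0, np.int32), np.zeros((0, 1)),
                                       np.zeros(0), np.zeros(0, np.int32))
            return (empty, timings) if return_timings else empty
        t0 = time.perf_counter()
        graph = self._graph(cloud)
        timings["slicing"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        out = _forward(self.network_, graph, self._scale_cfg())
        timings["network"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        if self.use_embedding:
            pred = decode_instances(
                graph.cloud, out.embeddings.data, out.semantic_logits.data,
                bandwidth=self._bandwidth(), min_cluster_size=self.min_cluster_size,
                stem_as_instance=self.stem_as_instance,
                semantic_filtering=self.use_semantic_filter)
        else:
            mask, semantic_pred = semantic_filter(out.semantic_logits.data)
            radius = (graph.thicknesses or {}).get("fine", 0.02)
            pred = connected_component_instances(
                graph.cloud, mask, semantic_pred, radius,
                min_cluster_size=self.min_cluster_size,
                stem_as_instance=self.stem_as_instance)
        timings["clustering"] = time.perf_counter() - t0
        return (pred, timings) if return_timings else pred

    def predict(self, X) -> List[InstancePrediction]:
        if isinstance(X, LabeledCloud):
            X = [X]
        return [self.predict_one(c) for c in X]

    def score(self, X, y=None) -> float:
        """Leaf AP50 on labeled clouds (higher is better)."""
        from .metrics import evaluate

        clouds = [X] if isinstance(X, LabeledCloud) else list(X)
        preds = self.predict(clouds)
        result = evaluate(preds, clouds)
        return result.per_class.get("leaf", {}).get("AP50", float("nan"))


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(est: LeafSegmenter, path) -> None:
    """Single-archive checkpoint: parameters + config + loss history."""
    if not hasattr(est, "network_"):
        raise RuntimeError("estimator is not fitted")
    meta = {"params": est.get_params(),
            "loss_history": getattr(est, "loss_history_", [])}
    state = est.network_.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> LeafSegmenter:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    est = LeafSegmenter(**meta["params"])
    est.network_ = est._build_network()
    est.network_.load_state_dict(state)
    est.loss_history_ = meta["loss_history"]
    est.n_features_in_ = 3
    return est
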