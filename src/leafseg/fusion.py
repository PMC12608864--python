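"""Context fusion: feature alignment, self-attention, pyramid fusion.

Per-level features from the slicer are first projected into a shared
``model_dim`` space by a two-layer perceptron, then refined by stacked
single-head scaled dot-product self-attention blocks (softmax((q·k)/√d)
weighted sums of value vectors, with residual connections and layer
normalization).  The three pyramid levels are finally merged top-down:
coarse features are interpolated onto the next finer level's positions with
inverse-distance-weighted k-NN averaging and fused by concatenation plus a
small per-point map, ending with fused features on every level-0 point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.spatial import cKDTree

from ._autodiff import Tensor, concat
from .nn import LayerNorm, Linear, Module
from .slicing import PointFeatureSet

__all__ = ["AttentionConfig", "FeatureAligner", "SelfAttentionBlock",
           "knn_interpolate", "PyramidFusion", "ContextFusionModule"]


@dataclass
class AttentionConfig:
    model_dim: int = 256
    n_blocks: int = 2
    interp_k: int = 3

    def __post_init__(self):
        if self.model_dim <= 0 or self.n_blocks < 0:
            raise ValueError("model_dim must be > 0 and n_blocks >= 0")


class FeatureAligner(Module):
    """Two-layer per-point map into the unified model_dim space."""

    def __init__(self, n_in: int, model_dim: int, rng: np.random.Generator):
        self.n_in = n_in
        self.fc1 = Linear(n_in, model_dim, rng)
        self.fc2 = Linear(model_dim, model_dim, rng)

    def __call__(self, features: Tensor) -> Tensor:
        if features.shape[-1] != self.n_in:
            raise ValueError(
                f"feature width {features.shape[-1]} != aligner input {self.n_in}")
        return self.fc2(self.fc1(features).relu())


class SelfAttentionBlock(Module):
    """Single-head transformer block: attention + residual/norm + feed-forward."""

    def __init__(self, model_dim: int, rng: np.random.Generator):
        self.model_dim = model_dim
        self.wq = Linear(model_dim, model_dim, rng)
        self.wk = Linear(model_dim, model_dim, rng)
        self.wv = Linear(model_dim, model_dim, rng)
        self.norm1 = LayerNorm(model_dim)
        self.ff1 = Linear(model_dim, model_dim, rng)
        self.ff2 = Linear(model_dim, model_dim, rng)
        self.norm2 = LayerNorm(model_dim)

    def attention_weights(self, f: Tensor) -> Tensor:
        """Row-stochastic attention matrix a[i, j] = softmax_j(q_i·k_j/√d)."""
        q, k = self.wq(f), self.wk(f)
        return ((q @ k.T) * (1.0 / np.sqrt(self.model_dim))).softmax(axis=1)

    def attend(self, f: Tensor) -> Tensor:
        """The raw attention output Σ_j a[i, j] v_j (before residual/norm)."""
        return self.attention_weights(f) @ self.wv(f)

    def __call__(self, f: Tensor) -> Tensor:
        if not np.isfinite(f.data).all():
            raise FloatingPointError("non-finite attention input")
        y = self.norm1(f + self.attend(f))
        return self.norm2(y + self.ff2(self.ff1(y).relu()))


def knn_interpolate(source: PointFeatureSet, query_positions: np.ndarray,
                    k: int = 3, eps: float = 1e-8) -> Tensor:
    """Inverse-distance-weighted k-NN feature interpolation.

    A query within `eps` of a source point returns that source's feature
    exactly; otherwise weights are 1/(dist+eps), normalized over the k
    nearest sources.
    """
    n_src = len(source.positions)
    if n_src == 0:
        raise ValueError("empty interpolation source")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_src:
        import warnings

        warnings.warn(f"interpolation k={k} clamped to source size {n_src}", stacklevel=2)
        k = n_src
    tree = cKDTree(source.positions)
    dist, idx = tree.query(query_positions, k=k)
    dist = np.atleast_2d(dist.reshape(len(query_positions), k))
    idx = np.atleast_2d(idx.reshape(len(query_positions), k))
    w = 1.0 / (dist + eps)
    exact = dist[:, 0] < eps
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    feats = source.features if isinstance(source.features, Tensor) else Tensor(source.features)
    out = None
    for j in range(k):
        term = feats.gather(idx[:, j]) * w[:, j:j + 1]
        out = term if out is None else out + term
    return out


class PyramidFusion(Module):
    """Top-down fusion of levels 2 → 1 → 0 (concatenate + small MLP)."""

    def __init__(self, model_dim: int, rng: np.random.Generator, interp_k: int = 3):
        self.model_dim = model_dim
        self.interp_k = interp_k
        self.fuse21_a = Linear(2 * model_dim, model_dim, rng)
        self.fuse21_b = Linear(model_dim, model_dim, rng)
        self.fuse10_a = Linear(2 * model_dim, model_dim, rng)
        self.fuse10_b = Linear(model_dim, model_dim, rng)

    def _fuse(self, top: Tensor, lateral: Tensor, a: Linear, b: Linear) -> Tensor:
        return b(a(concat([top, lateral], axis=1)).relu())

    def __call__(self, level0: PointFeatureSet, level1: Optional[PointFeatureSet],
                 level2: Optional[PointFeatureSet]) -> PointFeatureSet:
        feats0 = level0.features if isinstance(level0.features, Tensor) else Tensor(level0.features)
        carry = None
        if level2 is not None and level1 is not None:
            top = knn_interpolate(level2, level1.positions, k=self.interp_k)
            lat = level1.features if isinstance(level1.features, Tensor) else Tensor(level1.features)
            carry = PointFeatureSet(1, level1.positions,
                                    self._fuse(top, lat, self.fuse21_a, self.fuse21_b),
                                    level1.point_indices)
        elif level1 is not None:
            carry = level1
        elif level2 is not None:
            carry = level2
        if carry is not None:
            top = knn_interpolate(carry, level0.positions, k=self.interp_k)
        else:
            top = feats0  # single-level fallback: skip connections degenerate
        fused = self._fuse(top, feats0, self.fuse10_a, self.fuse10_b)
        return PointFeatureSet("fused", level0.positions, fused, level0.point_indices)


class ContextFusionModule(Module):
    """Aligners + per-level attention stacks + pyramid fusion, end to end."""

    def __init__(self, input_widths: List[int], cfg: AttentionConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.aligners = [FeatureAligner(w, cfg.model_dim, rng) for w in input_widths]
        self.blocks = [[SelfAttentionBlock(cfg.model_dim, rng) for _ in range(cfg.n_blocks)]
                       for _ in input_widths]
        self.pyramid = PyramidFusion(cfg.model_dim, rng, interp_k=cfg.interp_k)

    def align_and_attend(self, level: PointFeatureSet, which: int) -> PointFeatureSet:
        feats = level.features if isinstance(level.features, Tensor) else Tensor(level.features)
        f = self.aligners[which](feats)
        for block in self.blocks[which]:
            f = block(f)
        return PointFeatureSet(level.level, level.positions, f, level.point_indices)

    def __call__(self, level0: PointFeatureSet, level1: Optional[PointFeatureSet],
                 level2: Optional[PointFeatureSet]) -> PointFeatureSet:
        a0 = self.align_and_attend(level0, 0)
        a1 = self.align_and_attend(level1, 1) if level1 is not None else None
        a2 = self.align_and_attend(level2, 2) if level2 is not None else None
        return self.pyramid(a0, a1, a2)
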