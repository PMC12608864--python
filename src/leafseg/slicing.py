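"""Multi-scale recursive slab slicing and per-slice feature encoding.

The point cloud is partitioned three times — at coarse, medium and fine slab
thicknesses — by parallel planes perpendicular to the gravity axis (+z).
Each slab whose geometry is still complex (enough points, enough normal
dispersion, below the depth cap) is re-sliced along its own principal axis
with the thickness halved, producing a tree of nested slabs per scale.
Every slab is encoded by a shared permutation-invariant point-set encoder
(per-point MLP, learned soft attention gate, max pooling), and each point
receives the concatenated encodings of all slabs on its root-to-leaf path.

Scale thicknesses are data-adaptive: coarse is a fraction of the plant
height (default 8%, inside the conventional 5–10% band), medium tracks a
median leaf-extent estimate, and fine is a small multiple of the median
nearest-neighbor spacing, i.e. close to the resolution limit of the cloud.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._autodiff import Tensor, concat
from .cloud import LabeledCloud, estimate_normals
from .nn import Linear, Module

__all__ = [
    "ScaleConfig", "SliceNode", "SliceTree", "compute_scale_thicknesses",
    "slice_once", "choose_direction", "recursive_slice", "SliceEncoder",
    "backtrack_aggregate", "farthest_point_sample", "normal_axis_variance",
    "SCALES",
]

SCALES = ("coarse", "medium", "fine")


class DegenerateGeometryError(ValueError):
    """Input geometry too degenerate to slice (zero extent / coincident points)."""


@dataclass
class ScaleConfig:
    coarse_fraction: float = 0.08        # slab thickness / plant height
    medium_thickness: Optional[float] = None  # absolute override, meters
    medium_leaf_fraction: float = 0.2    # of height / sqrt(expected leaf count)
    expected_leaf_count: int = 6
    fine_multiplier: float = 4.0         # × median nearest-neighbor spacing
    min_points: int = 32                 # recursion floor
    normal_var_threshold: float = 0.01   # geometric-simplicity cutoff
    max_depth: int = 3

    def __post_init__(self):
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.coarse_fraction <= 0:
            raise ValueError("coarse_fraction must be > 0")


@dataclass
class SliceNode:
    point_indices: np.ndarray
    depth: int
    direction: np.ndarray
    interval: Tuple[float, float]
    children: List["SliceNode"] = field(default_factory=list)
    termination_reason: str = "none"     # none | min_points | simplicity | max_depth

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "direction": [float(v) for v in self.direction],
            "interval": [float(self.interval[0]), float(self.interval[1])],
            "n_points": int(len(self.point_indices)),
            "point_indices": [int(i) for i in self.point_indices],
            "termination_reason": self.termination_reason,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class SliceTree:
    scale: str
    roots: List[SliceNode]
    n_points: int

    def nodes(self) -> List[SliceNode]:
        out, stack = [], list(self.roots)
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def max_depth(self) -> int:
        return max((n.depth for n in self.nodes()), default=-1)

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "scale": self.scale,
            "n_points": self.n_points,
            "roots": [r.to_dict() for r in self.roots],
        }, **kwargs)


# --------------------------------------------------------------------------
# geometry primitives
# --------------------------------------------------------------------------

def median_nn_spacing(points: np.ndarray) -> float:
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return float(np.median(dist[:, 1]))


def compute_scale_thicknesses(cloud: LabeledCloud, cfg: ScaleConfig) -> Dict[str, float]:
    """Coarse/medium/fine slab thicknesses; clamped so fine <= medium <= coarse."""
    if len(cloud) < 2:
        raise ValueError("need at least 2 points")
    height = cloud.height
    if height <= 0:
        raise DegenerateGeometryError("plant has zero z-extent")
    coarse = cfg.coarse_fraction * height
    if cfg.medium_thickness is not None:
        medium = float(cfg.medium_thickness)
    else:
        medium = cfg.medium_leaf_fraction * height / max(1.0, np.sqrt(cfg.expected_leaf_count))
    fine = cfg.fine_multiplier * median_nn_spacing(cloud.points)
    medium = min(medium, coarse)
    fine = min(fine, medium)
    return {"coarse": coarse, "medium": medium, "fine": fine}


def slice_once(indices: np.ndarray, points: np.ndarray, direction: np.ndarray,
               thickness: float) -> List[Tuple[np.ndarray, Tuple[float, float]]]:
    """Partition `indices` into contiguous half-open slabs along `direction`.

    Bins are [low, low + thickness) starting at the minimum projection; a
    point exactly on a bin boundary goes to the upper bin.  Only nonempty
    slabs are returned.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    proj = points[indices] @ direction
    lo = proj.min()
    bins = np.floor((proj - lo) / thickness).astype(np.int64)
    out = []
    for b in np.unique(bins):
        mask = bins == b
        interval = (lo + b * thickness, lo + (b + 1) * thickness)
        out.append((indices[mask], interval))
    return out


def choose_direction(points: np.ndarray) -> np.ndarray:
    """Principal axis of a sub-region, sign-fixed for reproducibility.

    The sign is chosen so the z component is nonnegative; if it is zero, the
    x then y components decide.
    """
    if len(points) < 2 or np.allclose(points, points[0]):
        raise DegenerateGeometryError("all points coincident")
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    _, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    for axis in (2, 0, 1):
        if v[axis] > 0:
            break
        if v[axis] < 0:
            v = -v
            break
    return v


def normal_axis_variance(normals: np.ndarray) -> float:
    """Dispersion of sign-disambiguated unit normals: 1 − ‖mean normal‖.

    0 for a plane (identical normals), approaching 1 for isotropic normals.
    """
    from .cloud import orient_normals

    if len(normals) == 0:
        return 0.0
    mean = orient_normals(normals).mean(axis=0)
    return float(1.0 - np.linalg.norm(mean))


def recursive_slice(cloud: LabeledCloud, scale: str, cfg: ScaleConfig,
                    thickness: Optional[float] = None) -> SliceTree:
    """Build one scale's slice tree by recursive slab subdivision.

    Depth 0 slices the whole cloud along +z at the scale thickness; deeper
    levels re-slice each complex slab along its own principal axis with the
    thickness halved per depth.  Leaves record why recursion stopped.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    if len(cloud) == 0:
        return SliceTree(scale=scale, roots=[], n_points=0)
    if cloud.normals is None:
        cloud = estimate_normals(cloud, k=min(16, max(3, len(cloud) - 1)))
    if thickness is None:
        thickness = compute_scale_thicknesses(cloud, cfg)[scale]
    points, normals = cloud.points, cloud.normals
    z = np.array([0.0, 0.0, 1.0])

    def build(indices: np.ndarray, depth: int, direction: np.ndarray,
              interval: Tuple[float, float]) -> SliceNode:
        node = SliceNode(indices, depth, direction, interval)
        if len(indices) < cfg.min_points:
            node.termination_reason = "min_points"
            return node
        if normal_axis_variance(normals[indices]) < cfg.normal_var_threshold:
            node.termination_reason = "simplicity"
            return node
        if depth >= cfg.max_depth:
            node.termination_reason = "max_depth"
            return node
        try:
            child_dir = choose_direction(points[indices])
        except DegenerateGeometryError:
            node.termination_reason = "simplicity"
            return node
        child_thickness = thickness / (2.0 ** (depth + 1))
        for idx, ivl in slice_once(indices, points, child_dir, child_thickness):
            node.children.append(build(idx, depth + 1, child_dir, ivl))
        return node

    all_idx = np.arange(len(cloud))
    roots = [build(idx, 0, z, ivl) for idx, ivl in slice_once(all_idx, points, z, thickness)]
    return SliceTree(scale=scale, roots=roots, n_points=len(cloud))


# --------------------------------------------------------------------------
# per-slice encoder and backtracking aggregation
# --------------------------------------------------------------------------

@dataclass
class PointFeatureSet:
    """Per-point features at one pyramid level (fine=0, medium=1, coarse=2)."""

    level: object                       # 0 | 1 | 2 | "fused"
    positions: np.ndarray               # M × 3
    features: object                    # Tensor or ndarray, M × D
    point_indices: Optional[np.ndarray] = None  # indices into the full cloud

    @property
    def data(self) -> np.ndarray:
        return self.features.data if isinstance(self.features, Tensor) else self.features


class SliceEncoder(Module):
    """Permutation-invariant slab encoder: MLP → soft gate → max pool.

    Per-point input is the slab-centered, diagonal-scaled coordinates plus
    the point normal (6 values).  A learned scalar score per point is
    soft-normalized across the slab and gates the per-point features before
    elementwise max pooling, amplifying responses of salient points (margins,
    vein ridges) — a light form of local attention.
    """

    def __init__(self, d_slice: int, rng: np.random.Generator):
        self.d_slice = d_slice
        self.fc1 = Linear(6, 32, rng)
        self.fc2 = Linear(32, 64, rng)
        self.fc3 = Linear(64, d_slice, rng)
        self.score = Linear(d_slice, 1, rng)

    def encode_batch(self, rows: np.ndarray, seg: np.ndarray, n_seg: int) -> Tensor:
        """Encode many slabs at once; `rows` grouped by slab id `seg` (sorted)."""
        h = self.fc3(self.fc2(self.fc1(Tensor(rows)).relu()).relu()).relu()
        scores = self.score(h).reshape(-1)
        # gates normalized to unit mean per slab (not unit sum), so that
        # duplicating a point leaves the pooled feature unchanged
        counts = np.bincount(seg, minlength=n_seg).astype(np.float64)
        gate = scores.segment_softmax(seg, n_seg) * counts[seg]
        gated = h * gate.reshape(-1, 1)
        return gated.segment_max(seg, n_seg)

    def __call__(self, points: np.ndarray, normals: np.ndarray) -> Tensor:
        """Encode a single slab of points; returns a length-d_slice feature."""
        rows = slab_input_rows(points, normals)
        return self.encode_batch(rows, np.zeros(len(rows), dtype=np.intp), 1).reshape(-1)


def slab_input_rows(points: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Slab-normalized per-point encoder input: centered/scaled xyz + normal.

    The centroid accumulates each column in sorted order, so the rows (and
    hence the pooled slab feature) are bitwise invariant to point order.
    """
    centroid = np.sort(points, axis=0).sum(axis=0) / len(points)
    centered = points - centroid
    diag = np.linalg.norm(points.max(axis=0) - points.min(axis=0))
    if diag <= 0:
        diag = 1.0
    return np.hstack([centered / diag, normals])


def tree_encoder_batch(cloud: LabeledCloud, tree: SliceTree):
    """Flatten a tree into one encoder batch.

    Returns (rows, seg, n_nodes, depth_maps) where depth_maps[d] maps each
    cloud point to its node id at depth d (or n_nodes for "no node", used as
    a zero-feature slot).
    """
    nodes = []
    stack = list(tree.roots)
    while stack:
        node = stack.pop()
        nodes.append(node)
        stack.extend(node.children)
    nodes.sort(key=lambda n: (n.depth, n.point_indices[0] if len(n.point_indices) else -1))
    n_nodes = len(nodes)
    rows_list, seg_list = [], []
    max_depth = max((n.depth for n in nodes), default=0)
    depth_maps = [np.full(tree.n_points, n_nodes, dtype=np.intp) for _ in range(max_depth + 1)]
    for node_id, node in enumerate(nodes):
        idx = node.point_indices
        rows_list.append(slab_input_rows(cloud.points[idx], cloud.normals[idx]))
        seg_list.append(np.full(len(idx), node_id, dtype=np.intp))
        depth_maps[node.depth][idx] = node_id
    rows = np.vstack(rows_list) if rows_list else np.zeros((0, 6))
    seg = np.concatenate(seg_list) if seg_list else np.zeros(0, dtype=np.intp)
    return rows, seg, n_nodes, depth_maps


def path_features(encoder: SliceEncoder, rows: np.ndarray, seg: np.ndarray,
                 n_nodes: int, depth_maps: List[np.ndarray], n_points: int,
                 pad_depth: int) -> Tensor:
    """Per-point path features from a pre-flattened encoder batch."""
    node_feat = encoder.encode_batch(rows, seg, n_nodes)
    # append a zero row used by depths where a point has no node
    zero_row = Tensor(np.zeros((1, encoder.d_slice)))
    padded = concat([node_feat, zero_row], axis=0)
    slots = []
    for d in range(pad_depth + 1):
        if d < len(depth_maps):
            slots.append(padded.gather(depth_maps[d]))
        else:
            slots.append(Tensor(np.zeros((n_points, encoder.d_slice))))
    return concat(slots, axis=1)


def encode_tree(cloud: LabeledCloud, tree: SliceTree, encoder: SliceEncoder,
                pad_depth: int) -> Tensor:
    """Per-point path features: concatenation of slab encodings along each
    point's root-to-leaf path, zero-padded to ``pad_depth + 1`` slots."""
    rows, seg, n_nodes, depth_maps = tree_encoder_batch(cloud, tree)
    return path_features(encoder, rows, seg, n_nodes, depth_maps, tree.n_points, pad_depth)


def farthest_point_sample(points: np.ndarray, m: int, start: int = 0) -> np.ndarray:
    """Greedy farthest-point subsampling; deterministic from `start`."""
    n = len(points)
    m = min(m, n)
    if m <= 0:
        return np.zeros(0, dtype=np.intp)
    chosen = np.empty(m, dtype=np.intp)
    chosen[0] = start
    dist = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(dist))
        chosen[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    return chosen


def backtrack_aggregate(cloud: LabeledCloud, trees: Dict[str, SliceTree],
                        encoders: Dict[str, SliceEncoder], cfg: ScaleConfig,
                        fps_ratios: Tuple[float, float] = (0.25, 0.0625),
                        extra_channels: Optional[np.ndarray] = None):
    """Assemble the three pyramid levels of per-point multi-scale features.

    Level 0 carries fine-scale path features on all N points; levels 1 and 2
    live on farthest-point-sampled subsets (default ratios 0.25 and 0.0625)
    and carry the sampled points' medium and coarse path features.  When
    ``extra_channels`` is given (N × E), those per-point channels are
    concatenated at every level.
    """
    n = len(cloud)
    feats = {s: encode_tree(cloud, trees[s], encoders[s], cfg.max_depth) for s in SCALES}
    for s in SCALES:
        covered = np.zeros(n, dtype=bool)
        for node in trees[s].roots:
            covered[node.point_indices] = True
        if not covered.all():
            raise RuntimeError(f"{s} slice tree does not cover all points")
    idx1 = farthest_point_sample(cloud.points, max(1, int(round(fps_ratios[0] * n))))
    idx2 = farthest_point_sample(cloud.points, max(1, int(round(fps_ratios[1] * n))))

    def with_extra(t: Tensor, idx: np.ndarray) -> Tensor:
        if extra_channels is None:
            return t
        return concat([t, Tensor(extra_channels[idx])], axis=1)

    all_idx = np.arange(n)
    level0 = PointFeatureSet(0, cloud.points, with_extra(feats["fine"], all_idx), all_idx)
    level1 = PointFeatureSet(1, cloud.points[idx1],
                             with_extra(feats["medium"].gather(idx1), idx1), idx1)
    level2 = PointFeatureSet(2, cloud.points[idx2],
                             with_extra(feats["coarse"].gather(idx2), idx2), idx2)
    return level0, level1, level2
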