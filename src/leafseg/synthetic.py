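"""Procedural potted-plant point clouds with ground-truth labels.

The generator emulates the structure of scanned potted plants: a vertical
stem with K leaves arranged by phyllotaxy (divergence angle 137.5° by
default), each leaf a curved elliptic blade with optional sinusoidal margin
serration.  Sensor effects reproduce the three difficulties real scans show:
leaf-to-leaf occlusion (point-based hidden-surface culling from a viewpoint),
geometric similarity / adhesion (crowded phyllotaxy with near-touching
blades) and non-uniform density (height-dependent thinning plus Gaussian
coordinate noise).

All randomness flows from one integer seed through ``np.random.SeedSequence``
spawning, so per-plant generation is order-independent and reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .cloud import LabeledCloud, LEAF, STEM, orient_normals, write_cloud

__all__ = ["PlantSpec", "make_leaf", "make_plant", "apply_sensor_effects", "make_dataset"]


@dataclass
class PlantSpec:
    """Parameters of one synthetic plant (lengths in meters)."""

    leaf_count: int = 6
    leaf_length_range: Tuple[float, float] = (0.08, 0.14)
    leaf_width_ratio: float = 0.5
    midrib_curl: float = 3.0            # curvature of the midrib, 1/m
    serration_amplitude: float = 0.0    # 0 = smooth margin
    phyllotaxy_angle_deg: float = 137.5
    stem_height: float = 0.30
    stem_radius: float = 0.005
    points_per_leaf: int = 150
    points_on_stem: int = 120
    noise_sigma: float = 0.001
    density_gradient: float = 2.0       # top-to-bottom retained-fraction ratio
    occlusion_viewpoint: Optional[Tuple[float, float, float]] = None
    occlusion_angular_tol_deg: float = 0.35
    occlusion_depth_tol: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.leaf_count < 0:
            raise ValueError("leaf_count must be >= 0")
        if self.density_gradient < 1.0:
            raise ValueError("density_gradient must be >= 1")
        for name in ("stem_height", "stem_radius", "leaf_width_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.leaf_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("leaf_length_range must be positive and ordered")


def make_leaf(spec: PlantSpec, attachment, azimuth: float,
              rng: np.random.Generator, leaf_length: Optional[float] = None):
    """Sample one leaf blade; returns (points, unit normals).

    The blade is an elliptic outline of length L and half-width
    ``leaf_width_ratio * L / 2``, lifted onto a surface drooping along the
    midrib with curvature ``midrib_curl``, margin perturbed sinusoidally by
    ``serration_amplitude``, placed at ``attachment`` with heading
    ``azimuth`` (degrees) and a random downward droop angle.
    """
    if spec.points_per_leaf < 1:
        raise ValueError("points_per_leaf must be >= 1")
    if leaf_length is None:
        leaf_length = float(rng.uniform(*spec.leaf_length_range))
    L = leaf_length
    n = spec.points_per_leaf
    u = rng.random(n)                             # position along midrib, [0, 1]
    v = rng.uniform(-1.0, 1.0, n)                 # transverse fraction
    half_w = 0.5 * spec.leaf_width_ratio * L * np.sqrt(
        np.clip(1.0 - (2.0 * u - 1.0) ** 2, 0.0, None)
    )
    if spec.serration_amplitude > 0:
        half_w = np.clip(half_w + spec.serration_amplitude * np.sin(2 * np.pi * 8 * u), 0.0, None)
    x_l = u * L
    y_l = v * half_w
    z_l = -0.5 * spec.midrib_curl * x_l ** 2      # droop along the midrib
    local = np.column_stack([x_l, y_l, z_l])
    # analytic surface normal of z = -c x^2 / 2: (c x, 0, 1) / |.|
    n_l = np.column_stack([spec.midrib_curl * x_l, np.zeros(n), np.ones(n)])
    n_l /= np.linalg.norm(n_l, axis=1, keepdims=True)

    droop = np.deg2rad(rng.uniform(15.0, 55.0))
    theta = np.deg2rad(azimuth)
    # local frame: midrib heads outward at `azimuth`, tilted down by `droop`
    ex = np.array([np.cos(droop) * np.cos(theta), np.cos(droop) * np.sin(theta), -np.sin(droop)])
    ey = np.array([-np.sin(theta), np.cos(theta), 0.0])
    ez = np.cross(ex, ey)
    R = np.column_stack([ex, ey, ez])
    points = np.asarray(attachment, dtype=np.float64) + local @ R.T
    normals = orient_normals(n_l @ R.T)
    return points, normals


def make_plant(spec: PlantSpec) -> LabeledCloud:
    """Stem cylinder plus K phyllotactic leaves, fully labeled, with normals."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.leaf_count + 1)
    stem_rng = np.random.default_rng(children[0])

    pts, nrm, sem, inst = [], [], [], []
    m = spec.points_on_stem
    if m > 0:
        z = stem_rng.uniform(0.0, spec.stem_height, m)
        phi = stem_rng.uniform(0.0, 2 * np.pi, m)
        pts.append(np.column_stack([
            spec.stem_radius * np.cos(phi), spec.stem_radius * np.sin(phi), z]))
        nrm.append(orient_normals(np.column_stack([np.cos(phi), np.sin(phi), np.zeros(m)])))
        sem.append(np.full(m, STEM, np.int32))
        inst.append(np.full(m, -1, np.int32))

    h = spec.stem_height
    for i in range(spec.leaf_count):
        rng = np.random.default_rng(children[i + 1])
        frac = 0.35 + 0.6 * (i / max(1, spec.leaf_count - 1))
        azimuth = (i * spec.phyllotaxy_angle_deg) % 360.0
        attach = np.array([
            spec.stem_radius * np.cos(np.deg2rad(azimuth)),
            spec.stem_radius * np.sin(np.deg2rad(azimuth)),
            frac * h,
        ])
        p, nv = make_leaf(spec, attach, azimuth, rng)
        pts.append(p)
        nrm.append(nv)
        sem.append(np.full(len(p), LEAF, np.int32))
        inst.append(np.full(len(p), i, np.int32))

    if not pts:
        return LabeledCloud(np.zeros((0, 3)), np.zeros((0, 3)),
                            np.zeros(0, np.int32), np.zeros(0, np.int32))
    return LabeledCloud(np.vstack(pts), np.vstack(nrm),
                        np.concatenate(sem), np.concatenate(inst))


def _occlusion_cull(points: np.ndarray, viewpoint: np.ndarray,
                    angular_tol_deg: float, depth_tol: float) -> np.ndarray:
    """Keep-mask of the point-based hidden-surface approximation.

    Directions from the viewpoint are quantized into an angular grid of cell
    size ``angular_tol_deg``; within each cell only points whose range lies
    within ``depth_tol`` of the cell's minimum range survive.
    """
    rel = points - viewpoint
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0):
        raise ValueError("viewpoint coincides with a point")
    theta = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    cell = np.deg2rad(angular_tol_deg)
    key_t = np.floor(theta / cell).astype(np.int64)
    key_p = np.floor((phi + np.pi) / cell).astype(np.int64)
    key = key_t * 2_000_003 + key_p
    order = np.lexsort((r, key))
    sorted_key = key[order]
    starts = np.flatnonzero(np.r_[True, sorted_key[1:] != sorted_key[:-1]])
    min_r = np.minimum.reduceat(r[order], starts)
    # map each point to its cell's minimum range
    cell_ids = np.cumsum(np.r_[0, sorted_key[1:] != sorted_key[:-1]])
    per_point_min = np.empty(len(points))
    per_point_min[order] = min_r[cell_ids]
    return r <= per_point_min + depth_tol


def apply_sensor_effects(cloud: LabeledCloud, spec: PlantSpec) -> LabeledCloud:
    """Gaussian noise, height-dependent thinning, optional visibility culling."""
    if len(cloud) == 0:
        raise ValueError("cloud is empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(999,)))
    points = cloud.points.copy()
    if spec.noise_sigma > 0:
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)
    keep = np.ones(len(points), dtype=bool)
    if spec.density_gradient > 1.0:
        z = points[:, 2]
        lo, hi = z.min(), z.max()
        t = (z - lo) / (hi - lo) if hi > lo else np.ones_like(z)
        prob = 1.0 / spec.density_gradient + t * (1.0 - 1.0 / spec.density_gradient)
        keep &= rng.random(len(points)) < prob
    if spec.occlusion_viewpoint is not None:
        vp = np.asarray(spec.occlusion_viewpoint, dtype=np.float64)
        vis = _occlusion_cull(points, vp, spec.occlusion_angular_tol_deg,
                              spec.occlusion_depth_tol)
        keep &= vis
    if not keep.any():
        warnings.warn("all points culled by sensor effects", stacklevel=2)
    out = LabeledCloud(
        points[keep],
        None if cloud.normals is None else cloud.normals[keep],
        None if cloud.semantic is None else cloud.semantic[keep],
        None if cloud.instance is None else cloud.instance[keep],
    )
    return out


def _draw_spec(ranges: dict, seed: int, rng: np.random.Generator) -> PlantSpec:
    """One PlantSpec with fields drawn from `ranges` (scalar, (lo, hi) or list)."""
    kwargs = {"seed": seed}
    for name, rng_spec in ranges.items():
        if name == "seed":
            continue
        if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 0:
            raise ValueError(f"empty range for field {name!r}")
        if name == "leaf_count" and isinstance(rng_spec, (list, tuple)):
            lo, hi = int(min(rng_spec)), int(max(rng_spec))
            kwargs[name] = int(rng.integers(lo, hi + 1))
        elif isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 2 \
                and all(isinstance(v, (int, float)) for v in rng_spec) \
                and name not in ("leaf_length_range", "occlusion_viewpoint"):
            kwargs[name] = float(rng.uniform(float(rng_spec[0]), float(rng_spec[1])))
        else:
            kwargs[name] = rng_spec
    return PlantSpec(**kwargs)


def make_dataset(n_plants: int, spec_ranges: Optional[dict] = None, seed: int = 0,
                 out_dir=None, train_fraction: Optional[float] = None,
                 sensor_effects: bool = True):
    """Deterministically generate `n_plants` labeled clouds plus a manifest.

    Returns ``(clouds, manifest)``; the manifest records per-plant seed, the
    drawn spec and (when `out_dir` is given) the ply file written for it.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    spec_ranges = dict(spec_ranges or {})
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_plants)
    clouds: List[LabeledCloud] = []
    entries = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        plant_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _draw_spec(spec_ranges, plant_seed, rng)
        cloud = make_plant(spec)
        if sensor_effects and len(cloud):
            cloud = apply_sensor_effects(cloud, spec)
        clouds.append(cloud)
        entry = {"plant_id": i, "seed": plant_seed, "spec": asdict(spec)}
        if train_fraction is not None:
            entry["split"] = "train" if i < round(train_fraction * n_plants) else "test"
        entries.append(entry)
    manifest = {"seed": seed, "n_plants": n_plants, "plants": entries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for entry, cloud in zip(entries, clouds):
            fname = f"plant_{entry['plant_id']:04d}.ply"
            write_cloud(cloud, out_dir / fname, format="ply")
            entry["file"] = fname
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return clouds, manifest
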