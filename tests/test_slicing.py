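"""Recursive slicing: thickness rules, partitions, termination, encoding."""

import numpy as np
import pytest

from leafseg._autodiff import Tensor
from leafseg.cloud import LabeledCloud
from leafseg.slicing import (SCALES, DegenerateGeometryError, ScaleConfig,
                             SliceEncoder, backtrack_aggregate, choose_direction,
                             compute_scale_thicknesses, encode_tree,
                             farthest_point_sample, recursive_slice, slice_once)
from leafseg.synthetic import PlantSpec, make_plant


def planar_cloud(n=100, z=0.0, rng=None):
    rng = rng or np.random.default_rng(0)
    pts = np.column_stack([rng.normal(size=(n, 2)), np.full(n, z)])
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    return LabeledCloud(pts, normals)


class TestScaleThicknesses:
    def test_coarse_is_fraction_of_height(self, rng):
        pts = rng.uniform(0, 1, size=(300, 3))
        pts[:, 2] *= 1.0
        pts[0, 2], pts[1, 2] = 0.0, 1.0   # pin the extent
        t = compute_scale_thicknesses(LabeledCloud(pts), ScaleConfig(coarse_fraction=0.08))
        assert np.isclose(t["coarse"], 0.08)
        assert 0.05 <= t["coarse"] / 1.0 <= 0.10

    def test_fine_is_multiple_of_grid_spacing(self):
        s = 0.01
        g = np.mgrid[0:10, 0:10, 0:10].reshape(3, -1).T * s
        # coarse/medium widened so the fine <= medium <= coarse clamp is inert
        cfg = ScaleConfig(fine_multiplier=4, coarse_fraction=0.9, medium_thickness=0.05)
        t = compute_scale_thicknesses(LabeledCloud(g), cfg)
        assert np.isclose(t["fine"], 4 * s)

    def test_ordering_fine_le_medium_le_coarse(self, small_plant):
        t = compute_scale_thicknesses(small_plant, ScaleConfig())
        assert t["fine"] <= t["medium"] <= t["coarse"]

    def test_coplanar_cloud_raises_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            compute_scale_thicknesses(planar_cloud(), ScaleConfig())


class TestSliceOnce:
    def test_partition_into_at_most_extent_over_thickness_bins(self, rng):
        pts = rng.uniform(0, 1, size=(500, 3))
        idx = np.arange(500)
        slabs = slice_once(idx, pts, np.array([0.0, 0.0, 1.0]), 0.1)
        assert len(slabs) <= 11
        combined = np.concatenate([s[0] for s in slabs])
        assert sorted(combined.tolist()) == idx.tolist()

    def test_thickness_larger_than_extent_gives_single_slab(self, rng):
        pts = rng.uniform(0, 1, size=(50, 3))
        slabs = slice_once(np.arange(50), pts, np.array([0.0, 0.0, 1.0]), 10.0)
        assert len(slabs) == 1 and len(slabs[0][0]) == 50

    def test_boundary_point_goes_to_upper_bin(self):
        pts = np.array([[0, 0, 0.0], [0, 0, 0.05], [0, 0, 0.1], [0, 0, 0.17]])
        slabs = slice_once(np.arange(4), pts, np.array([0.0, 0.0, 1.0]), 0.1)
        members = [set(s[0].tolist()) for s in slabs]
        assert members == [{0, 1}, {2, 3}]  # z=0.1 exactly on boundary -> upper


class TestChooseDirection:
    def test_collinear_points_give_their_axis(self):
        pts = np.column_stack([np.linspace(0, 1, 30), np.zeros(30), np.zeros(30)])
        assert np.allclose(choose_direction(pts), [1, 0, 0], atol=1e-9)

    def test_anisotropic_plane_gives_long_axis(self, rng):
        pts = np.column_stack([rng.normal(0, 0.1, 200), rng.normal(0, 5.0, 200),
                               np.zeros(200)])
        d = choose_direction(pts)
        assert abs(d[1]) > 0.999
        # sign rule: first nonzero component in (z, x, y) order is positive
        first = next(d[a] for a in (2, 0, 1) if d[a] != 0)
        assert first > 0

    def test_isotropic_cube_is_deterministic_across_runs(self, rng):
        pts = rng.uniform(-1, 1, size=(500, 3))
        a = choose_direction(pts)
        b = choose_direction(pts.copy())
        assert np.array_equal(a, b)
        assert a[2] > 0 or (a[2] == 0 and a[0] > 0)

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            choose_direction(np.zeros((5, 3)))


def assert_partitions(tree):
    """Every node's children partition its points; roots partition the cloud."""
    all_pts = np.concatenate([r.point_indices for r in tree.roots]) \
        if tree.roots else np.zeros(0, int)
    assert sorted(all_pts.tolist()) == list(range(tree.n_points))
    for node in tree.nodes():
        if node.children:
            child_pts = np.concatenate([c.point_indices for c in node.children])
            assert sorted(child_pts.tolist()) == sorted(node.point_indices.tolist())
        else:
            assert node.termination_reason != "none"


class TestRecursiveSlice:
    def test_small_cloud_terminates_at_min_points(self, rng):
        pts = rng.normal(size=(20, 3))
        cloud = LabeledCloud(pts)
        tree = recursive_slice(cloud, "coarse", ScaleConfig(min_points=32))
        for root in tree.roots:
            assert root.termination_reason == "min_points"
            assert not root.children

    def test_max_depth_zero_caps_tree(self, small_plant):
        tree = recursive_slice(small_plant, "fine", ScaleConfig(max_depth=0, min_points=1,
                                                                normal_var_threshold=0.0))
        assert tree.max_depth() == 0

    def test_planar_slab_terminates_with_simplicity(self):
        cloud = planar_cloud(n=200)
        # bypass thickness computation (coplanar): slice along x instead
        tree = recursive_slice(cloud, "coarse", ScaleConfig(min_points=10), thickness=1.0)
        reasons = {r.termination_reason for r in tree.roots}
        assert reasons == {"simplicity"}

    def test_partition_invariant_on_plants(self):
        for seed in range(3):
            cloud = make_plant(PlantSpec(leaf_count=4, seed=seed, points_per_leaf=80,
                                         points_on_stem=60))
            for scale in SCALES:
                tree = recursive_slice(cloud, scale, ScaleConfig())
                assert_partitions(tree)

    def test_empty_cloud_gives_empty_tree(self):
        cloud = LabeledCloud(np.zeros((0, 3)))
        tree = recursive_slice(cloud, "fine", ScaleConfig())
        assert tree.roots == [] and tree.n_points == 0

    def test_tree_serializes_to_json(self, small_plant):
        import json

        tree = recursive_slice(small_plant, "coarse", ScaleConfig())
        data = json.loads(tree.to_json())
        assert data["n_points"] == len(small_plant)
        assert len(data["roots"]) == len(tree.roots)


class TestSliceEncoder:
    def test_permutation_invariance_is_bitwise(self, rng):
        enc = SliceEncoder(16, rng)
        pts = rng.normal(size=(40, 3))
        normals = rng.normal(size=(40, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        perm = rng.permutation(40)
        a = enc(pts, normals).data
        b = enc(pts[perm], normals[perm]).data
        assert np.array_equal(a, b)

    def test_duplicated_point_equals_single_point(self, rng):
        enc = SliceEncoder(16, rng)
        p = rng.normal(size=(1, 3))
        nrm = np.array([[0.0, 0.0, 1.0]])
        single = enc(p, nrm).data
        dup = enc(np.repeat(p, 7, axis=0), np.repeat(nrm, 7, axis=0)).data
        assert np.allclose(single, dup, atol=1e-12)

    def test_output_length_is_d_slice(self, rng):
        for d in (8, 32):
            enc = SliceEncoder(d, rng)
            out = enc(rng.normal(size=(15, 3)), np.tile([0, 0, 1.0], (15, 1)))
            assert out.shape == (d,)


@pytest.fixture(scope="module")
def setup():
    cloud = make_plant(PlantSpec(leaf_count=3, seed=5, points_per_leaf=90,
                                 points_on_stem=60))
    cfg = ScaleConfig()
    rng = np.random.default_rng(8)
    trees = {s: recursive_slice(cloud, s, cfg) for s in SCALES}
    encoders = {s: SliceEncoder(8, rng) for s in SCALES}
    return cloud, cfg, trees, encoders


class TestBacktrackAggregate:

    def test_levels_have_expected_shapes(self, setup):
        cloud, cfg, trees, encoders = setup
        l0, l1, l2 = backtrack_aggregate(cloud, trees, encoders, cfg)
        n = len(cloud)
        width = (cfg.max_depth + 1) * 8
        assert l0.data.shape == (n, width)
        assert l1.data.shape[0] == round(0.25 * n)
        assert l2.data.shape[0] == round(0.0625 * n)

    def test_max_depth_zero_gives_single_slot(self):
        cloud = make_plant(PlantSpec(leaf_count=2, seed=1, points_per_leaf=60,
                                     points_on_stem=40))
        cfg = ScaleConfig(max_depth=0)
        rng = np.random.default_rng(3)
        tree = recursive_slice(cloud, "coarse", cfg)
        feats = encode_tree(cloud, tree, SliceEncoder(8, rng), pad_depth=0)
        assert feats.shape == (len(cloud), 8)

    def test_points_in_same_leaf_node_share_fine_features(self, setup):
        cloud, cfg, trees, encoders = setup
        l0, _, _ = backtrack_aggregate(cloud, trees, encoders, cfg)
        leaves = [n for n in trees["fine"].nodes() if not n.children]
        node = max(leaves, key=lambda n: len(n.point_indices))
        feats = l0.data[node.point_indices]
        assert np.allclose(feats, feats[0], atol=1e-12)

    def test_coarse_features_separate_two_distant_blobs(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        a = rng.normal(0, 0.05, size=(150, 3)) + [0, 0, 0.2]
        b = rng.normal(0, 0.05, size=(150, 3)) + [0, 0, 1.2]
        pts = np.vstack([a, b])
        normals = rng.normal(size=(300, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = LabeledCloud(pts, normals)
        cfg = ScaleConfig()
        tree = recursive_slice(cloud, "coarse", cfg)
        feats = encode_tree(cloud, tree, SliceEncoder(8, rng), cfg.max_depth).data
        labels = KMeans(n_clusters=2, n_init=3, random_state=0).fit_predict(feats)
        assert silhouette_score(feats, labels) > 0


def test_farthest_point_sample_is_deterministic_and_spread(rng):
    pts = rng.normal(size=(200, 3))
    a = farthest_point_sample(pts, 20)
    b = farthest_point_sample(pts, 20)
    assert np.array_equal(a, b)
    assert len(set(a.tolist())) == 20
    # FPS min pairwise distance beats random subsets
    from scipy.spatial.distance import pdist

    fps_min = pdist(pts[a]).min()
    rand_min = np.median([pdist(pts[rng.choice(200, 20, replace=False)]).min()
                          for _ in range(10)])
    assert fps_min > rand_min
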