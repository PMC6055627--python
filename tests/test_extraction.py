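"""Network extraction: cube tiling, Pearson similarity, permutation
threshold calibration, binarization."""

import numpy as np
import pytest

from gmnet import (
    GreyMatterVolume,
    SimilarityMatrix,
    binarize,
    compute_similarity,
    extract_network,
    partition_cubes,
    permutation_threshold,
)
from gmnet.extract import NodeSet, load_network, save_network
from gmnet.synthetic import VolumeSpec, generate_gm_volume


def _volume(data):
    return GreyMatterVolume(data=np.asarray(data, dtype=float))


def _nodes_from_rows(*rows):
    rows = np.asarray(rows, dtype=float)
    coords = np.column_stack([np.arange(len(rows)) * 3, np.zeros(len(rows)), np.zeros(len(rows))])
    return NodeSet(coords, rows, volume_shape=(3 * len(rows), 3, 3))


class TestPartition:
    def test_exact_tiling_6cube(self):
        nodes = partition_cubes(_volume(np.full((6, 6, 6), 0.5)))
        assert nodes.n_nodes == 8

    def test_partial_slabs_dropped(self):
        nodes = partition_cubes(_volume(np.full((7, 7, 7), 0.5)))
        assert nodes.n_nodes == 8

    def test_all_zero_volume_yields_no_nodes_and_downstream_refuses(self):
        nodes = partition_cubes(_volume(np.zeros((6, 6, 6))))
        assert nodes.n_nodes == 0
        with pytest.raises(ValueError):
            compute_similarity(nodes)
        with pytest.raises(ValueError):
            extract_network(_volume(np.zeros((6, 6, 6))))

    def test_volume_smaller_than_cube_rejected(self):
        with pytest.raises(ValueError):
            partition_cubes(_volume(np.full((2, 6, 6), 0.5)))

    def test_min_gm_fraction_filters_cubes(self):
        data = np.zeros((6, 3, 3))
        data[:3] = 0.8
        data[3:] = 0.1
        assert partition_cubes(_volume(data), min_gm_fraction=0.5).n_nodes == 1
        assert partition_cubes(_volume(data)).n_nodes == 2

    def test_node_order_lexicographic_in_zyx(self):
        nodes = partition_cubes(_volume(np.full((6, 6, 6), 0.5)))
        coords = nodes.cube_index_coords
        keys = [tuple(c[::-1]) for c in coords]  # (z, y, x)
        assert keys == sorted(keys)


class TestSimilarity:
    def test_identical_cubes_correlate_one(self):
        v = np.random.default_rng(0).random(27)
        sim = compute_similarity(_nodes_from_rows(v, v))
        assert sim.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_affine_negated_cube_correlates_minus_one(self):
        v = np.random.default_rng(1).random(27)
        sim = compute_similarity(_nodes_from_rows(v, 1.0 - v))
        assert sim.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        """Fixed 27-vectors against the explicit sum-formula Pearson r."""
        a = np.linspace(0.1, 0.9, 27) ** 2
        b = np.sqrt(np.linspace(0.05, 0.95, 27))[::-1]
        n = 27
        num = n * (a * b).sum() - a.sum() * b.sum()
        den = np.sqrt(n * (a * a).sum() - a.sum() ** 2) * np.sqrt(
            n * (b * b).sum() - b.sum() ** 2
        )
        sim = compute_similarity(_nodes_from_rows(a, b))
        assert sim.values[0, 1] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_cube_warns_and_gets_zero(self):
        v = np.random.default_rng(2).random(27)
        with pytest.warns(UserWarning, match="zero intensity variance"):
            sim = compute_similarity(_nodes_from_rows(v, np.full(27, 0.3)))
        assert sim.values[0, 1] == 0.0

    def test_fewer_than_two_nodes_rejected(self):
        with pytest.raises(ValueError):
            compute_similarity(_nodes_from_rows(np.random.default_rng(3).random(27)))

    def test_rotation_maximization_recovers_rotated_cube(self):
        rng = np.random.default_rng(4)
        cube = rng.random((3, 3, 3))
        rotated = np.flip(np.transpose(cube, (1, 0, 2)), axis=0)
        nodes = _nodes_from_rows(cube.ravel(), rotated.ravel())
        plain = compute_similarity(nodes).values[0, 1]
        maxed = compute_similarity(nodes, maximize_over_rotations=True).values[0, 1]
        assert maxed == pytest.approx(1.0, abs=1e-12)
        assert plain < 0.999

    def test_symmetry_on_random_nodesets(self):
        rng = np.random.default_rng(5)
        nodes = _nodes_from_rows(*rng.random((10, 27)))
        for flag in (False, True):
            s = compute_similarity(nodes, maximize_over_rotations=flag).values
            assert np.allclose(s, s.T, atol=1e-12)


class TestThreshold:
    def test_pure_noise_flagged_near_empty(self):
        vol, _ = generate_gm_volume(VolumeSpec(n_latents=0, seed=21))
        nodes = partition_cubes(vol)
        sim = compute_similarity(nodes)
        with pytest.warns(UserWarning, match="flagged"):
            thr = permutation_threshold(sim, nodes, n_permutations=200, seed=1)
        assert thr.flagged_empty
        assert binarize(sim, thr.cutoff).n_edges <= 2

    def test_degenerate_rate_one_returns_null_minimum(self):
        vol, _ = generate_gm_volume(VolumeSpec(seed=22))
        nodes = partition_cubes(vol)
        sim = compute_similarity(nodes)
        thr = permutation_threshold(sim, nodes, spurious_rate=1.0, n_permutations=200, seed=2)
        assert thr.cutoff == pytest.approx(thr.null_min)

    def test_planted_pairs_survive_with_few_spurious(self):
        frac = []
        for seed in range(8):
            vol, truth = generate_gm_volume(
                VolumeSpec(latent_loading=0.9, noise_sd=0.1, seed=100 + seed)
            )
            res = extract_network(vol, n_permutations=300, seed=seed)
            coord = {tuple(c): i for i, c in enumerate(res.nodes.cube_index_coords)}
            designated = {
                tuple(sorted((coord[tuple(a)], coord[tuple(b)])))
                for a, b in truth["designated_pairs"]
            }
            adj = res.network.adjacency
            kept = {tuple(sorted(e)) for e in zip(*np.nonzero(np.triu(adj)))}
            assert designated <= kept  # every planted connection survives
            frac.append(len(kept - designated) / max(len(kept), 1))
        assert np.mean(frac) <= 0.065  # 5% target + Monte-Carlo slack

    def test_parameter_validation(self):
        vol, _ = generate_gm_volume(VolumeSpec(seed=23))
        nodes = partition_cubes(vol)
        sim = compute_similarity(nodes)
        with pytest.raises(ValueError):
            permutation_threshold(sim, nodes, spurious_rate=0.0)
        with pytest.raises(ValueError):
            permutation_threshold(sim, nodes, n_permutations=50)

    def test_threshold_deterministic_under_seed(self):
        vol, _ = generate_gm_volume(VolumeSpec(seed=24))
        nodes = partition_cubes(vol)
        sim = compute_similarity(nodes)
        t1 = permutation_threshold(sim, nodes, n_permutations=150, seed=9)
        t2 = permutation_threshold(sim, nodes, n_permutations=150, seed=9)
        assert t1.cutoff == t2.cutoff


class TestBinarize:
    def test_cutoff_above_max_gives_empty_graph(self):
        rng = np.random.default_rng(6)
        sim = compute_similarity(_nodes_from_rows(*rng.random((6, 27))))
        assert binarize(sim, 1.0).n_edges == 0

    def test_cutoff_minus_one_gives_complete_graph(self):
        rng = np.random.default_rng(7)
        sim = compute_similarity(_nodes_from_rows(*rng.random((8, 27))))
        assert binarize(sim, -1.0).n_edges == 28

    def test_edges_monotone_nonincreasing_in_cutoff(self):
        rng = np.random.default_rng(8)
        sim = compute_similarity(_nodes_from_rows(*rng.random((12, 27))))
        edges = [binarize(sim, c).n_edges for c in np.linspace(-1, 1, 21)]
        assert edges == sorted(edges, reverse=True)

    def test_non_finite_cutoff_rejected(self):
        sim = SimilarityMatrix(np.eye(3))
        with pytest.raises(ValueError):
            binarize(sim, float("nan"))


class TestInvariances:
    def test_axis_relabeling_preserves_degree_sequence(self):
        """Consistently transposing the voxel grid permutes nodes but leaves
        the sorted degree sequence unchanged (fixed cutoff binarization)."""
        vol, _ = generate_gm_volume(VolumeSpec(seed=31))
        cutoff = 0.5
        nets = []
        for perm in [(0, 1, 2), (2, 0, 1)]:
            v = GreyMatterVolume(data=np.transpose(vol.data, perm))
            nodes = partition_cubes(v)
            nets.append(binarize(compute_similarity(nodes), cutoff))
        d1, d2 = (sorted(n.degrees()) for n in nets)
        assert d1 == d2

    def test_network_roundtrip_matrix_market(self, tmp_path):
        vol, _ = generate_gm_volume(VolumeSpec(seed=32))
        res = extract_network(vol, n_permutations=150, seed=3)
        adj_p = tmp_path / "net.mtx"
        coo_p = tmp_path / "nodes.tsv"
        save_network(res.network, adj_p, coo_p)
        loaded = load_network(adj_p, coo_p)
        assert np.array_equal(loaded.adjacency, res.network.adjacency)
        assert np.array_equal(loaded.cube_index_coords, res.nodes.cube_index_coords)
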