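"""Contact mesh, PCA correctness, free-energy landscape, OPTICS clustering."""

from __future__ import annotations

import numpy as np
import pytest

from loopscape.ccpca import (
    FeatureMatrix,
    build_contact_mesh,
    cluster_scores,
    cluster_state_summary,
    compute_features,
    default_min_samples,
    fit_pca,
    free_energy_landscape,
)
from loopscape.contact_analysis import FrameFilter
from loopscape.errors import InputError
from loopscape.loop_state import DistanceTrace
from loopscape.presets import GAS_CONSTANT_KJ

from conftest import make_ensemble, make_topology


def grid_chain_atoms(chain, n_res, atoms_per_res=1, element="C"):
    return [
        (chain, r + 1, element, f"{element}{a + 1}")
        for r in range(n_res)
        for a in range(atoms_per_res)
    ]


class TestMesh:
    def test_stride_rule_on_10_and_25_atoms(self):
        top = make_topology(grid_chain_atoms("A", 10) + grid_chain_atoms("B", 25))
        mesh = build_contact_mesh(top, "A", "B")
        assert mesh.m == 10
        # larger chain: stride floor(25/10)=2, ordinals 0,2,...,18
        assert list(mesh.mesh_b) == [10 + 2 * k for k in range(10)]
        assert mesh.n_pairs == 100

    def test_equal_chains_fully_included(self):
        top = make_topology(grid_chain_atoms("A", 7) + grid_chain_atoms("B", 7))
        mesh = build_contact_mesh(top, "A", "B")
        assert list(mesh.mesh_a) == list(range(7))
        assert list(mesh.mesh_b) == list(range(7, 14))
        assert mesh.n_pairs == 49

    def test_cap_subsamples_reproducibly(self):
        top = make_topology(grid_chain_atoms("A", 10) + grid_chain_atoms("B", 10))
        m1 = build_contact_mesh(top, "A", "B", cap=50, seed=3)
        m2 = build_contact_mesh(top, "A", "B", cap=50, seed=3)
        assert m1.n_pairs == 50
        assert len({tuple(p) for p in m1.pair_list}) == 50
        np.testing.assert_array_equal(m1.pair_list, m2.pair_list)

    def test_hydrogens_excluded_from_mesh(self):
        top = make_topology(
            grid_chain_atoms("A", 4) + grid_chain_atoms("B", 4, element="H")
        )
        with pytest.raises(InputError):
            build_contact_mesh(top, "A", "B")


class TestFeatures:
    def test_shape_and_345_distance(self):
        atoms = grid_chain_atoms("A", 1) + grid_chain_atoms("B", 1)
        ens = make_ensemble(atoms, [[[0, 0, 0], [3, 4, 0]]])
        mesh = build_contact_mesh(ens.topology, "A", "B")
        features = compute_features(ens, mesh)
        assert features.shape == (1, 1)
        assert features.values[0, 0] == pytest.approx(5.0)

    def test_random_probes_match_brute_force(self):
        rng = np.random.default_rng(8)
        atoms = grid_chain_atoms("A", 6) + grid_chain_atoms("B", 9)
        coords = rng.uniform(0, 15, size=(5, 15, 3))
        ens = make_ensemble(atoms, coords)
        mesh = build_contact_mesh(ens.topology, "A", "B")
        features = compute_features(ens, mesh)
        for _ in range(10):
            f = rng.integers(5)
            p = rng.integers(mesh.n_pairs)
            i = mesh.mesh_a[mesh.pair_list[p, 0]]
            j = mesh.mesh_b[mesh.pair_list[p, 1]]
            expected = np.linalg.norm(coords[f, i] - coords[f, j])
            assert features.values[f, p] == pytest.approx(expected, abs=1e-12)

    def test_filter_restricts_rows(self):
        atoms = grid_chain_atoms("A", 2) + grid_chain_atoms("B", 2)
        ens = make_ensemble(atoms, np.zeros((4, 4, 3)) + np.arange(4)[:, None, None])
        mesh = build_contact_mesh(ens.topology, "A", "B")
        keep = FrameFilter(keep=np.array([True, False, True, False]), rule="test")
        features = compute_features(ens, mesh, keep)
        assert features.shape[0] == 2
        assert list(features.frame_ids) == [1, 3]


class TestPCA:
    def test_collinear_data_is_rank_one(self):
        x = np.linspace(0, 9, 10)
        features = FeatureMatrix(
            values=np.column_stack([x, 2 * x]), frame_ids=np.arange(10)
        )
        model = fit_pca(features, n_components=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_mean_row_scores_at_origin(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 10, size=(12, 4))
        col_mean = X.mean(axis=0)
        features = FeatureMatrix(values=X, frame_ids=np.arange(12))
        model = fit_pca(features, n_components=2)
        score_of_mean = (col_mean - model.mean) @ model.components.T
        np.testing.assert_allclose(score_of_mean, 0.0, atol=1e-10)

    def test_components_match_covariance_eigenvectors(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(20, 6)) @ rng.normal(size=(6, 6))
        features = FeatureMatrix(values=np.abs(X) + 5, frame_ids=np.arange(20))
        model = fit_pca(features, n_components=2)
        cov = np.cov(features.values, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(model.explained_variance_all, evals, atol=1e-8)
        for k in range(2):
            dot = abs(np.dot(model.components[k], evecs[:, k]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_full_reconstruction_and_variance_budget(self):
        rng = np.random.default_rng(21)
        X = rng.uniform(0, 30, size=(15, 7))
        features = FeatureMatrix(values=X, frame_ids=np.arange(15))
        model = fit_pca(features, n_components=2)
        Xc = X - model.mean
        scores_all = Xc @ model.components_all.T
        recon = scores_all @ model.components_all
        rel_err = np.linalg.norm(recon - Xc) / np.linalg.norm(Xc)
        assert rel_err < 1e-6
        total_var = Xc.var(axis=0, ddof=1).sum()
        assert model.explained_variance_all.sum() == pytest.approx(
            total_var, rel=1e-6
        )

    def test_zero_variance_columns_dropped_and_recorded(self):
        rng = np.random.default_rng(22)
        X = rng.uniform(0, 5, size=(10, 4))
        X[:, 2] = 7.0
        features = FeatureMatrix(values=X, frame_ids=np.arange(10))
        model = fit_pca(features, n_components=2)
        assert list(model.dropped_columns) == [2]
        assert np.all(model.components[:, 2] == 0.0)

    def test_single_frame_rejected(self):
        features = FeatureMatrix(values=np.ones((1, 3)), frame_ids=np.array([1]))
        with pytest.raises(InputError):
            fit_pca(features)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(30, 5)) + 10
        model = fit_pca(FeatureMatrix(values=X, frame_ids=np.arange(30)), 2)
        for comp in model.components_all:
            assert comp[np.argmax(np.abs(comp))] >= 0


class TestLandscape:
    def test_modal_bin_is_zero_and_half_probability_is_rt_ln2(self):
        # 2 points in one bin, 1 in another: P ratio 1/2
        scores = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]])
        land = free_energy_landscape(scores, bins=2, temperature=300.0)
        occupied = land.delta_g[~land.empty_mask]
        assert occupied.min() == 0.0
        expected = GAS_CONSTANT_KJ * 300.0 * np.log(2.0)
        assert expected == pytest.approx(1.7288, abs=2e-4)
        assert occupied.max() == pytest.approx(expected, abs=1e-12)

    def test_inverse_transform_reproduces_probability(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=(500, 2))
        land = free_energy_landscape(scores, bins=20)
        occupied = ~land.empty_mask
        rt = land.gas_constant * land.temperature
        p = np.exp(-land.delta_g[occupied] / rt)
        p = p / p.sum() * land.probability[occupied].sum()
        np.testing.assert_allclose(p, land.probability[occupied], atol=1e-12)

    def test_degenerate_identical_scores(self):
        scores = np.tile([[2.0, 3.0]], (50, 1))
        land = free_energy_landscape(scores, bins=10)
        occupied = ~land.empty_mask
        assert occupied.sum() == 1
        assert land.delta_g[occupied][0] == 0.0

    def test_probability_sums_to_one(self):
        rng = np.random.default_rng(32)
        land = free_energy_landscape(rng.normal(size=(200, 2)))
        assert land.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_larger_basin_has_lower_energy(self):
        rng = np.random.default_rng(33)
        big = rng.normal(0.0, 0.3, size=(400, 2))
        small = rng.normal(8.0, 0.3, size=(100, 2))
        land = free_energy_landscape(np.vstack([big, small]), bins=10)
        centers1, _ = land.bin_centers
        big_bins = centers1 < 4
        g_big = np.nanmin(land.delta_g[big_bins, :])
        g_small = np.nanmin(land.delta_g[~big_bins, :])
        assert g_big < g_small

    def test_non_finite_scores_rejected(self):
        with pytest.raises(InputError):
            free_energy_landscape(np.array([[np.nan, 0.0]]))


class TestClustering:
    def test_two_blobs_recovered_with_high_purity(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0.0, 0.5, size=(500, 2))
        blob2 = rng.normal([10.0, 0.0], 0.5, size=(500, 2))
        scores = np.vstack([blob1, blob2])
        truth = np.repeat([0, 1], 500)
        result = cluster_scores(scores, min_samples=default_min_samples(1000))
        assert result.n_clusters == 2
        for _cid, members, rep in result.clusters:
            vals, counts = np.unique(truth[members], return_counts=True)
            assert counts.max() / counts.sum() >= 0.99
            assert rep in members

    def test_single_blob_is_one_cluster(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 0.5, size=(600, 2))
        result = cluster_scores(scores, min_samples=default_min_samples(600))
        assert result.n_clusters == 1
        assert len(result.clusters[0][1]) >= 0.9 * 600

    def test_too_few_frames_rejected(self):
        with pytest.raises(InputError):
            cluster_scores(np.zeros((5, 2)), min_samples=10)

    def test_clusters_sorted_by_descending_size(self):
        rng = np.random.default_rng(6)
        scores = np.vstack(
            [
                rng.normal(0, 0.4, size=(300, 2)),
                rng.normal([8, 0], 0.4, size=(100, 2)),
            ]
        )
        result = cluster_scores(scores, min_samples=20)
        sizes = [len(m) for _c, m, _r in result.clusters]
        assert sizes == sorted(sizes, reverse=True)

    def test_representative_is_nearest_to_centroid(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 1.0, size=(200, 2))
        result = cluster_scores(scores, min_samples=20)
        for _cid, members, rep in result.clusters:
            centroid = scores[members].mean(axis=0)
            dists = np.linalg.norm(scores[members] - centroid, axis=1)
            assert np.linalg.norm(scores[rep] - centroid) == pytest.approx(
                dists.min()
            )


class TestPlantedPoseRecovery:
    @pytest.mark.parametrize("k,occupancies,seed", [(2, (0.7, 0.3), 7), (3, (0.5, 0.3, 0.2), 11)])
    def test_ccpca_recovers_planted_poses(self, k, occupancies, seed):
        """Full ccPCA + OPTICS on a K-pose ensemble finds exactly K pure clusters."""
        from loopscape.synthetic import SyntheticSpec, generate_binding_ensemble

        offsets = tuple(
            (-24.0, 10.0 * ((p + 1) // 2) * (-1) ** p, 0.0) for p in range(k)
        )
        spec = SyntheticSpec(
            n_frames=1000 if k == 2 else 1200,
            n_poses=k,
            pose_occupancies=occupancies,
            pose_offsets=offsets,
            bound_pose_contact_target=(0,),
            pose_open_fractions=tuple(0.0 for _ in range(k)),
            seed=seed,
        )
        ens, truth = generate_binding_ensemble(spec)
        mesh = build_contact_mesh(ens.topology, "E", "I")
        model = fit_pca(compute_features(ens, mesh), 2)
        result = cluster_scores(
            model.scores, min_samples=default_min_samples(len(model.scores))
        )
        assert result.n_clusters == k
        for _cid, members, _rep in result.clusters:
            vals, counts = np.unique(truth.pose_labels[members], return_counts=True)
            assert counts.max() / counts.sum() >= 0.95


class TestClusterSummary:
    def test_hand_computed_summary(self):
        labels = np.array([0, 0, 1, 1, 1, -1])
        from loopscape.ccpca import ClusterResult

        result = ClusterResult(
            labels=labels,
            clusters=[
                (0, np.array([0, 1]), 0),
                (1, np.array([2, 3, 4]), 2),
            ],
            optics_min_samples=2,
            optics_xi=0.1,
        )
        trace = DistanceTrace(
            values=np.array([17.0, 18.0, 12.0, 13.0, 14.0, 50.0]),
            frame_ids=np.arange(1, 7),
            group_a_label="loop",
            group_b_label="site",
        )
        summary = cluster_state_summary(result, trace, threshold=16.5)
        assert summary.mean_distance[0] == pytest.approx(17.5)
        assert summary.sd_distance[0] == pytest.approx(np.std([17, 18], ddof=1))
        assert summary.open_fraction[0] == 1.0
        assert summary.open_fraction[1] == 0.0
        assert summary.member_count.sum() == 5

    def test_misaligned_trace_rejected(self):
        from loopscape.ccpca import ClusterResult

        result = ClusterResult(
            labels=np.array([0, 0]),
            clusters=[(0, np.array([0, 1]), 0)],
            optics_min_samples=2,
            optics_xi=0.1,
        )
        trace = DistanceTrace(
            values=np.array([1.0]),
            frame_ids=np.array([1]),
            group_a_label="a",
            group_b_label="b",
        )
        with pytest.raises(InputError):
            cluster_state_summary(result, trace, 16.5)
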