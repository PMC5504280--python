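"""Feature assembly, data-driven initialization, and the combined k-means."""

import numpy as np
import pytest

from thalparc import cluster, phantom, pipeline
from thalparc.cluster import ClusterConfig, FeatureMatrix
from thalparc.io import VolumeMask


def _blob_features(rng, k=7, per_blob=40, spread=1.0, sep=30.0):
    """k well-separated Gaussian blobs on a synthetic grid."""
    centers = rng.normal(size=(k, 3)) * sep
    pos = np.concatenate(
        [c + rng.normal(scale=spread, size=(per_blob, 3)) for c in centers])
    idx = np.arange(len(pos))[:, None] * np.array([1, 0, 0])
    feats = FeatureMatrix(positions=pos, odf=np.zeros((len(pos), 2)),
                          voxel_index=idx.astype(int))
    return feats, centers


def _grid_mask_for(features):
    n = features.n_voxels
    grid = np.zeros((n, 1, 1), dtype=bool)
    grid[features.voxel_index[:, 0], 0, 0] = True
    return VolumeMask(grid=grid, voxel_size=np.ones(3))


class TestExtractFeatures:
    def test_odf_block_scaled_by_s_odf(self, rng):
        grid = np.zeros((4, 4, 4), dtype=bool)
        grid[1:3, 1:3, 1:3] = True
        mask = VolumeMask(grid=grid, voxel_size=np.array([2.0, 2.0, 2.5]))
        field = rng.normal(size=(4, 4, 4, 5))
        cfg = ClusterConfig(s_odf=55.0)
        feats = cluster.extract_features(field, mask, cfg)
        np.testing.assert_allclose(feats.odf, 55.0 * field[grid])
        # positions are voxel centers through the affine
        np.testing.assert_allclose(
            feats.positions[0], np.array([1, 1, 1]) * [2.0, 2.0, 2.5])

    def test_nan_coefficients_rejected(self):
        grid = np.ones((2, 2, 2), dtype=bool)
        mask = VolumeMask(grid=grid, voxel_size=np.ones(3))
        field = np.zeros((2, 2, 2, 3))
        field[0, 0, 0, 1] = np.nan
        with pytest.raises(ValueError, match="voxels"):
            cluster.extract_features(field, mask, ClusterConfig())

    def test_scaled_odf_distances_inside_spatial_range(self, clean_phantom):
        """S_ODF = 55 places ODF distances within the spatial interval."""
        from scipy.spatial.distance import pdist

        spec, dwi, mask, _, _ = clean_phantom
        cfg = pipeline.PipelineConfig(do_refine=False)
        cfg.bootstrap.n_samples = 5
        field = pipeline.odf_field(dwi, spec.scheme, mask, cfg)
        feats = cluster.extract_features(field, mask, cfg.cluster)
        rng = np.random.default_rng(0)
        sub = rng.choice(feats.n_voxels, 300, replace=False)
        d_pos = pdist(feats.positions[sub])
        d_odf = pdist(feats.odf[sub])
        assert d_pos.min() <= np.median(d_odf) <= d_pos.max()


class TestInitCentroids:
    def test_k1_is_mean_position(self, rng):
        feats, _ = _blob_features(rng, k=3)
        cfg = ClusterConfig(k=1, n_init_runs=5, seed=0)
        init = cluster.init_centroids(feats, cfg)
        np.testing.assert_allclose(init[0, :3], feats.positions.mean(axis=0),
                                   atol=1e-8)

    def test_seed_determinism(self, rng):
        feats, _ = _blob_features(rng)
        cfg = ClusterConfig(k=7, n_init_runs=10, seed=4)
        a = cluster.init_centroids(feats, cfg)
        b = cluster.init_centroids(feats, cfg)
        np.testing.assert_array_equal(a, b)

    def test_recovers_well_separated_blob_centers(self, rng):
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        feats, centers = _blob_features(rng, k=7, spread=0.5, sep=40.0)
        cfg = ClusterConfig(k=7, n_init_runs=30, seed=0)
        init = cluster.init_centroids(feats, cfg)
        cost = cdist(init[:, :3], centers)
        row, col = linear_sum_assignment(cost)
        assert cost[row, col].max() < 2.0  # within one voxel-ish of truth

    def test_k_exceeding_voxels_rejected(self, rng):
        feats, _ = _blob_features(rng, k=2, per_blob=3)
        with pytest.raises(ValueError):
            cluster.init_centroids(feats, ClusterConfig(k=100))


class TestKMeansCombined:
    def test_alpha_one_equals_position_only(self, rng):
        """With alpha = 1 the ODF block cannot influence the labels."""
        feats, _ = _blob_features(rng)
        feats.odf = rng.normal(size=(feats.n_voxels, 2)) * 100
        mask = _grid_mask_for(feats)
        init = cluster.init_centroids(feats, ClusterConfig(k=7, n_init_runs=5,
                                                           seed=0))
        cfg1 = ClusterConfig(k=7, alpha=1.0, seed=0)
        lab1 = cluster.kmeans_combined(feats, init, cfg1, mask)
        # position-only reference: zero out the ODF block entirely
        feats0 = FeatureMatrix(positions=feats.positions,
                               odf=np.zeros_like(feats.odf),
                               voxel_index=feats.voxel_index)
        init0 = init.copy()
        init0[:, 3:] = 0.0
        lab0 = cluster.kmeans_combined(feats0, init0, cfg1, mask)
        np.testing.assert_array_equal(lab1.labels, lab0.labels)

    def test_seven_nonempty_labels_on_phantom(self, clean_phantom):
        spec, dwi, mask, _, _ = clean_phantom
        cfg = pipeline.PipelineConfig(do_refine=False)
        cfg.cluster.n_init_runs = 50
        cfg.bootstrap.n_samples = 5
        lab, _ = pipeline.run_pipeline(dwi, spec.scheme, mask, None, cfg)
        sizes = [np.count_nonzero(lab.labels == i) for i in range(1, 8)]
        assert all(s > 0 for s in sizes)
        assert sum(sizes) == mask.n_voxels

    def test_recovers_phantom_regions(self, clean_phantom):
        """Combined clustering recovers the generative partition at SNR 30."""
        from sklearn.metrics import adjusted_rand_score

        spec, dwi, mask, _, truth = clean_phantom
        cfg = pipeline.PipelineConfig(do_refine=False)
        cfg.cluster.n_init_runs = 200
        lab, _ = pipeline.run_pipeline(dwi, spec.scheme, mask, None, cfg)
        ari = adjusted_rand_score(truth[mask.grid], lab.labels[mask.grid])
        assert ari >= 0.9

    def test_permutation_invariance(self, rng):
        """Shuffling voxel order leaves the deterministic labeling unchanged."""
        feats, _ = _blob_features(rng)
        mask = _grid_mask_for(feats)
        init = cluster.init_centroids(feats, ClusterConfig(k=7, n_init_runs=5,
                                                           seed=0))
        cfg = ClusterConfig(k=7, seed=0)
        lab = cluster.kmeans_combined(feats, init, cfg, mask)
        perm = rng.permutation(feats.n_voxels)
        feats_p = FeatureMatrix(positions=feats.positions[perm],
                                odf=feats.odf[perm],
                                voxel_index=feats.voxel_index[perm])
        lab_p = cluster.kmeans_combined(feats_p, init, cfg, mask)
        np.testing.assert_array_equal(lab.labels, lab_p.labels)

    def test_end_to_end_seeded_determinism(self, clean_phantom):
        spec, dwi, mask, _, _ = clean_phantom
        cfg = pipeline.PipelineConfig(do_refine=False)
        cfg.cluster.n_init_runs = 20
        cfg.bootstrap.n_samples = 10
        a, _ = pipeline.run_pipeline(dwi, spec.scheme, mask, None, cfg)
        b, _ = pipeline.run_pipeline(dwi, spec.scheme, mask, None, cfg)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAngularDifference:
    @pytest.mark.parametrize("v1,v2,expected", [
        ([1, 0, 0], [1, 0, 0], 0.0),
        ([1, 0, 0], [-1, 0, 0], 0.0),       # antipodal symmetry
        ([1, 0, 0], [0, 1, 0], np.pi / 2),
        ([1, 0, 0], [1, 1, 0], np.pi / 4),
    ])
    def test_values(self, v1, v2, expected):
        v2 = np.asarray(v2, dtype=float)
        v2 /= np.linalg.norm(v2)
        assert cluster.angular_difference(np.asarray(v1, dtype=float), v2) \
            == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cluster.angular_difference(np.zeros(3), np.array([1.0, 0, 0]))


class TestKMeansAD:
    def test_dyadic_mean_of_antipodal_pair(self):
        """The dyadic average of {+v, -v} is +-v; a plain mean would vanish."""
        v = np.array([0.6, 0.8, 0.0])
        d = cluster._dyadic_mean_direction(np.vstack([v, -v]))
        assert min(np.linalg.norm(d - v), np.linalg.norm(d + v)) < 1e-12

    def test_uniform_direction_reduces_to_spatial(self, rng):
        feats, _ = _blob_features(rng)
        mask = _grid_mask_for(feats)
        e1 = np.tile([0.0, 0.0, 1.0], (feats.n_voxels, 1))
        init = cluster.init_centroids(feats, ClusterConfig(k=7, n_init_runs=5,
                                                           seed=0))
        cfg = ClusterConfig(k=7, seed=0)
        lab_ad = cluster.kmeans_ad(feats, e1, init, cfg, mask)
        cfg_pos = ClusterConfig(k=7, alpha=1.0, seed=0)
        feats0 = FeatureMatrix(positions=feats.positions,
                               odf=np.zeros((feats.n_voxels, 1)),
                               voxel_index=feats.voxel_index)
        init0 = np.hstack([init[:, :3], np.zeros((7, 1))])
        lab_pos = cluster.kmeans_combined(feats0, init0, cfg_pos, mask)
        np.testing.assert_array_equal(lab_ad.labels, lab_pos.labels)

    def test_orthogonal_populations_split_by_direction_alone(self, rng):
        """alpha = 0: two spatially mixed, orthogonally oriented groups."""
        n = 100
        pos = rng.normal(size=(n, 3)) * 10
        e1 = np.tile([1.0, 0, 0], (n, 1))
        e1[n // 2:] = [0.0, 0, 1.0]
        idx = np.arange(n)[:, None] * np.array([1, 0, 0])
        feats = FeatureMatrix(positions=pos, odf=np.zeros((n, 1)),
                              voxel_index=idx.astype(int))
        mask = _grid_mask_for(feats)
        cfg = ClusterConfig(k=2, alpha=0.0, seed=0)
        init = np.hstack([pos[[0, -1]], np.zeros((2, 1))])
        lab = cluster.kmeans_ad(feats, e1, init, cfg, mask)
        got = lab.labels[lab.labels > 0]
        first, second = got[:n // 2], got[n // 2:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
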