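"""Spatial ICA on synchronization matrices, thresholding, artifact labels."""

import numpy as np
import pytest

from isps.decomp import (
    ComponentLabel,
    flag_artifact_components,
    match_components,
    replicability_between,
    split_half_replicability,
    sync_ica,
    threshold_spatial_map,
)


def _two_source_matrix(rng, n_vox=1000, n_t=120):
    """Rank-2 matrix with sparse disjoint spatial supports + small noise.

    Supports are kept sparse (5% of voxels) so the two indicator maps are
    nearly uncorrelated; dense disjoint supports are mutually dependent and
    no ICA can separate them perfectly.
    """
    s1 = np.zeros(n_vox)
    s1[:50] = 1.0
    s2 = np.zeros(n_vox)
    s2[500:550] = 1.0
    t1 = rng.normal(size=n_t)
    t2 = np.sign(rng.normal(size=n_t))  # non-Gaussian, independent of t1
    M = np.outer(s1, t1) + np.outer(s2, t2) + 0.01 * rng.normal(size=(n_vox, n_t))
    return M, np.stack([s1, s2])


class TestSyncIca:
    def test_recovers_disjoint_sources(self):
        M, truth = _two_source_matrix(np.random.default_rng(0))
        res = sync_ica(M, order=2, seed=0)
        _, rs = match_components(truth, res.spatial_maps)
        assert rs.min() > 0.95

    def test_seeded_determinism(self):
        M, _ = _two_source_matrix(np.random.default_rng(1))
        a = sync_ica(M, order=2, seed=7)
        b = sync_ica(M, order=2, seed=7)
        np.testing.assert_array_equal(a.spatial_maps, b.spatial_maps)
        np.testing.assert_array_equal(a.time_courses, b.time_courses)

    def test_maps_zscored_and_skew_positive(self):
        M, _ = _two_source_matrix(np.random.default_rng(2))
        res = sync_ica(M, order=2, seed=0)
        np.testing.assert_allclose(res.spatial_maps.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.spatial_maps.std(axis=1), 1.0, atol=1e-9)
        from scipy.stats import skew

        assert (skew(res.spatial_maps, axis=1) >= 0).all()

    def test_order_reduced_to_rank_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        M = np.outer(rng.normal(size=200), rng.normal(size=50))  # rank 1
        with caplog.at_level("WARNING"):
            res = sync_ica(M, order=5, seed=0)
        assert res.order == 1
        assert any("rank" in r.message for r in caplog.records)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(50, 30))
        with pytest.raises(ValueError):
            sync_ica(M, order=30, seed=0)  # order >= min(voxels, time)
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            sync_ica(M, order=3, seed=0)

    def test_time_course_length_matches_input(self):
        M, _ = _two_source_matrix(np.random.default_rng(5))
        res = sync_ica(M, order=2, seed=0)
        assert res.time_courses.shape == (2, M.shape[1])


class TestThreshold:
    def test_no_suprathreshold_voxels(self):
        zmap = np.full(100, 2.0)
        assert not threshold_spatial_map(zmap, 2.3).any()

    def test_minus_inf_threshold_selects_all(self):
        assert threshold_spatial_map(np.zeros(10), -np.inf).all()

    def test_gaussian_tail_count(self):
        from scipy.stats import norm

        z = np.random.default_rng(6).normal(size=10_000)
        count = threshold_spatial_map(z, 2.3).sum()
        expected = 10_000 * norm.sf(2.3)
        assert abs(count - expected) <= 3 * np.sqrt(expected)


class TestReplicability:
    def test_identical_halves_fully_replicable(self):
        rng = np.random.default_rng(7)
        M, _ = _two_source_matrix(rng)
        score = replicability_between(M, M.copy(), order=2, seed=0)
        assert score > 0.99

    def test_planted_fixture_prefers_true_order(self, planted_matrices, design):
        from isps.prep import prepare

        mats, _, _ = planted_matrices
        prepared = [prepare(m, tr_s=2.0).data for m in mats]
        _, scores = split_half_replicability(
            prepared, orders=(3, 10), n_splits=3, seed=0
        )
        assert scores[3] >= scores[10]  # over-factoring splits true sources

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            split_half_replicability([np.zeros((5, 10))] * 3)


class TestArtifactFlagging:
    def _result_with_map(self, zmap):
        from isps.decomp import ICAResult

        return ICAResult(
            spatial_maps=np.atleast_2d(zmap),
            time_courses=np.zeros((1, 10)),
            order=1,
            seed=0,
            n_iter=1,
            explained_variance_ratio=1.0,
        )

    def test_csf_component_unclassified(self):
        zmap = np.zeros(100)
        zmap[:10] = 5.0
        csf = np.zeros(100, dtype=bool)
        csf[:10] = True
        labels = flag_artifact_components(self._result_with_map(zmap), {"csf": csf})
        assert labels[0].status == "unclassified"

    def test_gray_component_retained(self):
        zmap = np.zeros(100)
        zmap[:10] = 5.0
        gray = np.zeros(100, dtype=bool)
        gray[:10] = True
        labels = flag_artifact_components(self._result_with_map(zmap), {"gray": gray})
        assert labels[0].status == "retained"

    def test_majority_white_rule(self):
        zmap = np.zeros(100)
        zmap[:10] = 5.0
        white = np.zeros(100, dtype=bool)
        white[:6] = True  # 60% of suprathreshold voxels
        labels = flag_artifact_components(self._result_with_map(zmap), {"white": white})
        assert labels[0].status == "unclassified"
        assert "60.0%" in labels[0].reason

    def test_empty_map_unclassified(self):
        labels = flag_artifact_components(self._result_with_map(np.zeros(50)), {})
        assert labels[0].status == "unclassified"
        assert "empty" in labels[0].reason

    def test_every_component_labelled_once(self):
        rng = np.random.default_rng(8)
        M, _ = _two_source_matrix(rng)
        res = sync_ica(M, order=2, seed=0)
        labels = flag_artifact_components(res, {})
        assert [l.component for l in labels] == [0, 1]
        assert all(isinstance(l, ComponentLabel) for l in labels)
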