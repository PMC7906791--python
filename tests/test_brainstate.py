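"""Session scoring, percentile groups, maps, DMN index, spectral reordering."""

import numpy as np
import pytest

from slowosc.brainstate import (
    binned_relationship,
    difference_map,
    intrinsic_dmn_correlation,
    percentile_groups,
    seed_correlation_map,
    spectral_reorder,
    variance_groups,
)


class TestScoreSessions:
    @pytest.fixture(scope="class")
    def tiny_model(self):
        from slowosc.gru import GRUForecaster, TrainConfig
        from slowosc.preprocess import make_target_pair
        from slowosc.synth import VesselTrialSpec, generate_vessel_trial
        from slowosc.timeseries import BandSpec

        band = BandSpec(0.01, 0.1)
        trial = generate_vessel_trial(VesselTrialSpec(
            n_vessels=6, n_timepoints=600, seed=1))
        pairs = [make_target_pair(ts, band) for ts in trial]
        cfg = TrainConfig(hidden_size=10, loss="cc", learning_rate=0.01,
                          l2=0.0, batch_size=3, n_epochs=6, washout=100)
        return GRUForecaster(pairs, cfg).fit(params_init_seed=0)

    def _sessions(self, n=4):
        from slowosc.synth import NetworkSessionSpec, generate_network_session

        return [generate_network_session(NetworkSessionSpec(
            n_timepoints=600, seed=100 + k)) for k in range(n)]

    def test_row_count_and_determinism(self, tiny_model):
        from slowosc.brainstate import score_sessions

        sessions = self._sessions()
        t1 = score_sessions(tiny_model, sessions, roi="ROI04")
        t2 = score_sessions(tiny_model, sessions, roi="ROI04")
        assert len(t1) == 4
        assert {"prediction_cc", "lag_s", "global_variance",
                "intrinsic_dmn_corr"} <= set(t1.columns)
        np.testing.assert_array_equal(t1["prediction_cc"].to_numpy(),
                                      t2["prediction_cc"].to_numpy())

    def test_missing_roi_recorded_others_proceed(self, tiny_model):
        from slowosc.brainstate import score_sessions

        sessions = self._sessions(3)
        sessions[1].roi_labels[4] = "RENAMED"
        table = score_sessions(tiny_model, sessions, roi="ROI04")
        assert table["prediction_cc"].isna().sum() == 1
        assert table["prediction_cc"].notna().sum() == 2


class TestPercentileGroups:
    def test_ranked_scores_select_extremes(self):
        scores = np.arange(1, 101, dtype=float)
        top, bottom = percentile_groups(scores, pct=0.05)
        assert sorted(scores[top]) == [96, 97, 98, 99, 100]
        assert sorted(scores[bottom]) == [1, 2, 3, 4, 5]

    def test_all_equal_stable_tie_rule(self):
        scores = np.ones(40)
        top, bottom = percentile_groups(scores, pct=0.05)
        np.testing.assert_array_equal(bottom, [0, 1])
        np.testing.assert_array_equal(top, [38, 39])

    def test_groups_disjoint(self, rng):
        scores = rng.standard_normal(60)
        top, bottom = percentile_groups(scores, pct=0.4)
        assert len(np.intersect1d(top, bottom)) == 0

    def test_invalid_pct_rejected(self, rng):
        with pytest.raises(ValueError):
            percentile_groups(rng.standard_normal(10), pct=0.6)

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            percentile_groups(np.arange(5.0), pct=0.05)


class TestSeedCorrelationMap:
    def test_seed_identical_to_column_gives_one(self, rng):
        mat = rng.standard_normal((100, 4))
        out = seed_correlation_map(mat[:, 2], mat)
        assert out[2] == pytest.approx(1.0)
        assert out.size == 4

    def test_orthogonalized_column_gives_zero(self, rng):
        seed = rng.standard_normal(200)
        col = rng.standard_normal(200)
        seed_c = seed - seed.mean()
        resid = col - col.mean() - (col - col.mean()) @ seed_c / (
            seed_c @ seed_c) * seed_c
        mat = np.column_stack([col, resid])
        out = seed_correlation_map(seed, mat)
        assert abs(out[1]) < 1e-10

    def test_zero_variance_column_flagged_nan(self, rng):
        mat = rng.standard_normal((50, 3))
        mat[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = seed_correlation_map(rng.standard_normal(50), mat)
        assert np.isnan(out[1])


class TestDifferenceMap:
    def test_identical_groups_zero_map_empty_mask(self, rng):
        maps = rng.uniform(-0.3, 0.3, size=(4, 6))
        dm = difference_map(maps, maps)
        np.testing.assert_allclose(dm.difference, 0.0)
        assert not dm.significant.any()

    def test_antisymmetric_under_group_swap(self, rng):
        a = rng.uniform(-0.3, 0.3, size=(5, 6))
        b = rng.uniform(-0.3, 0.3, size=(5, 6))
        d1 = difference_map(a, b)
        d2 = difference_map(b, a)
        np.testing.assert_allclose(d1.difference, -d2.difference, atol=1e-15)

    def test_shifted_nodes_detected(self, rng):
        a = rng.uniform(0.0, 0.1, size=(12, 8))
        b = a + rng.uniform(-0.005, 0.005, size=(12, 8))
        a = a.copy()
        a[:, [1, 5]] += 0.5
        dm = difference_map(a, b)
        assert dm.significant[1] and dm.significant[5]
        assert np.isnan(dm.masked[~dm.significant]).all()

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="2 maps"):
            difference_map(rng.uniform(size=(1, 4)), rng.uniform(size=(3, 4)))


class TestIntrinsicDmn:
    def test_component_equal_to_all_voxels(self, rng):
        comp = rng.standard_normal(120)
        voxels = np.tile(comp[:, None], (1, 5))
        assert intrinsic_dmn_correlation(comp, voxels) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            comp = rng.standard_normal(300)
            voxels = rng.standard_normal((300, 4))
            vals.append(intrinsic_dmn_correlation(comp, voxels))
        assert abs(np.mean(vals)) < 0.1

    def test_mean_of_correlations_not_correlation_of_mean(self, rng):
        # two perfectly anti-correlated voxels: mean trace is flat (corr
        # undefined/irrelevant) but mean correlation is exactly 0
        comp = rng.standard_normal(100)
        v = rng.standard_normal(100)
        voxels = np.column_stack([comp + 0.1 * v, -(comp + 0.1 * v)])
        out = intrinsic_dmn_correlation(comp, voxels)
        assert abs(out) < 1e-10
        assert np.allclose(voxels.mean(axis=1), 0.0)

    def test_empty_dmn_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            intrinsic_dmn_correlation(rng.standard_normal(50),
                                      np.empty((50, 0)))


class TestBinnedRelationship:
    def test_identity_curve_on_diagonal(self, rng):
        scores = rng.standard_normal(200)
        bs, bv = binned_relationship(scores, scores, bin_pct=0.1)
        np.testing.assert_allclose(bs, bv)
        assert np.all(np.diff(bs) > 0)

    def test_bin_count(self):
        scores = np.arange(4000.0)
        bs, bv = binned_relationship(scores, scores, bin_pct=0.02)
        assert bs.size == 50

    def test_remainder_goes_to_last_bin(self):
        scores = np.arange(105.0)
        values = np.ones(105)
        bs, bv = binned_relationship(scores, values, bin_pct=0.1)
        assert bs.size == 10
        # last bin holds 10 + 5 remainder sessions
        assert bs[-1] == pytest.approx(np.mean(np.arange(90.0, 105.0)))

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            binned_relationship(np.arange(3.0), np.arange(3.0), bin_pct=0.02)


class TestVarianceGroups:
    def _table(self, rng, n=60):
        import pandas as pd

        var = rng.uniform(0.5, 2.0, n)
        return pd.DataFrame({
            "prediction_cc": rng.uniform(0, 0.6, n),
            "global_variance": var,
            "intrinsic_dmn_corr": rng.uniform(0, 0.5, n),
        })

    def test_scaled_sessions_variance_ordering(self):
        import pandas as pd

        scales = np.array([1.0, 3.0, 2.0, 0.5, 4.0] * 4)
        table = pd.DataFrame({
            "prediction_cc": np.zeros(20) + np.arange(20) * 1e-3,
            "global_variance": scales**2,
        })
        rep = variance_groups(table, pct=0.2)
        top_scales = scales[rep["variance_top"]]
        assert top_scales.min() >= scales[
            np.setdiff1d(np.arange(20), rep["variance_top"])].max()

    def test_report_contains_group_overlap_and_spread(self, rng):
        rep = variance_groups(self._table(rng), pct=0.1)
        assert "overlap_top" in rep and "score_top_variance_range" in rep
        lo, hi = rep["score_top_variance_range"]
        assert lo <= hi

    def test_grouping_invariant_under_session_reorder(self, rng):
        table = self._table(rng)
        rep1 = variance_groups(table, pct=0.1)
        perm = rng.permutation(len(table))
        rep2 = variance_groups(table.iloc[perm].reset_index(drop=True), pct=0.1)
        set1 = set(table["global_variance"].to_numpy()[rep1["variance_top"]])
        set2 = set(table["global_variance"].to_numpy()[perm][rep2["variance_top"]])
        assert set1 == set2


class TestSpectralReorder:
    def test_shuffled_two_block_matrix_restored_contiguous(self, rng):
        n = 12
        labels = np.array([0] * 6 + [1] * 6)
        C = np.where(labels[:, None] == labels[None, :], 0.8, -0.2)
        np.fill_diagonal(C, 1.0)
        perm_in = rng.permutation(n)
        shuffled = C[np.ix_(perm_in, perm_in)]
        order = spectral_reorder(shuffled)
        reordered_labels = labels[perm_in][order]
        # blocks contiguous: exactly one transition in the label sequence
        assert (np.diff(reordered_labels) != 0).sum() == 1

    def test_output_is_permutation(self, rng):
        A = rng.standard_normal((8, 8))
        C = np.corrcoef(A)
        order = spectral_reorder(C)
        assert sorted(order) == list(range(8))

    def test_identity_matrix_deterministic(self):
        o1 = spectral_reorder(np.eye(5))
        o2 = spectral_reorder(np.eye(5))
        np.testing.assert_array_equal(o1, o2)

    def test_bandedness_does_not_decrease(self, rng):
        labels = np.array([0] * 5 + [1] * 5)
        C = np.where(labels[:, None] == labels[None, :], 0.7, -0.1)
        np.fill_diagonal(C, 1.0)
        perm_in = rng.permutation(10)
        shuffled = C[np.ix_(perm_in, perm_in)]

        def adjacent_sum(M):
            return sum(abs(M[i, i + 1]) for i in range(len(M) - 1))

        order = spectral_reorder(shuffled)
        reordered = shuffled[np.ix_(order, order)]
        assert adjacent_sum(reordered) >= adjacent_sum(shuffled) - 1e-12

    def test_asymmetric_matrix_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            spectral_reorder(rng.standard_normal((4, 4)))
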