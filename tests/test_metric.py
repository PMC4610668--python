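"""Unit and property tests for the eigenvalue-gap heritable-state metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heredity import (
    EigenSpectrum,
    MetricConfig,
    ObservationMatrix,
    add_regularization,
    convergence_curve,
    count_heritable_states,
    detect_gap,
    eigen_spectrum,
    preprocess,
    saturation_warning,
)


def cluster_data(k, n_features, rows_per_cluster, noise=0.0, seed=0):
    """k cluster centers in general position, duplicated, optional noise."""
    rng = np.random.default_rng(seed)
    centers = rng.random((k, n_features))
    data = np.repeat(centers, rows_per_cluster, axis=0)
    if noise > 0:
        data = data + rng.normal(0.0, noise, data.shape)
    rng.shuffle(data)  # interleave clusters so row prefixes stay representative
    return ObservationMatrix(data)


class TestPreprocess:
    def test_centers_columns(self):
        m = preprocess(ObservationMatrix(np.array([[1.0, 5.0], [3.0, 5.0]])))
        assert np.allclose(m.values[:, 0], [-1.0, 1.0])
        assert np.allclose(m.values[:, 1], [0.0, 0.0])

    def test_zero_variance_column_left_unscaled(self):
        raw = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 6.0]])
        cfg = MetricConfig(normalize_columns=True)
        out = preprocess(ObservationMatrix(raw), cfg)
        assert np.allclose(out.values[:, 0], 0.0)
        assert np.isclose(out.values[:, 1].std(ddof=1), 1.0)

    def test_random_matrix_means_vanish(self):
        rng = np.random.default_rng(3)
        out = preprocess(ObservationMatrix(rng.random((10, 4))))
        assert np.all(np.abs(out.values.mean(axis=0)) < 1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            preprocess(ObservationMatrix(np.ones((1, 4))))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ObservationMatrix(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestRegularization:
    def test_appends_exact_duplicates(self):
        m = ObservationMatrix(np.arange(12.0).reshape(3, 4))
        out = add_regularization(m, copies=10, seed=5)
        assert out.n_rows == 13
        block = out.values[3:]
        assert np.all(block == block[0])
        assert any(np.array_equal(block[0], row) for row in m.values)

    def test_zero_copies_is_noop(self):
        m = ObservationMatrix(np.arange(12.0).reshape(3, 4))
        out = add_regularization(m, copies=0, seed=5)
        assert np.array_equal(out.values, m.values)

    def test_seed_reproducibility(self):
        m = ObservationMatrix(np.random.default_rng(0).random((30, 4)))
        a = add_regularization(m, copies=3, seed=9)
        b = add_regularization(m, copies=3, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            add_regularization(ObservationMatrix(np.ones((2, 2))), copies=-1)


class TestEigenSpectrum:
    def test_rank_one_data(self):
        m = ObservationMatrix(np.array([[0.0, 0.0], [2.0, 0.0]]))
        spec = eigen_spectrum(preprocess(m))
        assert spec.n_eigs == 1
        assert spec.eigenvalues[0] > 0

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_duplicated_centers_have_rank_k_minus_1(self, k):
        spec = eigen_spectrum(preprocess(cluster_data(k, 50, 5, seed=k)))
        scale = spec.eigenvalues[0]
        assert np.sum(spec.eigenvalues > 1e-9 * scale) == k - 1

    def test_conservation(self):
        rng = np.random.default_rng(11)
        m = preprocess(ObservationMatrix(rng.normal(size=(40, 25))))
        spec = eigen_spectrum(m)
        total_var = m.values.var(axis=0, ddof=1).sum()
        assert np.isclose(spec.eigenvalues.sum(), total_var, rtol=1e-8)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(12)
        data = rng.normal(size=(30, 20))
        q, _ = np.linalg.qr(rng.normal(size=(20, 20)))
        s1 = eigen_spectrum(preprocess(ObservationMatrix(data)))
        s2 = eigen_spectrum(preprocess(ObservationMatrix(data @ q)))
        assert np.allclose(s1.eigenvalues, s2.eigenvalues, atol=1e-8)

    def test_zero_padding_semantics(self):
        spec = EigenSpectrum(np.array([3.0, 1.0]))
        assert spec.padded_window_sum(0, 10) == 4.0
        assert spec.padded_window_sum(2, 10) == 0.0


class TestDetectGap:
    def test_flat_spectrum_reports_no_structure(self):
        res = detect_gap(np.ones(50), alpha=0.1)
        assert res.j == 0
        assert res.n_states_raw == 1
        assert res.gapless
        assert res.converged

    def test_spiked_spectrum_hand_trace(self):
        # one strong eigenvalue over a flat tail of 99 at 0.1: the search
        # converges in two passes with lambda_> = 0.2 and T = 1.18
        spectrum = np.array([10.0] + [0.1] * 99)
        res = detect_gap(spectrum, alpha=0.1)
        assert res.j == 1
        assert res.n_states_raw == 2
        assert res.converged and not res.gapless
        j_last, lam_gt_last, t_last = res.threshold_trace[-1]
        assert j_last == 1
        assert np.isclose(lam_gt_last, 0.2)
        assert np.isclose(t_last, 1.18)

    def test_three_cluster_spectrum(self):
        spec = eigen_spectrum(preprocess(cluster_data(3, 40, 10, seed=2)))
        res = detect_gap(spec, alpha=0.1)
        assert res.j == 2
        assert res.n_states_raw == 3

    def test_tie_counts_as_below(self):
        # eigenvalues exactly at T must not be counted above it
        res = detect_gap(np.array([1.0, 1.0, 1.0, 1.0]), alpha=0.5)
        assert res.j == 0

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            detect_gap(np.array([]))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            detect_gap(np.array([2.0, 1.0]), alpha=1.5)


class TestCountHeritableStates:
    @pytest.mark.parametrize("k", [1, 2, 3, 5, 8])
    def test_exact_cluster_oracle_without_regularization(self, k):
        m = cluster_data(k, 120, 10, seed=k)
        cfg = MetricConfig(regularization_copies=0)
        if k == 1:
            # a single duplicated point has no variance at all
            res = count_heritable_states(
                cluster_data(1, 120, 10, noise=1e-6, seed=1), cfg, seed=0
            )
        else:
            res = count_heritable_states(m, cfg, seed=0)
        assert res.n_states == k

    @pytest.mark.parametrize("k", [2, 5, 8])
    def test_regularization_consistency_on_clusters(self, k):
        m = cluster_data(k, 120, 10, seed=k)
        with_reg = count_heritable_states(m, MetricConfig(), seed=0)
        without = count_heritable_states(
            m, MetricConfig(regularization_copies=0), seed=0
        )
        assert with_reg.n_states == without.n_states == k

    def test_single_state_with_regularization(self):
        m = cluster_data(1, 100, 200, noise=1e-3, seed=4)
        res = count_heritable_states(m, MetricConfig(), seed=0)
        assert res.n_states == 1

    def test_isotropic_null_yields_one_state(self):
        # i.i.d. noise has no heritable structure; regularization pins the
        # count at 1 across seeds
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = ObservationMatrix(rng.normal(size=(200, 200)))
            res = count_heritable_states(m, MetricConfig(), seed=seed)
            hits += res.n_states == 1
        assert hits >= 9

    def test_scale_equivariance(self):
        m = cluster_data(4, 60, 8, noise=0.01, seed=6)
        scaled = ObservationMatrix(m.values * 7.5)
        cfg = MetricConfig(regularization_copies=0)
        r1 = count_heritable_states(m, cfg, seed=0)
        r2 = count_heritable_states(scaled, cfg, seed=0)
        assert r1.n_states == r2.n_states
        assert r1.j == r2.j
        s1 = np.array([t for _, _, t in r1.threshold_trace])
        s2 = np.array([t for _, _, t in r2.threshold_trace])
        assert np.allclose(s2, s1 * 7.5**2)

    def test_rotation_invariance_of_count(self):
        rng = np.random.default_rng(8)
        m = cluster_data(3, 40, 10, noise=0.02, seed=8)
        q, _ = np.linalg.qr(rng.normal(size=(40, 40)))
        rot = ObservationMatrix(m.values @ q)
        cfg = MetricConfig(regularization_copies=0)
        assert (
            count_heritable_states(m, cfg, seed=0).n_states
            == count_heritable_states(rot, cfg, seed=0).n_states
        )

    def test_upper_bound(self):
        rng = np.random.default_rng(9)
        m = ObservationMatrix(rng.normal(size=(6, 40)))
        res = count_heritable_states(m, MetricConfig(regularization_copies=0), seed=0)
        assert 1 <= res.n_states <= 6

    @given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_count_bounds_property(self, k, seed):
        m = cluster_data(k, 30, 6, noise=0.05, seed=seed)
        res = count_heritable_states(m, MetricConfig(), seed=seed)
        assert 1 <= res.n_states <= min(m.n_rows, m.n_features)


class TestConvergenceCurve:
    def test_plateau_on_well_separated_species(self):
        m = cluster_data(5, 80, 40, noise=0.02, seed=10)
        curve = convergence_curve(m, MetricConfig(), row_counts=[50, 100, 150, 200], seed=0)
        assert list(curve["rows_used"]) == [50, 100, 150, 200]
        assert (curve["n_states"].to_numpy()[-2:] == 5).all()
        rising, _ = saturation_warning(curve)
        assert not rising

    def test_full_count_matches_direct_call(self):
        m = cluster_data(3, 30, 10, noise=0.01, seed=11)
        cfg = MetricConfig(seed=42)
        curve = convergence_curve(m, cfg, row_counts=[m.n_rows], seed=7)
        direct = count_heritable_states(m, cfg, seed=np.random.default_rng(7))
        assert curve["n_states"].iloc[0] == direct.n_states

    def test_subsample_mode_reproducible(self):
        m = cluster_data(4, 30, 20, noise=0.02, seed=12)
        a = convergence_curve(m, MetricConfig(), [20, 40], mode="subsample", seed=3)
        b = convergence_curve(m, MetricConfig(), [20, 40], mode="subsample", seed=3)
        assert a.equals(b)

    def test_invalid_row_counts_rejected(self):
        m = cluster_data(2, 10, 5, seed=13)
        with pytest.raises(ValueError):
            convergence_curve(m, MetricConfig(), [5, 100])
        with pytest.raises(ValueError):
            convergence_curve(m, MetricConfig(), [8, 4])


class TestSaturationWarning:
    def test_plateaued_curve(self):
        import pandas as pd

        curve = pd.DataFrame({"rows_used": [10, 20, 30], "n_states": [5, 5, 5]})
        rising, _ = saturation_warning(curve)
        assert not rising

    def test_strictly_increasing_curve(self):
        import pandas as pd

        curve = pd.DataFrame({"rows_used": [10, 20, 30], "n_states": [40, 80, 120]})
        rising, msg = saturation_warning(curve)
        assert rising
        assert "not trustworthy" in msg

    def test_short_curve_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            saturation_warning(pd.DataFrame({"rows_used": [10], "n_states": [5]}))
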