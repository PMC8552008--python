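"""VAF, RMSE, dimensional variance, entropy, circular correlation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gaitlatent as gl
from gaitlatent.metrics import ZeroVarianceError, circular_correlation


class TestVAF:
    def test_perfect_reconstruction_is_100(self, pose_matrix):
        assert gl.vaf(pose_matrix, pose_matrix) == pytest.approx(100.0)

    def test_mean_reconstruction_is_0(self, pose_matrix):
        mean = np.broadcast_to(pose_matrix.mean(axis=0), pose_matrix.shape)
        assert gl.vaf(pose_matrix, mean) == pytest.approx(0.0, abs=1e-9)

    def test_single_channel_hand_oracle(self):
        # y=(1,2,3), yhat=(1,2,4): var(resid)=var((0,0,-1))=2/9, var(y)=2/3
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.array([1.0, 2.0, 4.0])
        assert gl.vaf(y, y_hat) == pytest.approx(100 * (1 - (2 / 9) / (2 / 3)))
        assert gl.vaf(y, y_hat) == pytest.approx(66.666666, abs=1e-4)

    def test_shift_invariance(self, pose_matrix):
        y_hat = pose_matrix + np.random.default_rng(0).normal(
            0, 0.1, pose_matrix.shape
        )
        base = gl.vaf(pose_matrix, y_hat)
        shifted = gl.vaf(pose_matrix + 5.0, y_hat + 5.0)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            gl.vaf(np.ones((10, 3)), np.ones((10, 3)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gl.vaf(np.zeros((5, 3)), np.zeros((4, 3)))

    def test_windows_pooled_over_timesteps(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(10, 6, 4))
        flat = w.reshape(-1, 4)
        assert gl.vaf(w, w * 0.9) == pytest.approx(gl.vaf(flat, flat * 0.9))


class TestRMSE:
    def test_zero_on_identity(self, pose_matrix):
        assert gl.rmse(pose_matrix, pose_matrix) == 0.0

    def test_hand_oracle(self):
        assert gl.rmse(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == (
            pytest.approx(np.sqrt(25 / 2))
        )

    def test_mean_pose_baseline_is_unity(self):
        """On self-standardized data, always answering the mean pose gives
        RMSE exactly 1 — the 'no better than the mean' threshold."""
        rng = np.random.default_rng(2)
        x = rng.normal(2.0, 3.0, size=(500, 14))
        z = (x - x.mean(axis=0)) / x.std(axis=0)
        baseline = np.broadcast_to(z.mean(axis=0), z.shape)
        assert gl.rmse(z, baseline) == pytest.approx(1.0, abs=1e-6)

    def test_squared_rmse_decomposes_over_channels(self, pose_matrix):
        y_hat = np.zeros_like(pose_matrix)
        mse_per_channel = np.mean((pose_matrix - y_hat) ** 2, axis=0)
        assert gl.rmse(pose_matrix, y_hat) ** 2 == pytest.approx(
            mse_per_channel.mean()
        )


class TestDimensionalVariance:
    def test_equal_variance_is_uniform(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=(4000, 2))
        latent = (latent - latent.mean(0)) / latent.std(0)
        dv = gl.dimensional_variance(latent)
        np.testing.assert_allclose(dv.ratios, [0.5, 0.5], atol=1e-9)

    def test_hand_oracle_3_to_1(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(size=(5000, 2)) * [np.sqrt(3), 1.0]
        latent = latent / latent.std(0) * [np.sqrt(3), 1.0]
        dv = gl.dimensional_variance(latent)
        np.testing.assert_allclose(dv.ratios, [0.75, 0.25], atol=1e-9)

    def test_ratios_sum_to_one(self, pose_matrix):
        model = gl.fit_pca(pose_matrix)
        latent = gl.encode_pca(model, pose_matrix, k=5)
        dv = gl.dimensional_variance(latent)
        assert dv.ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dv.ratios >= 0)

    def test_pca_latent_ratios_equal_eigenvalue_ratios(self, pose_matrix):
        model = gl.fit_pca(pose_matrix)
        latent = gl.encode_pca(model, pose_matrix, k=4)
        dv = gl.dimensional_variance(latent)
        expected = model.eigenvalues[:4] / model.eigenvalues[:4].sum()
        np.testing.assert_allclose(dv.ratios, expected, atol=1e-9)

    def test_zero_latent_rejected(self):
        with pytest.raises(ZeroVarianceError):
            gl.dimensional_variance(np.zeros((10, 2)))


class TestVarianceEntropy:
    @pytest.mark.parametrize(
        "ratios,expected",
        [
            ([0.5, 0.5], np.log(2)),
            ([1.0, 0.0], 0.0),
            ([0.75, 0.25], -0.75 * np.log(0.75) - 0.25 * np.log(0.25)),
        ],
    )
    def test_hand_oracles(self, ratios, expected):
        assert gl.variance_entropy(np.array(ratios)) == pytest.approx(expected)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8)
    )
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_uniform(self, raw):
        ratios = np.array(raw) / np.sum(raw)
        h = gl.variance_entropy(ratios)
        assert -1e-12 <= h <= np.log(len(ratios)) + 1e-12


class TestCircularCorrelation:
    def test_rotation_gives_unity(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 2 * np.pi, 500)
        assert circular_correlation(a, np.mod(a + 1.0, 2 * np.pi)) == (
            pytest.approx(1.0, abs=1e-9)
        )

    def test_reflection_gives_minus_unity(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 2 * np.pi, 500)
        assert circular_correlation(a, np.mod(-a, 2 * np.pi)) == (
            pytest.approx(-1.0, abs=1e-9)
        )

    def test_independent_angles_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 2 * np.pi, 3000)
        b = rng.uniform(0, 2 * np.pi, 3000)
        assert abs(circular_correlation(a, b)) < 0.1

    def test_rank_version_invariant_to_monotone_warping(self):
        """A monotone (but nonlinear) circular re-parameterization of the
        phase leaves the rank correlation at 1."""
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 2 * np.pi, 400)
        warped = np.mod(a + 0.5 * np.sin(a) + 0.3, 2 * np.pi)
        assert gl.circular_rank_correlation(a, warped) == pytest.approx(1.0, abs=1e-6)

    def test_latent_angle_of_circle_recovers_phase(self):
        phase = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        latent = np.stack([3 + np.cos(phase), -1 + np.sin(phase)], axis=1)
        angles = gl.latent_angles(latent)
        assert gl.circular_rank_correlation(angles, phase) == (
            pytest.approx(1.0, abs=1e-6)
        )
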