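import numpy as np
import pytest

from treeheight.alignment import (DepthPair, apply_alignment, column_profile,
                                  depth_mse_loss, fit_scale_shift,
                                  threshold_accuracy)
from treeheight.types import DepthMap

from conftest import random_depth_pair


def _ols_oracle(r, a):
    """Independent closed-form OLS on flattened pairs (design-matrix solve)."""
    X = np.stack([r, np.ones_like(r)], axis=1)
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    return coef[0], coef[1]


class TestFitScaleShift:
    def test_identity_pair(self):
        values = np.linspace(100, 5000, 64).reshape(8, 8)
        rel = DepthMap(values=values, kind="relative")
        ab = DepthMap(values=values, kind="absolute")
        fit = fit_scale_shift(rel, ab)
        assert fit.S == pytest.approx(1.0, abs=1e-12)
        assert fit.D == pytest.approx(0.0, abs=1e-9)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_recovers_affine_on_random_mask(self, rng):
        rel, ab = random_depth_pair(rng, S=2.5, D=300.0)
        fit = fit_scale_shift(rel, ab)
        m = rel.valid & ab.valid
        S_or, D_or = _ols_oracle(rel.values[m].ravel(), ab.values[m].ravel())
        assert fit.S == pytest.approx(2.5, rel=1e-9)
        assert fit.D == pytest.approx(300.0, rel=1e-9)
        assert fit.S == pytest.approx(S_or, rel=1e-9)
        assert fit.D == pytest.approx(D_or, rel=1e-9)
        assert fit.n_pixels == m.sum()

    def test_matches_oracle_under_noise(self, rng):
        rel, ab = random_depth_pair(rng, shape=(50, 60), S=40.0, D=800.0, sigma=20.0)
        fit = fit_scale_shift(rel, ab)
        m = rel.valid & ab.valid
        S_or, D_or = _ols_oracle(rel.values[m].ravel(), ab.values[m].ravel())
        assert fit.S == pytest.approx(S_or, rel=1e-9)
        assert fit.D == pytest.approx(D_or, rel=1e-9)

    def test_traversal_order_invariance(self, rng):
        rel, ab = random_depth_pair(rng, sigma=5.0)
        fit1 = fit_scale_shift(rel, ab)
        # transpose both maps: same pixel multiset, different raster order
        rel_t = DepthMap(values=rel.values.T, kind="relative", valid=rel.valid.T)
        ab_t = DepthMap(values=ab.values.T, kind="absolute", valid=ab.valid.T)
        fit2 = fit_scale_shift(rel_t, ab_t)
        assert fit1.S == pytest.approx(fit2.S, rel=1e-12)
        assert fit1.D == pytest.approx(fit2.D, rel=1e-12)

    def test_constant_relative_is_singular(self):
        rel = DepthMap(values=np.full((5, 5), 3.0), kind="relative")
        ab = DepthMap(values=np.linspace(1, 100, 25).reshape(5, 5), kind="absolute")
        with pytest.raises(ValueError, match="singular|constant"):
            fit_scale_shift(rel, ab)

    def test_too_few_pixels(self):
        rel = DepthMap(values=np.array([[1.0, 2.0]]), kind="relative",
                       valid=np.array([[True, False]]))
        ab = DepthMap(values=np.array([[10.0, 20.0]]), kind="absolute")
        with pytest.raises(ValueError, match="2"):
            fit_scale_shift(rel, ab)

    def test_negative_scale_warns(self):
        r = np.linspace(1, 10, 16).reshape(4, 4)
        rel = DepthMap(values=r, kind="relative")
        ab = DepthMap(values=1000.0 - 50.0 * r, kind="absolute")
        with pytest.warns(UserWarning, match="negative"):
            fit_scale_shift(rel, ab)

    def test_robust_refit_rejects_outliers(self, rng):
        rel, ab = random_depth_pair(rng, shape=(40, 40), S=80.0, D=500.0,
                                    sigma=2.0, valid_fraction=1.0)
        a = ab.values.copy()
        a[:2, :] = 30000.0  # contaminate 5% of rows
        ab_bad = DepthMap(values=a, kind="absolute")
        plain = fit_scale_shift(rel, ab_bad)
        robust = fit_scale_shift(rel, ab_bad, robust=True)
        assert abs(robust.S - 80.0) < abs(plain.S - 80.0)
        assert robust.S == pytest.approx(80.0, rel=0.01)


class TestApplyAlignment:
    def test_identity_switches_kind(self):
        rel = DepthMap(values=np.linspace(1, 100, 16).reshape(4, 4), kind="relative")
        fit = fit_scale_shift(rel, DepthMap(values=rel.values, kind="absolute"))
        out = apply_alignment(rel, fit)
        assert out.kind == "absolute"
        np.testing.assert_allclose(out.values, rel.values, rtol=1e-12)

    def test_fit_then_apply_reproduces_absolute(self, rng):
        rel, ab = random_depth_pair(rng, S=40.0, D=250.0)
        fit = fit_scale_shift(rel, ab)
        out = apply_alignment(rel, fit)
        m = rel.valid & ab.valid
        np.testing.assert_allclose(out.values[m], ab.values[m], rtol=1e-9)

    def test_clamped_to_sensor_range(self):
        rel = DepthMap(values=np.array([[0.0, 100.0]]), kind="relative")
        from treeheight.alignment import AffineDepthAlignment
        fit = AffineDepthAlignment(S=1000.0, D=-500.0, n_pixels=2, residual_rms=0.0)
        out = apply_alignment(rel, fit)
        assert out.values.max() <= 65535.0
        assert out.values.min() >= 0.0

    def test_monotonicity_preserved(self, rng):
        r = np.sort(rng.uniform(0, 50, size=64)).reshape(8, 8)
        rel = DepthMap(values=r, kind="relative")
        from treeheight.alignment import AffineDepthAlignment
        fit = AffineDepthAlignment(S=100.0, D=100.0, n_pixels=2, residual_rms=0.0)
        out = apply_alignment(rel, fit).values.ravel()
        assert np.all(np.diff(out) >= 0)


class TestColumnProfile:
    def test_constant_map(self):
        dm = DepthMap(values=np.full((6, 4), 1500.0), kind="absolute")
        prof = column_profile(dm, 2)
        assert prof.shape == (6, 2)
        assert np.all(prof[:, 1] == 1500.0)

    def test_invalid_column_empty(self):
        values = np.full((5, 3), 900.0)
        values[:, 1] = 0.0
        prof = column_profile(DepthMap(values=values, kind="absolute"), 1)
        assert prof.shape == (0, 2)

    def test_out_of_range(self):
        dm = DepthMap(values=np.ones((3, 3)), kind="absolute")
        with pytest.raises(IndexError):
            column_profile(dm, 3)

    def test_aligned_profile_tracks_truth_within_rms(self, rng):
        rel, ab = random_depth_pair(rng, shape=(40, 40), S=60.0, D=400.0,
                                    sigma=10.0, valid_fraction=1.0)
        fit = fit_scale_shift(rel, ab)
        aligned = apply_alignment(rel, fit)
        prof_a = column_profile(aligned, 7)
        prof_t = column_profile(ab, 7)
        resid = prof_a[:, 1] - prof_t[:, 1]
        assert np.sqrt(np.mean(resid ** 2)) < 4 * fit.residual_rms


class TestDepthMetrics:
    def test_loss_zero_for_identical(self):
        dm = DepthMap(values=np.full((3, 3), 5.0), kind="relative")
        assert depth_mse_loss(DepthPair(dm, dm)) == 0.0

    def test_loss_hand_value_two_pixels(self):
        d = DepthMap(values=np.array([[1.0, 3.0]]), kind="relative")
        t = DepthMap(values=np.array([[1.0, 1.0]]), kind="relative")
        # (1/(2*2)) * (0 + 4) = 1.0
        assert depth_mse_loss(DepthPair(d, t)) == pytest.approx(1.0)

    def test_loss_single_pixel(self):
        d = DepthMap(values=np.array([[4.0]]), kind="relative")
        t = DepthMap(values=np.array([[2.0]]), kind="relative")
        assert depth_mse_loss(DepthPair(d, t)) == pytest.approx(2.0)

    def test_accuracy_identical(self):
        dm = DepthMap(values=np.full((4, 4), 7.0), kind="absolute")
        assert threshold_accuracy(DepthPair(dm, dm), 1.25) == 100.0

    def test_accuracy_half(self):
        d = DepthMap(values=np.array([[1.0, 2.0]]), kind="relative")
        t = DepthMap(values=np.array([[1.0, 1.0]]), kind="relative")
        assert threshold_accuracy(DepthPair(d, t), 1.25) == 50.0

    def test_strict_inequality_at_threshold_one(self):
        d = DepthMap(values=np.array([[2.0, 3.0]]), kind="relative")
        t = DepthMap(values=np.array([[1.0, 1.5]]), kind="relative")
        assert threshold_accuracy(DepthPair(d, t), 1.0 + 1e-12) == 0.0

    def test_nonpositive_depths_rejected(self):
        d = DepthMap(values=np.array([[-1.0, 2.0]]), kind="relative")
        t = DepthMap(values=np.array([[1.0, 1.0]]), kind="relative")
        with pytest.raises(ValueError, match="positive"):
            threshold_accuracy(DepthPair(d, t), 1.25)
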