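"""Powder averaging, per-voxel fits, volume fitting and log-space MSE."""

import math

import numpy as np
import pytest

import qdi
from qdi import (DecayCurve, FitBounds, GeometryError, InsufficientDataError,
                 QDIParams, fit_decay, fit_volume, mse_log, powder_average,
                 qdi_attenuation)
from conftest import noiseless_curve


class TestPowderAverage:
    def test_constant_across_directions(self, ds1_scheme):
        data = np.full((2, 2, 1, len(ds1_scheme)), 5.0)
        curves = powder_average(data, ds1_scheme)
        assert np.allclose(curves.s_norm, 1.0)
        assert curves.valid.all()

    def test_two_direction_mean(self):
        scheme = qdi.AcquisitionScheme(
            bvals=np.array([0.0, 1000.0, 1000.0]),
            bvecs=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float))
        data = np.array([[8.0, 2.0, 4.0]])
        curves = powder_average(data, scheme)
        assert curves.b.tolist() == [0.0, 1000.0]
        assert curves.s_norm[0, 1] == pytest.approx(3.0 / 8.0)

    def test_single_direction_passthrough(self, ds3_scheme):
        rng = np.random.default_rng(0)
        data = rng.uniform(1.0, 10.0, size=(3, len(ds3_scheme)))
        curves = powder_average(data, ds3_scheme)
        assert np.allclose(curves.s_norm[:, 1:], data[:, 1:] / data[:, :1], rtol=1e-12)

    def test_volume_count_mismatch(self, ds1_scheme):
        with pytest.raises(GeometryError):
            powder_average(np.ones((2, 5)), ds1_scheme)

    def test_no_b0_raises(self):
        scheme = qdi.AcquisitionScheme(bvals=np.array([500.0, 1000.0]),
                                       bvecs=np.array([[1, 0, 0], [0, 1, 0]], dtype=float))
        with pytest.raises(InsufficientDataError):
            powder_average(np.ones((2, 2)), scheme)

    def test_nonpositive_marked_invalid(self):
        scheme = qdi.AcquisitionScheme(
            bvals=np.array([0.0, 1000.0]), bvecs=np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        curves = powder_average(np.array([[10.0, 0.0]]), scheme)
        assert not curves.valid[0, 1]
        assert curves.valid[0, 0]

    def test_shell_jitter_grouped(self):
        scheme = qdi.AcquisitionScheme(
            bvals=np.array([0.0, 990.0, 1010.0]),
            bvecs=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float))
        curves = powder_average(np.array([[1.0, 0.5, 0.7]]), scheme)
        assert curves.b.size == 2
        assert curves.b[1] == pytest.approx(1000.0)


class TestFitDecay:
    def test_noiseless_recovery_gm(self, ds1_scheme, gm_params):
        curve = noiseless_curve(ds1_scheme, gm_params)
        result = fit_decay(curve)
        assert result.params.d12 == pytest.approx(gm_params.d12, rel=1e-6)
        assert result.params.alpha == pytest.approx(gm_params.alpha, rel=1e-6)
        assert result.converged

    def test_pure_exponential_hits_alpha_one(self, ds1_scheme):
        p = QDIParams(d12=1e-3, alpha=1.0)
        result = fit_decay(noiseless_curve(ds1_scheme, p))
        assert result.params.alpha >= 0.9999
        assert result.params.d12 == pytest.approx(1e-3, rel=1e-6)
        assert math.isnan(result.ip)

    def test_two_points_insufficient(self):
        curve = DecayCurve(b=np.array([0.0, 1000.0]), s_norm=np.array([1.0, 0.5]),
                           valid=np.array([True, True]))
        with pytest.raises(InsufficientDataError):
            fit_decay(curve)

    def test_missing_b0_insufficient(self):
        b = np.array([500.0, 1000.0, 2000.0, 4000.0])
        curve = DecayCurve(b=b, s_norm=np.exp(-1e-3 * b), valid=np.ones(4, bool))
        with pytest.raises(InsufficientDataError):
            fit_decay(curve)

    def test_explicit_init_respected(self, ds1_scheme, gm_params):
        curve = noiseless_curve(ds1_scheme, gm_params)
        result = fit_decay(curve, init=QDIParams(d12=1.5e-3, alpha=0.7))
        assert result.params.alpha == pytest.approx(gm_params.alpha, rel=1e-6)

    def test_ip_consistent_with_find_ip(self, ds1_scheme, gm_params, small_ip_table):
        curve = noiseless_curve(ds1_scheme, gm_params)
        with_table = fit_decay(curve, ip_table=small_ip_table)
        direct = fit_decay(curve)
        assert with_table.ip == pytest.approx(direct.ip, rel=0.01)
        assert direct.ip == pytest.approx(qdi.find_ip(direct.params), rel=1e-12)

    @pytest.mark.parametrize("d12,alpha", [(4e-4, 0.6), (1.5e-3, 0.92), (2.5e-3, 0.55)])
    def test_zero_noise_identifiability_box(self, ds1_scheme, d12, alpha):
        p = QDIParams(d12=d12, alpha=alpha)
        result = fit_decay(noiseless_curve(ds1_scheme, p))
        assert result.params.d12 == pytest.approx(d12, rel=1e-5)
        assert result.params.alpha == pytest.approx(alpha, rel=1e-5)


class TestMseLog:
    def test_zero_at_own_params(self, ds1_scheme, gm_params):
        curve = noiseless_curve(ds1_scheme, gm_params)
        assert mse_log(gm_params, curve) < 1e-20

    def test_constant_log_offset(self, ds1_scheme, gm_params):
        delta = 0.1
        curve = noiseless_curve(ds1_scheme, gm_params)
        shifted = DecayCurve(b=curve.b, s_norm=curve.s_norm * math.exp(delta),
                             valid=curve.valid)
        assert mse_log(gm_params, shifted) == pytest.approx(delta**2, rel=1e-10)

    def test_truncated_fit_scores_worse_on_full_range(self, ds1_scheme):
        # noisy GM-like voxel: a bmax=1200 fit must lose to the full fit
        rng = np.random.default_rng(8)
        p = QDIParams(d12=0.8e-3, alpha=0.88)
        signal = 1000.0 * np.atleast_1d(qdi_attenuation(ds1_scheme.bvals, p))
        noisy = qdi.add_rician_noise(signal, 10.0, seed=15)
        curve = powder_average(noisy[None, :], ds1_scheme).curve(0)
        full_fit = fit_decay(curve)
        trunc_fit = fit_decay(curve.truncated(1200.0))
        assert mse_log(trunc_fit.params, curve) >= mse_log(full_fit.params, curve)

    def test_local_optimality(self, ds1_scheme):
        rng = np.random.default_rng(21)
        p = QDIParams(d12=1e-3, alpha=0.8)
        signal = 1000.0 * np.atleast_1d(qdi_attenuation(ds1_scheme.bvals, p))
        noisy = qdi.add_rician_noise(signal, 20.0, seed=3)
        curve = powder_average(noisy[None, :], ds1_scheme).curve(0)
        best = fit_decay(curve)
        base = mse_log(best.params, curve)
        for _ in range(100):
            d = best.params.d12 * float(rng.uniform(0.9, 1.1))
            a = float(np.clip(best.params.alpha * rng.uniform(0.95, 1.05), 0.05, 1.0))
            assert mse_log(QDIParams(d12=d, alpha=a), curve) >= base - 1e-12

    def test_no_valid_points_raises(self):
        curve = DecayCurve(b=np.array([0.0, 1000.0]), s_norm=np.array([1.0, np.nan]),
                           valid=np.array([True, False]))
        with pytest.raises(InsufficientDataError):
            mse_log(QDIParams(d12=1e-3, alpha=0.9), curve)


class TestFitVolume:
    def test_phantom_round_trip_zero_noise(self, ds1_scheme, small_ip_table):
        spec = qdi.default_phantom_spec(shape=(3, 3, 2), snr_b0=np.inf, seed=1)
        data, truth, _ = qdi.make_phantom(spec, ds1_scheme)
        maps = fit_volume(data, ds1_scheme, mask=truth.mask, ip_table=small_ip_table)
        assert np.nanmean(np.abs(maps.alpha_map - truth.alpha_map)) <= 1e-6
        assert np.nanmax(np.abs(maps.d12_map / truth.d12_map - 1.0)) <= 1e-5

    def test_all_invalid_voxel_continues(self, ds1_short_scheme):
        data = np.zeros((2, 1, 1, len(ds1_short_scheme)))
        data[0, 0, 0] = 1000.0 * np.atleast_1d(
            qdi_attenuation(ds1_short_scheme.bvals, QDIParams(d12=1e-3, alpha=0.9)))
        maps = fit_volume(data, ds1_short_scheme, ip_table=qdi.build_ip_table(
            d12_range=(5e-4, 2e-3), alpha_range=(0.5, 0.95), n_d12=4, n_alpha=4))
        assert np.isfinite(maps.d12_map[0, 0, 0])
        assert np.isnan(maps.d12_map[1, 0, 0])

    def test_determinism(self, ds1_short_scheme, small_ip_table):
        spec = qdi.default_phantom_spec(shape=(3, 3, 1), snr_b0=40.0, seed=9)
        data, truth, _ = qdi.make_phantom(spec, ds1_short_scheme)
        m1 = fit_volume(data, ds1_short_scheme, mask=truth.mask, ip_table=small_ip_table)
        m2 = fit_volume(data, ds1_short_scheme, mask=truth.mask, ip_table=small_ip_table)
        assert np.array_equal(m1.d12_map, m2.d12_map, equal_nan=True)
        assert np.array_equal(m1.alpha_map, m2.alpha_map, equal_nan=True)

    def test_empty_mask_raises(self, ds1_short_scheme):
        data = np.ones((2, 2, 1, len(ds1_short_scheme)))
        with pytest.raises(ValueError):
            fit_volume(data, ds1_short_scheme, mask=np.zeros((2, 2, 1), bool))

    def test_mask_shape_mismatch(self, ds1_short_scheme):
        data = np.ones((2, 2, 1, len(ds1_short_scheme)))
        with pytest.raises(GeometryError):
            fit_volume(data, ds1_short_scheme, mask=np.ones((3, 2, 1), bool))
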