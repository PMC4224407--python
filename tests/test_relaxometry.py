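"""Inversion-recovery model, pixel fitting and fat-reference correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgemric import (
    AcquisitionProtocol,
    FatReference,
    IRSeries,
    apply_normalization,
    fit_t1_map,
    fit_t1_pixel,
    ir_signal,
    normalization_factors,
)
from dgemric.errors import CorrectionError, InputError, ProtocolError, StateError
from dgemric.relaxometry import SeriesMeta, T1_VALID_MAX_MS, T1_VALID_MIN_MS


class TestProtocol:
    def test_defaults_match_acquisition(self, protocol):
        assert protocol.tr_ms == 1800.0
        assert protocol.te_ms == 13.0
        assert protocol.ti_ms == (50.0, 150.0, 350.0, 700.0, 1050.0, 1400.0, 2000.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tr_ms": -1.0},
            {"ti_ms": (100.0, 50.0)},  # not increasing
            {"ti_ms": (0.0, 100.0)},  # nonpositive
            {"ti_ms": (100.0, 5000.0)},  # >= 2*TR
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        with pytest.raises(ProtocolError):
            AcquisitionProtocol(**kwargs)


class TestIrSignal:
    def test_direct_evaluation(self):
        # 100*|1 - 2e^(-0.7) + e^(-1.8)| evaluated independently
        assert ir_signal(700.0, 1000.0, 100.0, 1800.0) == pytest.approx(
            17.2128, abs=5e-5
        )

    def test_short_t1_limit_recovers_amplitude(self):
        # as T1 -> 0 both exponentials vanish and S -> S0
        assert ir_signal(700.0, 1e-3, 123.0, 1800.0) == pytest.approx(123.0, abs=1e-6)

    @given(
        ti=st.floats(10.0, 2000.0),
        t1=st.floats(50.0, 3000.0),
        s0=st.floats(1.0, 1e4),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_in_amplitude(self, ti, t1, s0, c):
        lhs = ir_signal(ti, t1, c * s0, 1800.0)
        rhs = c * ir_signal(ti, t1, s0, 1800.0)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(InputError):
            ir_signal(700.0, 0.0, 100.0, 1800.0)
        with pytest.raises(InputError):
            ir_signal(700.0, 1000.0, 100.0, -5.0)


class TestFitPixel:
    @pytest.mark.parametrize("t1_true", [450.0, 700.0, 900.0, 1100.0, 1400.0])
    def test_noiseless_roundtrip(self, protocol, t1_true):
        y = ir_signal(np.array(protocol.ti_ms), t1_true, 50.0, protocol.tr_ms)
        t1, s0, rss, ok = fit_t1_pixel(y, protocol)
        assert ok
        assert t1 == pytest.approx(t1_true, abs=0.1)
        assert s0 == pytest.approx(50.0, rel=1e-4)

    def test_scale_invariance(self, protocol):
        y = ir_signal(np.array(protocol.ti_ms), 900.0, 50.0, protocol.tr_ms)
        t1a, s0a, *_ = fit_t1_pixel(y, protocol)
        t1b, s0b, *_ = fit_t1_pixel(10.0 * y, protocol)
        assert t1b == pytest.approx(t1a, rel=1e-6)
        assert s0b == pytest.approx(10.0 * s0a, rel=1e-6)

    def test_validity_window_includes_1300(self, protocol):
        y = ir_signal(np.array(protocol.ti_ms), 1300.0, 80.0, protocol.tr_ms)
        t1, _, _, ok = fit_t1_pixel(y, protocol)
        assert ok and T1_VALID_MIN_MS <= t1 <= T1_VALID_MAX_MS

    def test_all_zero_signals_flagged(self, protocol):
        t1, s0, rss, ok = fit_t1_pixel(np.zeros(7), protocol)
        assert not ok

    def test_optimum_never_worse_than_grid_start(self, protocol):
        # the simplex may only improve on the coarse-grid initializer
        ti = np.array(protocol.ti_ms)
        for t1_true in np.linspace(300.0, 1600.0, 14):
            y = ir_signal(ti, t1_true, 60.0, protocol.tr_ms)
            grid = np.arange(200.0, 2000.1, 100.0)
            best_grid = min(
                float(((ir_signal(ti, g, y.max(), protocol.tr_ms) - y) ** 2).sum())
                for g in grid
            )
            *_, rss, ok = fit_t1_pixel(y, protocol)
            assert ok and rss <= best_grid + 1e-12


def _uniform_series(protocol, t1, s0=100.0, shape=(6, 6), meta=None):
    ti = np.array(protocol.ti_ms)
    img = np.broadcast_to(
        ir_signal(ti, t1, s0, protocol.tr_ms)[:, None, None], (7, *shape)
    ).copy()
    return IRSeries(images=img, protocol=protocol, meta=meta or SeriesMeta())


class TestFitMap:
    def test_noiseless_map_recovers_t1(self, protocol):
        series = _uniform_series(protocol, 916.16)
        t1map = fit_t1_map(series)
        assert t1map.valid.all()
        assert np.allclose(t1map.t1_ms, 916.16, atol=0.1)

    def test_fat_t1_below_window_is_invalid(self, protocol):
        series = _uniform_series(protocol, 380.0)
        t1map = fit_t1_map(series)
        assert np.allclose(t1map.t1_ms, 380.0, atol=0.5)
        assert not t1map.valid.any()

    def test_empty_mask_gives_all_invalid(self, protocol):
        series = _uniform_series(protocol, 900.0)
        t1map = fit_t1_map(series, roi_mask=np.zeros((6, 6), dtype=bool))
        assert not t1map.valid.any()
        assert np.isnan(t1map.t1_ms).all()

    def test_mask_shape_mismatch_rejected(self, protocol):
        series = _uniform_series(protocol, 900.0)
        with pytest.raises(InputError):
            fit_t1_map(series, roi_mask=np.ones((3, 3), dtype=bool))

    def test_global_scale_invariance(self, protocol):
        series = _uniform_series(protocol, 700.0, shape=(4, 4))
        scaled = IRSeries(images=3.7 * series.images, protocol=protocol)
        a = fit_t1_map(series)
        b = fit_t1_map(scaled)
        assert np.allclose(a.t1_ms, b.t1_ms, rtol=1e-6)

    def test_never_valid_outside_window(self, protocol):
        # T1 above the 1500 ms cutoff fits fine but must be excluded
        series = _uniform_series(protocol, 1700.0, shape=(3, 3))
        t1map = fit_t1_map(series)
        assert np.allclose(t1map.t1_ms, 1700.0, atol=1.0)
        assert not t1map.valid.any()


CORRUPTION = np.array([0.6, 1.4, 0.8, 1.9, 0.5, 1.1, 1.7])


def _disc_and_fat_series(protocol, disc_t1=900.0, fat_t1=380.0, factors=None):
    """12x12 frame: disc block at rows 6:12, fat block at rows 0:3."""
    ti = np.array(protocol.ti_ms)
    img = np.zeros((7, 12, 12))
    img[:, 6:12, :] = ir_signal(ti, disc_t1, 100.0, protocol.tr_ms)[:, None, None]
    img[:, 0:3, :] = ir_signal(ti, fat_t1, 100.0, protocol.tr_ms)[:, None, None]
    if factors is not None:
        img = img * np.asarray(factors)[:, None, None]
    fat_mask = np.zeros((12, 12), dtype=bool)
    fat_mask[0:3, :] = True
    disc_mask = np.zeros((12, 12), dtype=bool)
    disc_mask[6:12, :] = True
    return IRSeries(images=img, protocol=protocol), fat_mask, disc_mask


class TestNormalization:
    def test_clean_series_yields_constant_factors(self, protocol):
        series, fat_mask, disc_mask = _disc_and_fat_series(protocol)
        fat = normalization_factors(series, FatReference(380.0, fat_mask))
        assert np.allclose(fat.factors, fat.factors[0], rtol=1e-9)
        corrected = apply_normalization(series, fat)
        a = fit_t1_map(series, disc_mask)
        b = fit_t1_map(corrected, disc_mask)
        assert np.allclose(a.t1_ms[disc_mask], b.t1_ms[disc_mask], atol=1e-3)

    def test_corruption_correction_roundtrip(self, protocol):
        clean, fat_mask, disc_mask = _disc_and_fat_series(protocol)
        bad, *_ = _disc_and_fat_series(protocol, factors=CORRUPTION)
        fat = normalization_factors(bad, FatReference(380.0, fat_mask))
        fixed = fit_t1_map(apply_normalization(bad, fat), disc_mask)
        ref = fit_t1_map(clean, disc_mask)
        assert np.allclose(
            fixed.t1_ms[disc_mask], ref.t1_ms[disc_mask], atol=0.1
        )

    def test_factor_times_corruption_is_constant(self, protocol):
        bad, fat_mask, _ = _disc_and_fat_series(protocol, factors=CORRUPTION)
        fat = normalization_factors(bad, FatReference(380.0, fat_mask))
        prod = fat.factors * CORRUPTION
        assert np.allclose(prod, prod[0], rtol=1e-6)

    def test_corrected_fat_means_on_expected_curve(self, protocol):
        from dgemric.relaxometry import expected_fat_curve

        bad, fat_mask, _ = _disc_and_fat_series(protocol, factors=CORRUPTION)
        fat = normalization_factors(bad, FatReference(380.0, fat_mask))
        corrected = apply_normalization(bad, fat)
        means = corrected.images[:, fat_mask].mean(axis=1)
        e = expected_fat_curve(protocol, 380.0)
        scale = means[0] / e[0]
        assert np.allclose(means, scale * e, rtol=1e-9)

    def test_unit_factors_leave_images_bitwise_equal(self, protocol):
        series, fat_mask, _ = _disc_and_fat_series(protocol)
        fat = FatReference(380.0, fat_mask, factors=np.ones(7))
        out = apply_normalization(series, fat)
        assert np.array_equal(out.images, series.images)

    def test_double_application_warns(self, protocol):
        series, fat_mask, _ = _disc_and_fat_series(protocol)
        fat = FatReference(380.0, fat_mask, factors=np.ones(7))
        once = apply_normalization(series, fat)
        with pytest.warns(UserWarning, match="already"):
            apply_normalization(once, fat)

    def test_missing_factors_is_state_error(self, protocol):
        series, fat_mask, _ = _disc_and_fat_series(protocol)
        with pytest.raises(StateError):
            apply_normalization(series, FatReference(380.0, fat_mask))

    def test_empty_fat_region_rejected(self, protocol):
        series, _, _ = _disc_and_fat_series(protocol)
        with pytest.raises(CorrectionError):
            normalization_factors(
                series, FatReference(380.0, np.zeros((12, 12), dtype=bool))
            )

    def test_zero_fat_mean_rejected(self, protocol):
        series, fat_mask, _ = _disc_and_fat_series(protocol)
        series.images[2, fat_mask] = 0.0
        with pytest.raises(CorrectionError):
            normalization_factors(series, FatReference(380.0, fat_mask))
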