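import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wtdpsd import (
    ConfigurationError,
    DegenerateSeriesError,
    FeatureConfig,
    ImageSample,
    MomentSet,
    PseudoTimeSeries,
    ShortSeriesError,
    extract_features,
    power_transform,
    raw_moments,
    subband_to_series,
    tdpsd_features,
)
from wtdpsd.tdpsd import FEATURE_COLUMNS
from wtdpsd.synthetic import SyntheticSpec, generate


def series(values):
    return PseudoTimeSeries(np.asarray(values, dtype=np.float64))


class TestZeroRemoval:
    def test_removes_exact_zeros_preserving_order(self):
        s = subband_to_series(np.array([[0.0, 1.0], [2.0, 0.0]]), 0.0)
        assert np.array_equal(s.values, [1.0, 2.0])
        assert s.removed_count == 2
        assert s.original_count == 4

    def test_all_zero_band_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            subband_to_series(np.zeros((4, 4)), 0.0)

    def test_no_zeros_is_identity(self, rng):
        m = rng.uniform(1.0, 2.0, size=(6, 6))
        s = subband_to_series(m, 0.0)
        assert s.removed_count == 0
        assert np.array_equal(s.values, m.ravel())

    @given(st.floats(0.0, 10.0))
    @settings(deadline=None, derandomize=True)
    def test_tolerance_strips_small_magnitudes(self, tol):
        m = np.array([[-20.0, 5.0, -5.0, 15.0]])
        try:
            s = subband_to_series(m, tol)
        except DegenerateSeriesError:
            assert tol >= 20.0
            return
        assert np.all(np.abs(s.values) > tol)
        assert s.original_count == s.values.size + s.removed_count


class TestMoments:
    def test_hand_computed_values(self):
        m = raw_moments(series([1.0, 2.0, 3.0]))
        assert m.m0_raw == pytest.approx(math.sqrt(14), rel=1e-12)
        assert m.m2_raw == pytest.approx(math.sqrt(2), rel=1e-12)
        assert m.m4_raw == 0.0

    def test_constant_series_differences_vanish(self):
        c = -4.0
        m = raw_moments(series([c] * 4))
        assert m.m0_raw == pytest.approx(2 * abs(c))
        assert m.m2_raw == 0.0
        assert m.m4_raw == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            raw_moments(series([1.0, 2.0]))

    def test_parseval_total_power(self, rng):
        # zero-order moment squared equals the DFT power-spectrum sum
        for _ in range(50):
            x = rng.normal(size=rng.integers(8, 200))
            X = np.fft.fft(x)
            power_sum = float(np.sum(X * np.conj(X)).real) / len(x)
            m = raw_moments(PseudoTimeSeries(x))
            assert m.m0_raw**2 == pytest.approx(power_sum, rel=1e-8)

    def test_parseval_second_moment_of_differenced_series(self, rng):
        # the time-domain sum of squared first differences equals the
        # spectrum power of the differenced series (Parseval again)
        for _ in range(20):
            x = rng.normal(size=rng.integers(8, 200))
            d = np.diff(x)
            D = np.fft.fft(d)
            power_sum = float(np.sum(D * np.conj(D)).real) / len(d)
            m = raw_moments(PseudoTimeSeries(x))
            assert m.m2_raw**2 == pytest.approx(power_sum, rel=1e-6)


class TestPowerTransform:
    @pytest.mark.parametrize(
        "m_raw,lam,expected",
        [
            (1.0, 0.1, 10.0),
            (0.0, 0.1, 0.0),
            (math.sqrt(14), 0.1, 11.410545360838226),
        ],
    )
    def test_examples(self, m_raw, lam, expected):
        m = power_transform(MomentSet(m_raw, m_raw, m_raw), lam)
        assert m.m0 == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("lam", [0.0, -0.5])
    def test_nonpositive_lambda_rejected(self, lam):
        with pytest.raises(ConfigurationError):
            power_transform(MomentSet(1.0, 1.0, 1.0), lam)
        with pytest.raises(ConfigurationError):
            FeatureConfig(lam=lam)


class TestFeatures:
    def test_frozen_regression_vector(self):
        # frozen from an independent straight-line computation of the
        # seven descriptors for the series [1, 2, 3] at lambda = 0.1
        expected = [
            2.434537959475,
            0.056282145652,
            2.434537959475,
            -0.056282145652,
            0.0,
            -0.895879734614,
            0.0,
        ]
        feats, flags = tdpsd_features(series([1.0, 2.0, 3.0]), 0.1)
        assert feats == pytest.approx(expected, abs=1e-10)
        assert "f5_degenerate" in flags

    def test_teager_energy_of_cosine_matches_closed_form(self):
        # for x[n] = A cos(w n) the summed Teager energy approaches
        # N * A^2 * sin^2(w)
        N, A, w = 1024, 2.0, 0.3
        x = A * np.cos(w * np.arange(N))
        teo = float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]))
        closed = N * A**2 * math.sin(w) ** 2
        assert abs(teo - closed) / closed < 0.02
        feats, _ = tdpsd_features(PseudoTimeSeries(x), 0.1)
        assert feats[6] == pytest.approx(math.log(teo), rel=1e-10)

    @pytest.mark.parametrize("s", [2.0, 10.0])
    def test_scaling_shifts_f1_by_lambda_log_s(self, s, rng):
        lam = 0.1
        x = rng.normal(size=100)
        base, _ = tdpsd_features(PseudoTimeSeries(x), lam)
        scaled, _ = tdpsd_features(PseudoTimeSeries(s * x), lam)
        assert scaled[0] - base[0] == pytest.approx(lam * math.log(s), rel=1e-9)

    @pytest.mark.parametrize("s", [0.5, 2.0, 1000.0])
    def test_f5_is_scale_invariant(self, s, rng):
        x = rng.normal(size=200)
        base, _ = tdpsd_features(PseudoTimeSeries(x), 0.1)
        scaled, _ = tdpsd_features(PseudoTimeSeries(s * x), 0.1)
        assert abs(scaled[4] - base[4]) < 1e-10

    def test_constant_series_routes_to_sentinels(self):
        feats, flags = tdpsd_features(series([3.0, 3.0, 3.0, 3.0]), 0.1)
        assert feats[4] == 0.0  # 0/0 irregularity sentinel
        assert "f5_degenerate" in flags
        assert "f7_nonpositive" in flags  # zero Teager sum hits the log guard
        assert np.all(np.isfinite(feats))


class TestExtractFeatures:
    def test_any_image_yields_exactly_49_finite_values(self, rng):
        img = ImageSample(rng.uniform(0, 255, size=(256, 256)), id="r")
        fv = extract_features(img)
        assert fv.values.shape == (49,)
        assert np.all(np.isfinite(fv.values))
        assert len(FEATURE_COLUMNS) == 49

    def test_bit_identical_images_give_bit_identical_features(self, rng):
        pixels = rng.uniform(0, 255, size=(64, 64))
        a = extract_features(ImageSample(pixels.copy(), id="a"))
        b = extract_features(ImageSample(pixels.copy(), id="b"))
        assert np.array_equal(a.values, b.values)

    def test_all_zero_image_gives_flagged_sentinel_rows(self):
        fv = extract_features(ImageSample(np.zeros((64, 64)), id="z"))
        assert sorted(fv.sentinel_bands) == sorted(
            ["LH1", "HL1", "HH1", "LL2", "LH2", "HL2", "HH2"]
        )
        assert np.all(fv.values == 0.0)
        assert all(fv.flags[b] == ["sentinel"] for b in fv.sentinel_bands)

    def test_disjoint_texture_frequencies_change_irregularity(self):
        # two grating phantoms with well-separated dominant frequencies
        # should differ in the irregularity factor in most subbands
        lo, _ = generate(
            SyntheticSpec(n_per_class=1, image_size=256, class_signal=1.0,
                          seed=5, phantom_kind="texture", noise_sigma=0.0)
        )
        hc = next(s for s in lo if s.label == "HC")
        ad = next(s for s in lo if s.label == "AD")
        f_hc = extract_features(hc).values.reshape(7, 7)
        f_ad = extract_features(ad).values.reshape(7, 7)
        n_diff = int(np.sum(np.abs(f_hc[:, 4] - f_ad[:, 4]) > 1e-3))
        assert n_diff >= 4

    def test_normalize_m0_changes_only_moment_features(self, rng):
        img = ImageSample(rng.uniform(0, 255, size=(64, 64)), id="n")
        plain = extract_features(img, FeatureConfig())
        normed = extract_features(img, FeatureConfig(normalize_m0=True))
        a, b = plain.values.reshape(7, 7), normed.values.reshape(7, 7)
        # f6 and f7 are computed from the series itself, not the moments
        assert np.allclose(a[:, 5], b[:, 5])
        assert np.allclose(a[:, 6], b[:, 6])
        assert not np.allclose(a[:, 0], b[:, 0])
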