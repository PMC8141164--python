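import numpy as np
import pytest

import restmotion as rm
from restmotion import features as F
from restmotion.errors import ShapeError
from restmotion.features import EntropyParams, UndefinedFeatureError

from conftest import zero_recording
from oracles import apen_oracle, fuzzyen_oracle

RATE = 50.0
T = np.arange(750) / RATE
SINE_5HZ = np.sin(2 * np.pi * 5.0 * T)  # 75 whole periods


class TestAmplitudeFeatures:
    def test_rms_closed_form_sine(self):
        assert F.rms(SINE_5HZ) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_rms_zeros(self):
        assert F.rms(np.zeros(10)) == 0.0

    def test_peak(self):
        assert F.peak([-3.0, 2.0]) == 2.0
        # cosine phase puts a sample exactly on the crest
        assert F.peak(np.cos(2 * np.pi * 5.0 * T)) == pytest.approx(1.0, rel=0.01)

    def test_mavfd_example(self):
        assert F.mavfd([0.0, 1.0, 0.0, 1.0]) == 1.0

    def test_mavsd_linear_ramp(self):
        ramp = np.arange(20) * 0.3
        assert F.mavsd(ramp) == pytest.approx(0.6)

    def test_loop_oracles(self, rng):
        x = rng.normal(size=97)
        assert F.rms(x) == pytest.approx(
            np.sqrt(sum(v * v for v in x) / len(x)), abs=1e-12
        )
        assert F.peak(x) == max(x)
        assert F.mav(x) == pytest.approx(sum(abs(v) for v in x) / len(x), abs=1e-12)
        assert F.mavfd(x) == pytest.approx(
            sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1),
            abs=1e-12,
        )
        assert F.mavsd(x) == pytest.approx(
            sum(abs(x[i + 2] - x[i]) for i in range(len(x) - 2)) / (len(x) - 2),
            abs=1e-12,
        )

    def test_preconditions(self):
        with pytest.raises(ShapeError):
            F.rms(np.array([]))
        with pytest.raises(ShapeError):
            F.mavfd([1.0])
        with pytest.raises(ShapeError):
            F.mavsd([1.0, 2.0])


class TestSpectrum:
    def test_pure_sine_single_dominant_bin(self):
        spec = F.power_spectrum(SINE_5HZ, RATE)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(5.0)
        assert spec.power.max() / spec.total_power > 0.99

    def test_parseval(self, rng):
        x = rng.normal(size=750)
        x -= x.mean()
        spec = F.power_spectrum(x, RATE)
        assert spec.total_power == pytest.approx(np.mean(x * x), rel=0.01)

    def test_white_noise_flat(self, rng):
        x = rng.normal(size=50_000)
        spec = F.power_spectrum(x, RATE, estimator="welch")
        inner = spec.power[1:-1]
        assert inner.max() / inner.mean() < 2.0

    def test_zero_signal_zero_spectrum(self):
        spec = F.power_spectrum(np.zeros(750), RATE)
        np.testing.assert_array_equal(spec.power, 0.0)

    def test_grid_monotone(self):
        spec = F.power_spectrum(SINE_5HZ, RATE)
        assert np.all(np.diff(spec.frequencies) > 0)
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[-1] == pytest.approx(RATE / 2)


class TestSpectralFeatures:
    def test_pure_sine_centroids(self):
        spec = F.power_spectrum(np.sin(2 * np.pi * 8.0 * T), RATE)
        step = spec.frequencies[1] - spec.frequencies[0]
        for fn in (F.fmean, F.fpeak, F.f50, F.f80):
            assert abs(fn(spec) - 8.0) <= step

    def test_two_line_mean(self):
        y = np.sin(2 * np.pi * 4.0 * T) + np.sin(2 * np.pi * 12.0 * T)
        spec = F.power_spectrum(y, RATE)
        assert F.fmean(spec) == pytest.approx(8.0, abs=0.1)

    def test_band_power_contains_5hz_line(self):
        spec = F.power_spectrum(SINE_5HZ, RATE)
        assert F.power_band(spec) / spec.total_power >= 0.95

    def test_band_power_by_direct_summation(self, rng):
        x = rng.normal(size=750)
        spec = F.power_spectrum(x, RATE)
        mask = (spec.frequencies >= 3.5) & (spec.frequencies <= 7.5)
        assert F.power_band(spec) == pytest.approx(float(spec.power[mask].sum()))
        assert F.power_band(spec) <= spec.total_power

    def test_quantile_order(self, rng):
        x = rng.normal(size=750)
        spec = F.power_spectrum(x, RATE)
        assert 0 <= F.f50(spec) <= F.f80(spec) <= RATE / 2

    def test_zero_spectrum_undefined(self):
        spec = F.power_spectrum(np.zeros(750), RATE)
        for fn in (F.fmean, F.fpeak, F.f50, F.f80):
            with pytest.raises(UndefinedFeatureError):
                fn(spec)


class TestZeroCrossing:
    def test_sine_closed_form(self):
        # 5 Hz over 15 s: 2 * 5 * 15 = 150 crossings (boundary +/- 1)
        assert abs(F.zero_crossing(SINE_5HZ) - 150) <= 1

    def test_constant_no_crossings(self):
        assert F.zero_crossing(np.full(10, 3.0)) == 0

    def test_zeros_attach_to_preceding_sign(self):
        assert F.zero_crossing([1.0, 0.0, 1.0]) == 0
        assert F.zero_crossing([1.0, 0.0, -1.0]) == 1

    def test_sign_change_loop_oracle(self, rng):
        x = rng.normal(size=200)
        signs = np.sign(x)
        count = 0
        prev = None
        for s in signs:
            if s == 0:
                continue  # oracle: zeros carry the previous sign
            if prev is not None and s != prev:
                count += 1
            prev = s
        assert F.zero_crossing(x) == count


class TestEntropies:
    def test_apen_constant_is_zero(self):
        assert F.apen(np.full(30, 2.5)) == 0.0

    def test_apen_matches_bruteforce(self, rng):
        x = rng.normal(size=50)
        assert F.apen(x) == pytest.approx(apen_oracle(x), abs=1e-10)

    def test_fuzzyen_matches_bruteforce(self, rng):
        x = rng.normal(size=50)
        assert F.fuzzyen(x) == pytest.approx(fuzzyen_oracle(x), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_sine_more_regular_than_shuffle(self, seed):
        t = np.arange(300) / RATE
        sine = np.sin(2 * np.pi * 5.0 * t)
        shuffled = np.random.default_rng(seed).permutation(sine)
        assert F.apen(sine) < F.apen(shuffled)
        assert F.fuzzyen(sine) < F.fuzzyen(shuffled)

    def test_offset_invariance(self, rng):
        x = rng.normal(size=80)
        assert F.fuzzyen(x + 100.0) == pytest.approx(F.fuzzyen(x), abs=1e-9)
        assert F.apen(x + 100.0) == pytest.approx(F.apen(x), abs=1e-9)

    def test_nonnegative(self, rng):
        x = rng.normal(size=120)
        assert F.apen(x) >= -1e-12
        assert F.fuzzyen(x) >= -1e-12

    def test_short_signal_rejected(self):
        with pytest.raises(ShapeError):
            F.apen(np.ones(3), EntropyParams(m=2))
        with pytest.raises(ShapeError):
            F.fuzzyen(np.ones(3), EntropyParams(m=2))


class TestVariabilityAndShape:
    def test_variance_example(self):
        assert F.variance([1.0, 2.0, 3.0]) == 1.0

    def test_range_sine(self):
        assert F.range_(np.cos(2 * np.pi * 5.0 * T)) == pytest.approx(2.0, rel=0.01)

    def test_iqr_quantile_oracle(self, rng):
        x = rng.normal(size=101)
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation rule
        assert F.intla(x) == pytest.approx(q3 - q1, abs=1e-12)

    def test_skewness_symmetric(self):
        assert F.skewness(np.array([-1.0, 1.0] * 20)) == pytest.approx(0.0, abs=1e-12)

    def test_kurtosis_gaussian_non_excess(self):
        x = np.random.default_rng(0).normal(size=100_000)
        assert F.kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_moment_loop_oracle(self, rng):
        x = rng.normal(size=64)
        n = len(x)
        mean = sum(x) / n
        sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        assert F.skewness(x) == pytest.approx(m3 / sd**3, abs=1e-12)
        assert F.kurtosis(x) == pytest.approx(m4 / sd**4, abs=1e-12)


class TestExtractFeatures:
    def test_vector_has_108_unique_names(self, sample_recording):
        vec = rm.extract_features(sample_recording)
        assert len(vec.names) == 108
        assert len(set(vec.names)) == 108
        assert vec.values.shape == (108,)

    def test_36_accelerometer_features(self, sample_recording):
        vec = rm.extract_features(sample_recording)
        acc = [n for n in vec.names if n.startswith(("acc1.", "acc2."))]
        assert len(acc) == 36

    def test_order_sensor_by_feature(self, sample_recording):
        vec = rm.extract_features(sample_recording)
        expected = [
            f"{sensor}.{feat}"
            for sensor in rm.RESULTANT_ORDER
            for feat in rm.FEATURE_NAMES
        ]
        assert vec.names == expected

    def test_deterministic(self, sample_recording):
        a = rm.extract_features(sample_recording)
        b = rm.extract_features(sample_recording)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_zero_recording_flags(self):
        with pytest.warns(UserWarning):
            vec = rm.extract_features(zero_recording())
        vals = vec.as_dict()
        for sensor in rm.RESULTANT_ORDER:
            for feat in ("rms", "peak", "mav", "mavfd", "mavsd", "bandpower",
                         "variance", "range", "iqr", "apen", "fuzzyen"):
                assert vals[f"{sensor}.{feat}"] == 0.0
            assert vals[f"{sensor}.zero_crossing"] == 0.0
            for feat in ("fmean", "fpeak", "f50", "f80", "skewness", "kurtosis"):
                assert np.isnan(vals[f"{sensor}.{feat}"])

    def test_feature_table_shape(self, default_table):
        assert default_table.shape == (27, 111)  # meta + 108 features
        assert list(default_table.columns[:3]) == ["subject_id", "label", "hy"]
        assert default_table.label.value_counts()["PD"] == 15
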