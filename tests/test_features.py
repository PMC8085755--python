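import numpy as np
import pytest

from toponet.features import (FEATURE_NAMES, WindowGeometry, abs_energy,
                              autocorrelation, c3, default_registry,
                              extract_feature_vector, extract_sequence, slope)
from .conftest import make_record
from .oracles import (naive_abs_energy, naive_autocorrelation, naive_c3,
                      naive_feature_vector, naive_slope)


class TestPrimitives:
    def test_abs_energy(self):
        assert abs_energy([1, 2, 3]) == 14
        assert abs_energy(np.zeros(10)) == 0
        assert abs_energy(np.full(20, 3.0)) == pytest.approx(20 * 9)
        with pytest.raises(ValueError):
            abs_energy([])

    def test_autocorrelation_degenerate_and_alternating(self):
        assert autocorrelation(np.full(20, 5.0), 3) == 0.0
        alternating = np.tile([1.0, -1.0], 20)
        assert autocorrelation(alternating, 1) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0), 5)

    def test_autocorrelation_iid_noise_centres_on_zero(self):
        vals = [autocorrelation(np.random.default_rng(s).normal(size=120), 40)
                for s in range(1000)]
        assert abs(np.mean(vals)) < 0.05

    def test_c3(self):
        assert c3(np.full(10, 2.0), 3) == pytest.approx(8.0)
        assert c3([1, 2, 3, 4, 5, 6], 1) == pytest.approx(52.5)
        with pytest.raises(ValueError):
            c3(np.arange(6.0), 3)

    def test_slope(self):
        assert slope([1, 2, 3]) == pytest.approx(1.0)
        assert slope(np.full(10, 4.0)) == pytest.approx(0.0)
        assert slope([0, 2, 4, 6]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            slope([1.0])

    def test_primitives_match_naive_oracles(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            x = rng.uniform(-50, 150, size=int(rng.integers(10, 40)))
            xs = x.tolist()
            assert abs_energy(x) == pytest.approx(naive_abs_energy(xs), abs=1e-9)
            assert slope(x) == pytest.approx(naive_slope(xs), abs=1e-9)
            assert c3(x, 2) == pytest.approx(naive_c3(xs, 2), abs=1e-9)
            lag = int(rng.integers(1, len(x)))
            assert autocorrelation(x, lag) == pytest.approx(
                naive_autocorrelation(xs, lag), abs=1e-9)


class TestFeatureVector:
    def test_registry_names_and_order(self):
        assert FEATURE_NAMES == (
            "hr_mean", "hr_std", "hr_sum", "hr_slope", "hr_abs_energy",
            "hr_c2", "hr_c3", "hr_quantiles_01", "hr_quantiles_03",
            "hr_quantiles_07",
            "resp_mean", "resp_std", "resp_slope", "resp_abs_energy", "resp_c3",
            "spo2_mean", "spo2_std", "spo2_slope", "spo2_c3", "spo2_abs_energy",
            "all_autocorrelation",
        )
        assert len(default_registry()) == 21

    def test_constant_hr_closed_forms(self):
        window = {"hr": np.full(20, 80.0), "rr": np.full(20, 16.0),
                  "spo2": np.full(20, 97.0)}
        v = dict(zip(FEATURE_NAMES, extract_feature_vector(window,
                                                           all_autocorrelation=0.0)))
        assert v["hr_mean"] == pytest.approx(80)
        assert v["hr_std"] == pytest.approx(0)
        assert v["hr_sum"] == pytest.approx(1600)
        assert v["hr_slope"] == pytest.approx(0)
        assert v["hr_abs_energy"] == pytest.approx(128000)
        assert v["hr_c2"] == pytest.approx(80 ** 3)
        for q in ("hr_quantiles_01", "hr_quantiles_03", "hr_quantiles_07"):
            assert v[q] == pytest.approx(80)
        assert v["resp_c3"] == pytest.approx(16 ** 3)
        assert v["spo2_std"] == pytest.approx(0)

    def test_vector_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            hr = rng.uniform(50, 150, 20)
            rr = rng.uniform(8, 40, 20)
            spo2 = rng.uniform(85, 100, 20)
            got = extract_feature_vector({"hr": hr, "rr": rr, "spo2": spo2},
                                         all_autocorrelation=0.3)
            want = naive_feature_vector(hr.tolist(), rr.tolist(), spo2.tolist(), 0.3)
            assert got == pytest.approx(want, abs=1e-9)

    def test_incomplete_window_errors(self):
        bad = {"hr": np.array([80.0, np.nan] + [80.0] * 18),
               "rr": np.full(20, 16.0), "spo2": np.full(20, 97.0)}
        with pytest.raises(ValueError):
            extract_feature_vector(bad)


class TestSequence:
    def test_default_geometry_shape(self):
        rng = np.random.default_rng(1)
        rec = make_record(rng.uniform(70, 90, 300), rng.uniform(12, 20, 300),
                          rng.uniform(94, 99, 300))
        seq = extract_sequence(rec, 120)
        assert seq.shape == (21, 21)

    def test_insufficient_history_errors(self):
        rec = make_record(np.full(119, 80.0))
        with pytest.raises(ValueError):
            extract_sequence(rec, 119)

    def test_constant_record_rows_identical(self):
        rec = make_record(np.full(200, 80.0))
        seq = extract_sequence(rec, 150)
        assert np.allclose(seq, seq[0])

    def test_cross_channel_autocorrelation_replicated(self):
        rng = np.random.default_rng(2)
        rec = make_record(rng.uniform(70, 90, 200), rng.uniform(12, 20, 200),
                          rng.uniform(94, 99, 200))
        seq = extract_sequence(rec, 200)
        col = seq[:, FEATURE_NAMES.index("all_autocorrelation")]
        assert np.allclose(col, col[0])
        # equals the mean over channels of the full-window lag-40 statistic
        from toponet.features import autocorrelation as ac
        want = np.mean([ac(rec.channels[c].values[80:200], 40)
                        for c in ("hr", "rr", "spo2")])
        assert col[0] == pytest.approx(want, abs=1e-12)

    def test_shift_on_periodic_signal_shifts_sequence(self):
        t = np.arange(400, dtype=float)
        hr = 80 + 10 * np.sin(2 * np.pi * t / 20)       # period = sub-window
        rr = 16 + 2 * np.sin(2 * np.pi * t / 20)
        spo2 = 97 + np.sin(2 * np.pi * t / 20)
        rec = make_record(hr, rr, spo2)
        a = extract_sequence(rec, 200)
        b = extract_sequence(rec, 220)  # shift by one period x stride
        assert np.allclose(a, b, atol=1e-8)

    def test_custom_geometry_step_count(self):
        geom = WindowGeometry(observing_window=60, sub_window=20, step=10,
                              autocorr_lag=40)
        rec = make_record(np.random.default_rng(0).uniform(70, 90, 100))
        assert extract_sequence(rec, 60, geom).shape == (5, 21)
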