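import numpy as np
import pytest

from accelpa import SignalRecording, read_raw_csv, reintegrate_to_20hz, trim, write_raw_csv
from accelpa.errors import (
    SignalFormatError,
    SignalParseError,
    SignalTimingError,
    UnsupportedRateError,
)


def make_rec(samples, rate=20.0, start=1000.0, subject="S1", site="hip"):
    return SignalRecording(subject, site, rate, start, np.asarray(samples, float))


class TestSimpleDialect:
    def test_read_counts_rows(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text(
            "# subject=S1\n# site=hip\n# rate_hz=20\n"
            "timestamp_iso8601,ax_g,ay_g,az_g\n"
            "2020-01-01T00:00:00+00:00,0.0,0.0,1.0\n"
            "2020-01-01T00:00:00.05+00:00,0.0,0.0,1.0\n"
            "2020-01-01T00:00:00.10+00:00,0.0,0.0,1.0\n"
            "2020-01-01T00:00:00.15+00:00,0.0,0.0,1.0\n"
        )
        rec = read_raw_csv(p)
        assert rec.n_samples == 4
        assert rec.duration_s == pytest.approx(0.2)
        assert rec.subject_id == "S1" and rec.site == "hip"

    def test_empty_file_is_empty_recording(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text(
            "# subject=S1\n# site=thigh\n# rate_hz=20\n"
            "# start=2020-01-01T00:00:00+00:00\n"
            "timestamp_iso8601,ax_g,ay_g,az_g\n"
        )
        rec = read_raw_csv(p)
        assert rec.n_samples == 0 and rec.site == "thigh"

    def test_malformed_header_raises_format_error(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("# subject=S1\n# site=hip\n# rate_hz=20\ntime,x,y,z\n")
        with pytest.raises(SignalFormatError):
            read_raw_csv(p)

    def test_non_uniform_spacing_raises_timing_error(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text(
            "# subject=S1\n# site=hip\n# rate_hz=20\n"
            "timestamp_iso8601,ax_g,ay_g,az_g\n"
            "2020-01-01T00:00:00+00:00,0,0,1\n"
            "2020-01-01T00:00:00.05+00:00,0,0,1\n"
            "2020-01-01T00:00:00.30+00:00,0,0,1\n"
        )
        with pytest.raises(SignalTimingError):
            read_raw_csv(p)

    def test_non_numeric_value_raises_parse_error_with_row(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text(
            "# subject=S1\n# site=hip\n# rate_hz=20\n"
            "timestamp_iso8601,ax_g,ay_g,az_g\n"
            "2020-01-01T00:00:00+00:00,0,0,1\n"
            "2020-01-01T00:00:00.05+00:00,0,oops,1\n"
        )
        with pytest.raises(SignalParseError, match="row 1"):
            read_raw_csv(p)

    @pytest.mark.parametrize("n", [0, 7, 600])
    def test_round_trip_lossless_to_1e6_g(self, tmp_path, rng, n):
        rec = make_rec(rng.normal(0, 1, size=(n, 3)), rate=20.0, start=1e9 + 0.25)
        path = tmp_path / "rt.csv"
        write_raw_csv(rec, path)
        back = read_raw_csv(path)
        assert back.n_samples == n
        assert back.allclose(rec, atol=1e-6)


class TestActigraphDialect:
    HEADER = (
        "------------ Data File Created By ActiGraph GT3X+ ActiLife v6.11.4 "
        "Firmware v2.5.0 date format M/d/yyyy at 40 Hz  Filter Normal ------------\n"
        "Serial Number: NEO1D123456\n"
        "Start Time 09:00:00\n"
        "Start Date 3/1/2016\n"
        "Epoch Period (hh:mm:ss) 00:00:00\n"
        "Download Time 11:00:00\n"
        "Download Date 3/1/2016\n"
        "Current Memory Address: 0\n"
        "Current Battery Voltage: 4.07     Mode = 12\n"
        "--------------------------------------------------\n"
    )

    def test_parse_header_and_rows(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text(
            self.HEADER
            + "Accelerometer X,Accelerometer Y,Accelerometer Z\n"
            + "0.004,-0.012,0.996\n0.008,-0.016,1.000\n"
        )
        rec = read_raw_csv(p, dialect="actigraph_raw", subject_id="S9", site="thigh")
        assert rec.sampling_rate_hz == 40.0
        assert rec.n_samples == 2
        assert rec.subject_id == "S9" and rec.site == "thigh"
        # 2016-03-01 09:00:00 UTC
        assert rec.start_time == pytest.approx(1456822800.0)

    def test_missing_rate_raises(self, tmp_path):
        p = tmp_path / "raw.csv"
        p.write_text("not a header\n0,0,1\n")
        with pytest.raises(SignalFormatError):
            read_raw_csv(p, dialect="actigraph_raw", site="hip")


class TestReintegration:
    def test_constant_signal_unchanged(self):
        rec = make_rec(np.tile([0.0, 0.0, 1.0], (8, 1)), rate=40.0)
        out = reintegrate_to_20hz(rec)
        assert out.sampling_rate_hz == 20.0
        assert out.n_samples == 4
        assert np.allclose(out.samples, [0.0, 0.0, 1.0])

    def test_pair_means_on_ramp(self):
        ramp = np.zeros((8, 3))
        ramp[:, 0] = np.arange(1, 9)
        out = reintegrate_to_20hz(make_rec(ramp, rate=40.0))
        assert np.allclose(out.samples[:, 0], [1.5, 3.5, 5.5, 7.5])

    def test_20hz_input_identity(self):
        rec = make_rec(np.ones((10, 3)), rate=20.0)
        assert reintegrate_to_20hz(rec) == rec

    def test_odd_trailing_sample_dropped(self):
        rec = make_rec(np.ones((9, 3)), rate=40.0)
        assert reintegrate_to_20hz(rec).n_samples == 4

    def test_other_rate_rejected(self):
        with pytest.raises(UnsupportedRateError):
            reintegrate_to_20hz(make_rec(np.ones((4, 3)), rate=30.0))

    def test_halves_count_and_preserves_mean(self, rng):
        rec = make_rec(rng.normal(size=(100, 3)), rate=40.0)
        out = reintegrate_to_20hz(rec)
        assert out.n_samples == 50
        assert np.allclose(out.samples.mean(axis=0), rec.samples.mean(axis=0))


class TestTrim:
    def test_full_span_identity(self, rng):
        rec = make_rec(rng.normal(size=(40, 3)), start=50.0)
        out = trim(rec, 50.0, 50.0 + rec.duration_s)
        assert out == rec

    def test_30s_window_has_600_samples(self, rng):
        rec = make_rec(rng.normal(size=(20 * 90 * 60, 3)), rate=20.0, start=0.0)
        assert trim(rec, 60.0, 90.0).n_samples == 600

    def test_boundary_sample_at_t1_excluded(self):
        rec = make_rec(np.arange(12).reshape(4, 3), rate=1.0, start=0.0)
        out = trim(rec, 0.0, 2.0)
        assert out.n_samples == 2  # samples at t=0,1; t=2 excluded

    def test_outside_interval_gives_empty(self):
        rec = make_rec(np.ones((4, 3)), rate=1.0, start=0.0)
        assert trim(rec, 100.0, 200.0).n_samples == 0

    def test_idempotent(self, rng):
        rec = make_rec(rng.normal(size=(50, 3)), rate=20.0, start=10.0)
        once = trim(rec, 10.7, 11.9)
        assert trim(once, 10.7, 11.9) == once
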