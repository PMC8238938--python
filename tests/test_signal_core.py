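"""Trace data model, signal-loss accounting, windowing, resampling and I/O."""

import numpy as np
import pytest

from ctgnet.signal_core import (
    CTGTrace,
    WindowSpec,
    compute_signal_loss,
    downsample,
    extract_last_window,
    interpolate_invalid,
    passes_quality,
    read_ctg_csv,
    read_wfdb_record,
    write_ctg_csv,
    write_wfdb_record,
)
from ctgnet.synthetic import TraceGenParams, generate_trace


class TestCTGTrace:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            CTGTrace(fhr=np.ones(10) * 140, uc=np.ones(9), fs=4.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            CTGTrace(fhr=np.array([]), uc=np.array([]), fs=4.0)

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            CTGTrace(fhr=np.full(4, 140.0), uc=np.zeros(4), fs=0.0)

    @pytest.mark.parametrize(
        "value, valid",
        [(140.0, True), (50.0, True), (210.0, True), (49.9, False),
         (210.1, False), (0.0, False), (np.nan, False)],
    )
    def test_validity_mask_inference(self, value, valid):
        tr = CTGTrace(fhr=np.array([140.0, value]), uc=np.zeros(2), fs=1.0)
        assert bool(tr.valid_fhr[1]) is valid


class TestSignalLoss:
    def test_all_valid_is_zero(self, constant_trace):
        assert compute_signal_loss(constant_trace) == 0.0

    def test_fraction_is_invalid_over_total(self):
        fhr = np.full(1800, 140.0)
        fhr[:288] = np.nan
        tr = CTGTrace(fhr=fhr, uc=np.zeros(1800), fs=1.0)
        assert compute_signal_loss(tr) == pytest.approx(0.16)

    def test_planted_dropout_recovered(self):
        # 10% dropout planted in contiguous runs over a 30-min 1-Hz record
        params = TraceGenParams(fs=1.0, dropout_fraction=0.10)
        tr, _ = generate_trace(params, "normal", np.random.default_rng(7))
        assert compute_signal_loss(tr) == pytest.approx(0.10, abs=1.0 / len(tr))

    def test_planted_dropout_matches_for_many_seeds(self):
        for seed in range(5):
            params = TraceGenParams(fs=4.0, dropout_fraction=0.07)
            tr, _ = generate_trace(params, "abnormal", np.random.default_rng(seed))
            assert compute_signal_loss(tr) == pytest.approx(0.07, abs=1.0 / len(tr))


class TestQualityGate:
    def test_boundary_loss_passes(self):
        # exclusion requires strictly more than 16% loss
        fhr = np.full(1800, 140.0)
        fhr[:288] = np.nan
        tr = CTGTrace(fhr=fhr, uc=np.zeros(1800), fs=1.0)
        assert passes_quality(tr, 1800.0, 0.16)

    def test_short_record_fails(self):
        tr = CTGTrace(fhr=np.full(1799, 140.0), uc=np.zeros(1799), fs=1.0)
        assert not passes_quality(tr, 1800.0, 0.16)

    def test_excess_loss_fails(self):
        fhr = np.full(3600, 140.0)
        fhr[: int(0.161 * 3600) + 1] = np.nan
        tr = CTGTrace(fhr=fhr, uc=np.zeros(3600), fs=1.0)
        assert not passes_quality(tr, 1800.0, 0.16)


class TestLastWindow:
    def test_identity_when_exact_length(self, constant_trace):
        out = extract_last_window(constant_trace, WindowSpec(1800.0))
        assert len(out) == len(constant_trace)
        np.testing.assert_array_equal(out.fhr, constant_trace.fhr)

    def test_trailing_zeros_discarded(self):
        # 45-min record at 1 Hz with a 5-min trailing zero run:
        # the 30-min window covers minutes 10-40
        fhr = np.arange(2700, dtype=float) + 60.0
        fhr[2400:] = 0.0
        tr = CTGTrace(fhr=fhr, uc=np.zeros(2700), fs=1.0)
        out = extract_last_window(tr, WindowSpec(1800.0))
        assert len(out) == 1800
        assert out.fhr[-1] == fhr[2399]
        assert out.fhr[0] == fhr[600]

    def test_last_sample_is_last_nonzero(self):
        fhr = np.full(3600, 140.0)
        fhr[3000:] = 0.0
        tr = CTGTrace(fhr=fhr, uc=np.zeros(3600), fs=1.0)
        out = extract_last_window(tr, WindowSpec(1800.0))
        assert out.fhr[-1] == 140.0
        assert len(out) == 1800

    def test_idempotent(self):
        fhr = np.full(2000, 140.0) + np.sin(np.arange(2000) / 50.0)
        tr = CTGTrace(fhr=fhr, uc=np.zeros(2000), fs=1.0)
        once = extract_last_window(tr, WindowSpec(1800.0))
        twice = extract_last_window(once, WindowSpec(1800.0))
        np.testing.assert_array_equal(once.fhr, twice.fhr)

    def test_short_record_raises_with_shortfall(self):
        tr = CTGTrace(fhr=np.full(100, 140.0), uc=np.zeros(100), fs=1.0)
        with pytest.raises(ValueError, match="too short"):
            extract_last_window(tr, WindowSpec(1800.0))


class TestDownsample:
    def test_thirty_minutes_at_4hz_gives_1800(self, constant_trace):
        out = downsample(constant_trace, 1.0)
        assert len(out) == 1800
        assert out.fs == 1.0

    def test_constant_preserved(self, constant_trace):
        out = downsample(constant_trace, 1.0)
        np.testing.assert_allclose(out.fhr, 140.0)

    def test_bin_mean(self):
        fhr = np.array([138.0, 140.0, 142.0, 144.0])
        tr = CTGTrace(fhr=fhr, uc=np.zeros(4), fs=4.0)
        out = downsample(tr, 1.0)
        assert out.fhr[0] == pytest.approx(141.0)

    def test_partial_bin_uses_valid_samples_only(self):
        fhr = np.array([140.0, np.nan, 150.0, np.nan])
        tr = CTGTrace(fhr=fhr, uc=np.zeros(4), fs=4.0)
        out = downsample(tr, 1.0)
        assert out.fhr[0] == pytest.approx(145.0)
        assert out.valid_fhr[0]

    def test_empty_bin_invalid(self):
        fhr = np.full(8, np.nan)
        fhr[4:] = 140.0
        tr = CTGTrace(fhr=fhr, uc=np.zeros(8), fs=4.0)
        out = downsample(tr, 1.0)
        assert not out.valid_fhr[0] and out.valid_fhr[1]

    def test_length_is_floor(self):
        tr = CTGTrace(fhr=np.full(7201, 140.0), uc=np.zeros(7201), fs=4.0)
        assert len(downsample(tr, 1.0)) == 1800

    def test_non_integer_ratio_rejected(self, constant_trace):
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(constant_trace, 3.0)


class TestInterpolateInvalid:
    def test_interior_gap_linear(self):
        fhr = np.array([140.0, np.nan, np.nan, 146.0])
        tr = CTGTrace(fhr=fhr, uc=np.zeros(4), fs=1.0)
        out = interpolate_invalid(tr)
        np.testing.assert_allclose(out.fhr, [140.0, 142.0, 144.0, 146.0])
        assert out.valid_fhr.all()


class TestCSVRoundTrip:
    def test_lossless_round_trip(self, tmp_path):
        params = TraceGenParams(fs=4.0, dropout_fraction=0.05)
        tr, _ = generate_trace(params, "normal", np.random.default_rng(3))
        path = tmp_path / "trace.csv"
        write_ctg_csv(tr, path)
        back = read_ctg_csv(path)
        assert back.fs == pytest.approx(4.0)
        np.testing.assert_array_equal(back.valid_fhr, tr.valid_fhr)
        np.testing.assert_allclose(
            back.fhr[back.valid_fhr], tr.fhr[tr.valid_fhr], rtol=0, atol=1e-9
        )

    def test_empty_cell_becomes_invalid(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("time_s,fhr_bpm,uc_units\n0.0,140,5\n1.0,,5\n2.0,141,5\n")
        tr = read_ctg_csv(path)
        assert len(tr) == 3
        assert not tr.valid_fhr[1]

    def test_fs_inferred_from_time_step(self, tmp_path):
        path = tmp_path / "quarter.csv"
        rows = "".join(f"{i * 0.25},140,5\n" for i in range(8))
        path.write_text("time_s,fhr_bpm,uc_units\n" + rows)
        assert read_ctg_csv(path).fs == pytest.approx(4.0)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,fhr_bpm\n0,140\n")
        with pytest.raises(ValueError, match="uc_units"):
            read_ctg_csv(path)

    def test_non_monotone_time_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,fhr_bpm,uc_units\n0,140,5\n2,140,5\n1,140,5\n")
        with pytest.raises(ValueError, match="row 3"):
            read_ctg_csv(path)


class TestWFDB:
    def test_round_trip_constant_signals(self, tmp_path):
        tr = CTGTrace(fhr=np.full(100, 140.0), uc=np.full(100, 25.0), fs=4.0)
        write_wfdb_record(tr, tmp_path / "rec01")
        back = read_wfdb_record(tmp_path / "rec01")
        assert back.fs == 4.0
        np.testing.assert_allclose(back.fhr, 140.0)
        np.testing.assert_allclose(back.uc, 25.0)

    def test_zero_runs_marked_invalid(self, tmp_path):
        fhr = np.full(100, 140.0)
        fhr[40:60] = 0.0
        tr = CTGTrace(fhr=fhr, uc=np.full(100, 10.0), fs=4.0)
        write_wfdb_record(tr, tmp_path / "rec02")
        back = read_wfdb_record(tmp_path / "rec02")
        assert not back.valid_fhr[40:60].any()
        assert back.valid_fhr[:40].all()

    def test_missing_channel_names_available(self, tmp_path):
        header = tmp_path / "rec03.hea"
        header.write_text("rec03 1 4 10\nrec03.dat 16 100(0)/unit 16 0 0 0 0 ECG\n")
        np.zeros(10, dtype="<i2").tofile(tmp_path / "rec03.dat")
        with pytest.raises(ValueError, match="ECG"):
            read_wfdb_record(tmp_path / "rec03")
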