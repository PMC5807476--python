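import numpy as np
import pytest

from aunpcount.voltammetry_io import (
    ReferenceError_,
    Voltammogram,
    VoltammogramFormatError,
    detect_cycles,
    read_voltammogram,
    to_nhe,
    write_voltammogram,
)
from conftest import triangular_potential


class TestVoltammogram:
    def test_single_ramp_is_one_cycle(self, ramp_trace):
        assert ramp_trace.n_cycles == 1
        assert ramp_trace.cycles == ((0, 801),)
        assert ramp_trace.offset_to_nhe == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            Voltammogram(potential=np.arange(3.0), current=np.arange(4.0), scan_rate=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            Voltammogram(potential=np.array([1.0]), current=np.array([0.0]), scan_rate=0.1)

    def test_nan_current_rejected(self):
        e = np.linspace(0, 1, 10)
        i = np.zeros(10)
        i[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Voltammogram(potential=e, current=i, scan_rate=0.1)

    @pytest.mark.parametrize("nu", [0.0, -0.1, np.nan])
    def test_bad_scan_rate_rejected(self, nu):
        with pytest.raises(ValueError, match="scan_rate"):
            Voltammogram(potential=np.arange(5.0), current=np.zeros(5), scan_rate=nu)

    def test_unknown_reference_rejected(self):
        with pytest.raises(ReferenceError_):
            Voltammogram(potential=np.arange(5.0), current=np.zeros(5), scan_rate=0.1,
                         reference="SCE")

    def test_calibrated_wire_needs_offset(self):
        with pytest.raises(ReferenceError_, match="offset"):
            Voltammogram(potential=np.arange(5.0), current=np.zeros(5), scan_rate=0.1,
                         reference="AgWire_calibrated")
        v = Voltammogram(potential=np.arange(5.0), current=np.zeros(5), scan_rate=0.1,
                         reference="AgWire_calibrated", offset_to_nhe=0.21)
        assert v.offset_to_nhe == 0.21


class TestCycleDetection:
    @pytest.mark.parametrize("k", range(1, 11))
    def test_k_triangular_periods_give_k_cycles(self, k):
        e = triangular_potential(k)
        cycles = detect_cycles(e)
        assert len(cycles) == k
        assert cycles[0][0] == 0 and cycles[-1][1] == e.size

    def test_six_cycle_stripping_program(self):
        # +0.9 -> +1.5 -> +0.9 V repeated six times
        e = triangular_potential(6, 0.9, 1.5, 601)
        assert len(detect_cycles(e)) == 6

    def test_jitter_within_hysteresis_does_not_split(self):
        e = np.linspace(0.0, 1.0, 500)
        e[250] -= 0.004  # single-sample ADC glitch against the sweep direction
        assert len(detect_cycles(e)) == 1

    def test_cycles_tile_the_trace(self):
        e = triangular_potential(4)
        cycles = detect_cycles(e)
        stops = [b for _, b in cycles[:-1]]
        starts = [a for a, _ in cycles[1:]]
        assert stops == starts


class TestToNHE:
    def test_identity_when_already_nhe(self, ramp_trace):
        assert to_nhe(ramp_trace) is ramp_trace

    def test_constant_shift(self):
        v = Voltammogram(potential=np.full(10, 1.0), current=np.zeros(10),
                         scan_rate=0.1, reference="AgAgCl_sat")
        out = to_nhe(v)
        np.testing.assert_allclose(out.potential, 1.197)
        assert out.reference == "NHE" and out.offset_to_nhe == 0.0
        np.testing.assert_array_equal(out.current, v.current)

    def test_idempotent(self):
        v = Voltammogram(potential=np.linspace(0, 1, 20), current=np.zeros(20),
                         scan_rate=0.1, reference="CuCuSO4")
        once = to_nhe(v)
        twice = to_nhe(once)
        np.testing.assert_array_equal(once.potential, twice.potential)


class TestFileRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(7)
        e = triangular_potential(6, 0.9, 1.5, 601)
        i = rng.normal(0, 1e-6, e.size)
        v = Voltammogram(potential=e, current=i, scan_rate=0.1,
                         meta={"electrolyte": "100 mM acetate"})
        path = write_voltammogram(v, tmp_path / "trace.csv")
        back = read_voltammogram(path)
        np.testing.assert_array_equal(back.potential, v.potential)
        np.testing.assert_array_equal(back.current, v.current)
        assert back.scan_rate == v.scan_rate
        assert back.cycles == v.cycles
        assert back.n_cycles == 6
        assert back.meta["electrolyte"] == "100 mM acetate"

    def test_header_lists_all_segments(self, tmp_path):
        e = triangular_potential(6)
        v = Voltammogram(potential=e, current=np.zeros_like(e), scan_rate=0.1)
        path = write_voltammogram(v, tmp_path / "t.csv")
        header = [l for l in path.read_text().splitlines() if l.startswith("# cycles")][0]
        assert header.count(":") == 6

    def test_two_column_file_without_header(self, tmp_path):
        p = tmp_path / "plain.csv"
        p.write_text("0.0,1e-6\n0.1,2e-6\n0.2,3e-6\n")
        v = read_voltammogram(p, scan_rate=0.1)
        assert v.n_cycles == 1
        np.testing.assert_allclose(v.potential, [0.0, 0.1, 0.2])

    @pytest.mark.parametrize("delim", [",", "\t", ";"])
    def test_delimiters_auto_detected(self, tmp_path, delim):
        p = tmp_path / "d.txt"
        p.write_text(delim.join(["0.0", "1e-6"]) + "\n" + delim.join(["0.1", "2e-6"]) + "\n")
        v = read_voltammogram(p, scan_rate=0.1)
        assert v.potential.size == 2

    def test_nonnumeric_rows_skipped(self, tmp_path, caplog):
        p = tmp_path / "messy.csv"
        p.write_text("potential,current\n0.0,1e-6\noops,bad\n0.1,2e-6\n")
        v = read_voltammogram(p, scan_rate=0.1)
        assert v.potential.size == 2

    def test_unparseable_file_names_first_bad_line(self, tmp_path):
        p = tmp_path / "garbage.csv"
        p.write_text("hello world\nnot,numbers\n")
        with pytest.raises(VoltammogramFormatError, match="line 1"):
            read_voltammogram(p, scan_rate=0.1)

    def test_single_sample_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("0.0,1e-6\n")
        with pytest.raises(ValueError, match="fewer than 2"):
            read_voltammogram(p, scan_rate=0.1)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_voltammogram(tmp_path / "nope.csv", scan_rate=0.1)

    def test_instrument_text_dialect(self, tmp_path):
        p = tmp_path / "inst.txt"
        p.write_text(
            "instrument=CHI1000C\nscan_rate_v_s=0.05\nreference=AgAgCl_sat\n"
            "0.0\t1e-6\n0.1\t2e-6\n0.2\t1e-6\n"
        )
        v = read_voltammogram(p, dialect="instrument_text")
        assert v.scan_rate == 0.05
        assert v.reference == "AgAgCl_sat"

    def test_sign_flip_for_cathodic_positive_instruments(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("0.0,1e-6\n0.1,2e-6\n")
        v = read_voltammogram(p, scan_rate=0.1, sign=-1)
        np.testing.assert_allclose(v.current, [-1e-6, -2e-6])
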