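import math

import numpy as np
import pytest

from wabkit.banddecomp import ClassStats, ReplicateSummary
from wabkit.errors import DataError, FormatError, RangeError, UsageError
from wabkit.spectra_io import (
    SampleMeta,
    Spectrum,
    read_decomposition_table,
    read_manifest,
    read_spectrum,
    resample,
    write_decomposition_table,
    write_manifest,
    write_spectrum,
)


class TestReadSpectrum:
    def test_csv_readback(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2000,0.10\n2001,0.11\n2002,0.12\n")
        s = read_spectrum(p)
        assert len(s.wavenumbers) == 3
        np.testing.assert_allclose(np.diff(s.wavenumbers), 1.0)
        np.testing.assert_allclose(s.absorbance, [0.10, 0.11, 0.12])

    def test_descending_order_sorted(self, tmp_path):
        asc = tmp_path / "asc.csv"
        desc = tmp_path / "desc.csv"
        asc.write_text("2000,0.1\n2001,0.2\n2002,0.3\n")
        desc.write_text("2002,0.3\n2001,0.2\n2000,0.1\n")
        a, d = read_spectrum(asc), read_spectrum(desc)
        np.testing.assert_array_equal(a.wavenumbers, d.wavenumbers)
        np.testing.assert_array_equal(a.absorbance, d.absorbance)

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("2000,0.1\n2100,0.2\n2100,0.3\n2200,0.4\n")
        with pytest.raises(DataError):
            read_spectrum(p)

    def test_header_and_tabs_tolerated(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("wavenumber\tabsorbance\n2000\t0.1\n2001\t0.2\n")
        s = read_spectrum(p)
        assert len(s.wavenumbers) == 2

    def test_garbage_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("not,numbers\nat,all\n")
        with pytest.raises(FormatError):
            read_spectrum(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            read_spectrum(tmp_path / "nope.csv")

    def test_jcamp_xy_pairs(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=demo\n##XYDATA=(XY..XY)\n"
            "2000.0, 0.10  2001.0, 0.11\n2002.0, 0.12\n##END=\n"
        )
        s = read_spectrum(p, dialect="jcamp")
        np.testing.assert_allclose(s.wavenumbers, [2000, 2001, 2002])
        np.testing.assert_allclose(s.absorbance, [0.10, 0.11, 0.12])

    def test_jcamp_x_plus_y_table(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=demo\n##DELTAX=1\n##XYDATA=(X++(Y..Y))\n"
            "2000 0.10 0.11 0.12\n2003 0.13 0.14\n##END=\n"
        )
        s = read_spectrum(p, dialect="jcamp")
        np.testing.assert_allclose(s.wavenumbers, [2000, 2001, 2002, 2003, 2004])
        np.testing.assert_allclose(s.absorbance, [0.10, 0.11, 0.12, 0.13, 0.14])

    def test_jcamp_without_xydata_is_format_error(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text("##TITLE=demo\n##END=\n")
        with pytest.raises(FormatError):
            read_spectrum(p, dialect="jcamp")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2000,0.1\n2001,0.2\n")
        with pytest.raises(UsageError):
            read_spectrum(p, dialect="spc")


def test_write_read_roundtrip_exact(tmp_path):
    rng = np.random.default_rng(42)
    s = Spectrum(2000.0 + np.arange(50.0), rng.normal(0.3, 0.1, 50))
    p = tmp_path / "rt.csv"
    write_spectrum(s, p)
    back = read_spectrum(p)
    np.testing.assert_allclose(back.wavenumbers, s.wavenumbers, atol=1e-12)
    np.testing.assert_allclose(back.absorbance, s.absorbance, atol=1e-12)


class TestSpectrumInvariants:
    def test_length_mismatch(self):
        with pytest.raises(DataError):
            Spectrum(np.array([2000.0, 2001.0]), np.array([0.1]))

    def test_too_short(self):
        with pytest.raises(DataError):
            Spectrum(np.array([2000.0]), np.array([0.1]))

    def test_non_monotonic(self):
        with pytest.raises(DataError):
            Spectrum(np.array([2000.0, 2000.0, 2001.0]), np.zeros(3))

    def test_non_finite_absorbance(self):
        with pytest.raises(DataError):
            Spectrum(np.array([2000.0, 2001.0]), np.array([0.1, np.nan]))


class TestSampleMeta:
    def test_unknown_sugar(self):
        with pytest.raises(DataError):
            SampleMeta(sample_id="x", sugar="glucose")

    @pytest.mark.parametrize("sp", [0.0, -1.0, math.nan])
    def test_bad_sp_ratio(self, sp):
        with pytest.raises(DataError):
            SampleMeta(sample_id="x", sugar="trehalose", sp_ratio=sp)

    def test_protein_free_sentinel_ok(self):
        m = SampleMeta(sample_id="x", sugar="trehalose", sp_ratio=math.inf)
        assert math.isinf(m.sp_ratio)


class TestResample:
    def test_identity_on_own_grid(self):
        s = Spectrum(2000.0 + np.arange(10.0), np.linspace(0, 1, 10))
        r = resample(s, s.wavenumbers)
        np.testing.assert_array_equal(r.absorbance, s.absorbance)

    def test_exact_on_linear_ramp(self):
        w = 2000.0 + np.arange(11.0)
        s = Spectrum(w, 0.5 + 0.01 * (w - 2000.0))
        mid = w[:-1] + 0.5
        r = resample(s, mid)
        np.testing.assert_allclose(r.absorbance, 0.5 + 0.01 * (mid - 2000.0), rtol=1e-14)

    def test_no_extrapolation(self):
        s = Spectrum(2000.0 + np.arange(10.0), np.zeros(10))
        with pytest.raises(RangeError):
            resample(s, np.array([1990.0, 2000.0]))

    def test_metadata_preserved(self):
        meta = SampleMeta(sample_id="a", sugar="sucrose", sp_ratio=80.0)
        s = Spectrum(2000.0 + np.arange(10.0), np.ones(10), meta)
        assert resample(s, s.wavenumbers[2:5]).meta == meta


class TestManifest:
    def test_roundtrip_with_inf(self, tmp_path):
        entries = [
            (SampleMeta("a_sp80", "trehalose", 80.0, 1), "a1.csv"),
            (SampleMeta("a_spinf", "trehalose", math.inf, 2), "a2.csv"),
        ]
        p = tmp_path / "manifest.csv"
        write_manifest(entries, p)
        back = read_manifest(p)
        assert [m for m, _ in back] == [m for m, _ in entries]
        assert back[0][1] == tmp_path / "a1.csv"

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,sugar\nx,trehalose\n")
        with pytest.raises(FormatError):
            read_manifest(p)


class TestDecompositionTable:
    @staticmethod
    def _summary():
        return ReplicateSummary(
            sample_id="t_sp80",
            classes={
                "W2a": ClassStats(0.6, 0.05, 2100.123456789, 1.5, 3),
                "W4": ClassStats(0.4, 0.05, 2250.0, 0.5, 3),
            },
            n_replicates=3,
        )

    def test_row_count_and_roundtrip(self, tmp_path):
        p = tmp_path / "summary.csv"
        write_decomposition_table([self._summary()], p)
        df = read_decomposition_table(p)
        assert len(df) == 2
        row = df[df["class"] == "W2a"].iloc[0]
        assert row["mean_population"] == pytest.approx(0.6, abs=1e-12)
        assert row["mean_center"] == pytest.approx(2100.123456789, abs=1e-12)

    def test_empty_results_is_usage_error(self, tmp_path):
        with pytest.raises(UsageError):
            write_decomposition_table([], tmp_path / "t.csv")

    def test_unwritable_path_is_io_error(self, tmp_path):
        with pytest.raises(OSError):
            write_decomposition_table([self._summary()], tmp_path / "no" / "dir" / "t.csv")
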