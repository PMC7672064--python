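import base64
import struct
import zlib

import pytest

from orbitag import Peak, ProteinRecord, Spectrum, read_fasta, read_peaklist
from orbitag.spectra_io import (
    FastaAlphabetError,
    read_mzml,
    read_report,
    read_scan_series,
    write_fasta,
    write_peaklist,
    write_report,
)
from orbitag.identify import MatchResult


class TestSpectrum:
    def test_peaks_sorted_on_construction(self):
        s = Spectrum(peaks=[Peak(500.0, 10.0), Peak(400.0, 5.0)])
        assert [p.mz for p in s.peaks] == [400.0, 500.0]

    def test_near_duplicate_mz_merged_with_summed_intensity(self):
        s = Spectrum(peaks=[Peak(400.0, 5.0), Peak(400.0 + 1e-9, 7.0)])
        assert len(s) == 1
        assert s.peaks[0].intensity == 12.0

    def test_invalid_peaks_rejected(self):
        with pytest.raises(ValueError):
            Peak(-1.0, 5.0)
        with pytest.raises(ValueError):
            Peak(100.0, -2.0)


class TestPeaklistIO:
    def test_csv_roundtrip_and_sorting(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("500.0,10\n400.0,5\n")
        s = read_peaklist(p)
        assert [pk.mz for pk in s.peaks] == [400.0, 500.0]

    def test_empty_file_is_empty_spectrum(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        assert len(read_peaklist(p)) == 0

    def test_duplicate_rows_merge(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("400.0,5\n400.0,7\n")
        s = read_peaklist(p)
        assert len(s) == 1 and s.peaks[0].intensity == 12.0

    def test_header_and_tab_autodetected(self, tmp_path):
        p = tmp_path / "peaks.tsv"
        p.write_text("mz\tintensity\n400.0\t5\n5.0e2\t1e1\n")
        s = read_peaklist(p)
        assert len(s) == 2 and s.peaks[1].intensity == 10.0

    def test_unparseable_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("400.0,5\noops,3\n")
        with pytest.raises(ValueError, match="line 2"):
            read_peaklist(p)

    def test_write_read_roundtrip(self, tmp_path):
        s = Spectrum(peaks=[Peak(400.123456, 5.0), Peak(812.654321, 7.5)])
        path = tmp_path / "out.csv"
        write_peaklist(s, path)
        s2 = read_peaklist(path)
        assert [p.mz for p in s2.peaks] == pytest.approx([p.mz for p in s.peaks], abs=1e-6)
        assert [p.intensity for p in s2.peaks] == [5.0, 7.5]

    def test_scan_series_split_by_scan_column(self, tmp_path):
        p = tmp_path / "scans.csv"
        p.write_text("mz,intensity,scan\n400.0,5,0\n401.0,6,0\n400.0,2,1\n")
        scans = read_scan_series(p)
        assert [len(s) for s in scans] == [2, 1]


def _make_mzml(path, spectra, mode="centroid spectrum"):
    """Write a minimal mzML by hand (synthetic fixture, generated at
    test time; enough structure for a centroided read)."""

    def encode(values):
        raw = struct.pack(f"<{len(values)}d", *values)
        return base64.b64encode(zlib.compress(raw)).decode()

    chunks = []
    for i, (mzs, ints) in enumerate(spectra):
        chunks.append(f"""
      <spectrum index="{i}" id="scan={i}" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="{mode}" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{encode(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{encode(ints)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r0">
    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">
{''.join(chunks)}
    </spectrumList>
  </run>
</mzML>""")


class TestMzml:
    def test_centroided_mzml_read(self, tmp_path):
        p = tmp_path / "one.mzml"
        _make_mzml(p, [([400.0, 500.0], [5.0, 10.0])])
        s = read_peaklist(p)
        assert [pk.mz for pk in s.peaks] == [400.0, 500.0]
        assert s.polarity == "positive"

    def test_multiscan_mzml(self, tmp_path):
        p = tmp_path / "two.mzml"
        _make_mzml(p, [([400.0], [5.0]), ([401.0, 402.0], [1.0, 2.0])])
        scans = read_mzml(p)
        assert [len(s) for s in scans] == [1, 2]

    def test_profile_mode_rejected(self, tmp_path):
        p = tmp_path / "prof.mzml"
        _make_mzml(p, [([400.0], [5.0])], mode="profile spectrum")
        with pytest.raises(ValueError, match="centroid"):
            read_mzml(p)


class TestFasta:
    def test_multiline_sequence_joined(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">p1\nKVFG\nRC\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].sequence == "KVFGRC"

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">a\nAAA\n>b\nCCC\n>c\nDDD\n")
        assert [r.identifier for r in read_fasta(p)] == ["a", "b", "c"]

    def test_invalid_character_position_reported(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">p1\nKVF7\n")
        with pytest.raises(FastaAlphabetError) as err:
            read_fasta(p)
        assert err.value.position == 4 and err.value.record_id == "p1"

    def test_stop_stripped_selenocysteine_mapped(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">p1\nKVUG*\n")
        assert read_fasta(p)[0].sequence == "KVCG"

    def test_b_and_z_rejected(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">p1\nKVBZ\n")
        with pytest.raises(FastaAlphabetError):
            read_fasta(p)

    def test_write_read_roundtrip(self, tmp_path):
        recs = [ProteinRecord("p1", "p1 test", "KVFGRC" * 15)]
        path = tmp_path / "out.fasta"
        write_fasta(recs, path)
        back = read_fasta(path)
        assert back[0].sequence == recs[0].sequence


class TestReports:
    def _results(self):
        return [
            MatchResult("LYSC", 8.0, 53, matches=[], unique_tag_count=1),
            MatchResult("TRFE", 1.0, 5, matches=[], unique_tag_count=0),
        ]

    def test_empty_results_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report([], p, "tsv")
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("protein\t")

    def test_tsv_row_contents(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_report(self._results(), p, "tsv")
        lines = p.read_text().splitlines()
        assert lines[1].split("\t")[0] == "LYSC"
        assert lines[1].split("\t")[1] == "8.000000"

    def test_json_roundtrip(self, tmp_path):
        p = tmp_path / "r.json"
        write_report(self._results(), p, "json")
        back = read_report(p)
        assert back[0]["protein"] == "LYSC" and back[0]["coverage_percent"] == 53
        write_report(self._results(), tmp_path / "r2.json", "json")
        assert (tmp_path / "r2.json").read_text() == p.read_text()
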