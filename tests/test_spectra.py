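"""Spectrum model, MGF / minimal-mzML I/O, and reference-scan selection."""

import numpy as np
import pytest

from revmet import chemlib as cl
from revmet.spectra import (
    ChooserCriteria,
    Spectrum,
    UnsupportedMzmlError,
    choose_reference_spectrum,
    normalize_spectrum,
    read_mgf,
    read_mzml_minimal,
    write_mgf,
    write_mzml_minimal,
)


def _demo_spectra():
    return [
        Spectrum("alpha", 466.3163, [100.0, 200.0, 300.5], [10.0, 5.0, 1.0],
                 precursor_intensity=5e4, charge=1, scan_number=12,
                 source_file="run1.mzML", instrument_tag="qtof"),
        Spectrum("beta", 300.1, [50.0, 60.0], [1.0, 2.0], scan_number=13),
        Spectrum("gamma", 120.0, [80.0], [7.0], precursor_intensity=1.0,
                 charge=1, scan_number=14),
    ]


class TestSpectrumModel:
    def test_unsorted_peaks_resorted_with_flag(self):
        s = Spectrum("s", 500.0, [300.0, 100.0, 200.0], [1.0, 2.0, 3.0])
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensities) == [2.0, 3.0, 1.0]
        assert s.was_resorted

    def test_duplicate_mz_merged(self):
        s = Spectrum("s", 500.0, [100.0, 100.0, 200.0], [1.0, 2.0, 3.0])
        assert s.n_peaks == 2
        assert s.intensities[0] == 3.0

    def test_invalid_peaks_rejected(self):
        with pytest.raises(ValueError):
            Spectrum("s", 500.0, [0.0], [1.0])
        with pytest.raises(ValueError):
            Spectrum("s", 500.0, [100.0], [-1.0])


class TestMgf:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "demo.mgf"
        originals = _demo_spectra()
        write_mgf(originals, path)
        loaded = read_mgf(path)
        assert len(loaded) == 3
        for orig, back in zip(originals, loaded):
            assert back.spectrum_id == orig.spectrum_id
            assert back.precursor_mz == pytest.approx(orig.precursor_mz)
            assert back.precursor_intensity == pytest.approx(orig.precursor_intensity) \
                if orig.precursor_intensity is not None else back.precursor_intensity is None
            assert back.charge == orig.charge
            assert back.scan_number == orig.scan_number
            np.testing.assert_allclose(back.mz, orig.mz)
            np.testing.assert_allclose(back.intensities, orig.intensities)

    def test_missing_pepmass_raises(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(ValueError, match="PEPMASS"):
            read_mgf(path)

    def test_malformed_block_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=100\n100.0 1.0\n")
        with pytest.raises(ValueError, match="line 1"):
            read_mgf(path)
        path.write_text("END IONS\n")
        with pytest.raises(ValueError, match="line 1"):
            read_mgf(path)

    def test_unsorted_mgf_peaks_resorted(self, tmp_path):
        path = tmp_path / "unsorted.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=x\nPEPMASS=500.0\n"
            "300.0 1.0\n100.0 2.0\nEND IONS\n")
        (spec,) = read_mgf(path)
        assert list(spec.mz) == [100.0, 300.0]
        assert spec.was_resorted

    def test_empty_write_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_mgf([], tmp_path / "empty.mgf")


class TestMzmlMinimal:
    @pytest.mark.parametrize("compress,bits", [(False, 64), (True, 64), (False, 32)])
    def test_round_trip(self, tmp_path, compress, bits):
        path = tmp_path / "demo.mzML"
        originals = _demo_spectra()
        write_mzml_minimal(originals, path, compress=compress, bits=bits)
        loaded = read_mzml_minimal(path)
        assert len(loaded) == 3
        atol = 1e-9 if bits == 64 else 1e-3
        for orig, back in zip(originals, loaded):
            assert back.ms_level == 2
            assert back.scan_number == orig.scan_number
            assert back.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-9)
            np.testing.assert_allclose(back.mz, orig.mz, atol=atol)
            np.testing.assert_allclose(back.intensities, orig.intensities, atol=atol)

    def test_zlib_twin_matches_uncompressed(self, tmp_path):
        originals = _demo_spectra()
        write_mzml_minimal(originals, tmp_path / "plain.mzML", compress=False)
        write_mzml_minimal(originals, tmp_path / "zlib.mzML", compress=True)
        plain = read_mzml_minimal(tmp_path / "plain.mzML")
        packed = read_mzml_minimal(tmp_path / "zlib.mzML")
        for a, b in zip(plain, packed):
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_ms1_only_file(self, tmp_path):
        ms1 = Spectrum("scan=1", None, [100.0, 101.0], [5.0, 1.0], ms_level=1)
        path = tmp_path / "ms1.mzML"
        write_mzml_minimal([ms1], path)
        loaded = read_mzml_minimal(path)
        assert [s.ms_level for s in loaded] == [1]
        assert not [s for s in loaded if s.ms_level == 2]

    def test_unsupported_encoding_is_explicit(self, tmp_path):
        path = tmp_path / "weird.mzML"
        write_mzml_minimal(_demo_spectra(), path)
        # swap the declared precision to an unsupported integer encoding
        text = path.read_text().replace("MS:1000523", "MS:1000519")
        path.write_text(text)
        with pytest.raises(UnsupportedMzmlError, match="unsupported"):
            read_mzml_minimal(path)

    def test_handwritten_fixture_parses(self, tmp_path):
        # an mzML snippet written independently of the module's writer
        import base64, struct
        mz = base64.b64encode(struct.pack("<3d", 100.0, 200.0, 300.5)).decode()
        it = base64.b64encode(struct.pack("<3d", 10.0, 5.0, 1.0)).decode()
        path = tmp_path / "hand.mzML"
        path.write_text(f"""<?xml version="1.0"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=7" defaultArrayLength="3">
   <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
   <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
    <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="466.3163"/>
   </selectedIon></selectedIonList></precursor></precursorList>
   <binaryDataArrayList count="2">
    <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
     <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
     <binary>{mz}</binary></binaryDataArray>
    <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
     <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
     <binary>{it}</binary></binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run></mzML>""")
        (spec,) = read_mzml_minimal(path)
        assert spec.scan_number == 7
        assert spec.precursor_mz == pytest.approx(466.3163)
        np.testing.assert_allclose(spec.mz, [100.0, 200.0, 300.5])
        np.testing.assert_allclose(spec.intensities, [10.0, 5.0, 1.0])


class TestNormalize:
    def test_base_peak(self):
        s = Spectrum("s", 500.0, [100.0, 200.0], [4.0, 1.0])
        out = normalize_spectrum(s, "base_peak")
        np.testing.assert_allclose(out.intensities, [1.0, 0.25])

    def test_l2(self):
        s = Spectrum("s", 500.0, [100.0, 200.0], [3.0, 4.0])
        out = normalize_spectrum(s, "l2")
        np.testing.assert_allclose(out.intensities, [0.6, 0.8])

    def test_sqrt_l2(self):
        s = Spectrum("s", 500.0, [100.0, 200.0], [4.0, 4.0])
        out = normalize_spectrum(s, "sqrt_l2")
        np.testing.assert_allclose(out.intensities, [0.7071, 0.7071], atol=1e-4)

    @pytest.mark.parametrize("mode", ["base_peak", "l2"])
    def test_idempotent(self, mode):
        rng = np.random.default_rng(5)
        s = Spectrum("s", 500.0, np.sort(rng.uniform(50, 400, 10)),
                     rng.uniform(0.1, 100, 10))
        once = normalize_spectrum(s, mode)
        twice = normalize_spectrum(once, mode)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_sqrt_l2_yields_stable_unit_vector(self):
        # sqrt_l2 is a transform, not a projection: applying it twice takes a
        # fourth root, so idempotence cannot hold; what is invariant is that
        # its output is a unit vector, i.e. a fixed point of plain l2
        rng = np.random.default_rng(5)
        s = Spectrum("s", 500.0, np.sort(rng.uniform(50, 400, 10)),
                     rng.uniform(0.1, 100, 10))
        out = normalize_spectrum(s, "sqrt_l2")
        assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            normalize_spectrum(out, "l2").intensities, out.intensities, atol=1e-12)

    def test_all_zero_rejected(self):
        s = Spectrum("s", 500.0, [100.0], [0.0])
        with pytest.raises(ValueError):
            normalize_spectrum(s, "l2")


class TestChooser:
    target_mass = 465.30904  # Gly-CA; [M+H]+ = 466.31632

    def _candidates(self):
        return [
            Spectrum("a", 466.31500, [100.0] * 6, [1.0] * 6,
                     precursor_intensity=1e4, scan_number=1),
            Spectrum("b", 466.32096, [100.0] * 6, [1.0] * 6,
                     precursor_intensity=5e4, scan_number=2),
            Spectrum("c", 466.33032, [100.0] * 6, [1.0] * 6,
                     precursor_intensity=9e4, scan_number=3),
        ]

    def test_most_abundant_precursor_within_window(self):
        # candidate c is ~30 ppm out; among a and b the more intense b wins
        chosen = choose_reference_spectrum(self._candidates(), self.target_mass)
        assert chosen.spectrum_id == "b"

    def test_none_when_nothing_passes(self):
        far = [s.replace(precursor_mz=470.0) for s in self._candidates()]
        assert choose_reference_spectrum(far, self.target_mass) is None

    def test_order_invariance(self):
        cands = self._candidates()
        for perm in ([2, 0, 1], [1, 2, 0]):
            chosen = choose_reference_spectrum(
                [cands[i] for i in perm], self.target_mass)
            assert chosen.spectrum_id == "b"

    def test_tie_breaks_ppm_then_scan(self):
        mz = cl.adduct_mz(self.target_mass, cl.ADDUCTS["[M+H]+"])
        cands = [
            Spectrum("far", mz * (1 + 8e-6), [100.0], [1.0],
                     precursor_intensity=10.0, scan_number=9),
            Spectrum("near", mz * (1 + 2e-6), [100.0], [1.0],
                     precursor_intensity=10.0, scan_number=8),
        ]
        assert choose_reference_spectrum(cands, self.target_mass).spectrum_id == "near"
        same_ppm = [
            Spectrum("late", mz, [100.0], [1.0], precursor_intensity=10.0,
                     scan_number=7),
            Spectrum("early", mz, [100.0], [1.0], precursor_intensity=10.0,
                     scan_number=4),
        ]
        assert choose_reference_spectrum(same_ppm, self.target_mass).spectrum_id == "early"

    def test_result_is_inside_window(self):
        chosen = choose_reference_spectrum(self._candidates(), self.target_mass)
        mz = cl.adduct_mz(self.target_mass, cl.ADDUCTS["[M+H]+"])
        assert abs(cl.ppm_error(chosen.precursor_mz, mz)) <= 10.0

    def test_missing_precursor_intensity(self):
        cands = [Spectrum("x", 466.31632, [100.0], [3.0], scan_number=1)]
        with pytest.raises(ValueError, match="precursor intensity"):
            choose_reference_spectrum(cands, self.target_mass)
        chosen = choose_reference_spectrum(
            cands, self.target_mass, fallback_to_fragment_sum=True)
        assert chosen.spectrum_id == "x"

    def test_ms1_candidates_ignored(self):
        cands = [Spectrum("ms1", 466.31632, [100.0], [1.0], ms_level=1,
                          precursor_intensity=1e6)]
        assert choose_reference_spectrum(cands, self.target_mass) is None
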