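"""Spectrum data model, MGF / minimal-mzML I/O, and reference-scan selection.

The reference-scan chooser mirrors the MSMS-Chooser workflow: given the
computed adduct m/z of a target compound, it returns the acquired MS/MS scan
whose precursor lies within a ppm window, preferring the scan with the most
abundant precursor ion.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chemlib import Adduct, ADDUCTS, adduct_mz, ppm_error

__all__ = [
    "Peak",
    "Spectrum",
    "ChooserCriteria",
    "read_mgf",
    "write_mgf",
    "read_mzml_minimal",
    "write_mzml_minimal",
    "normalize_spectrum",
    "choose_reference_spectrum",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """A centroided mass spectrum with acquisition metadata.

    Peaks are stored as parallel numpy arrays and kept sorted ascending in
    m/z; exact-duplicate m/z values are merged by summing intensities. If the
    input peak list was out of order, ``was_resorted`` records that.
    """

    spectrum_id: str
    precursor_mz: float | None
    mz: np.ndarray
    intensities: np.ndarray
    precursor_intensity: float | None = None
    charge: int | None = None
    ms_level: int = 2
    source_file: str = ""
    scan_number: int = -1
    instrument_tag: str = "other"
    was_resorted: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.shape != self.intensities.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.mz <= 0) or np.any(self.intensities < 0):
            raise ValueError("peaks require mz > 0 and intensity >= 0")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensities = self.intensities[order]
            self.was_resorted = True
        if self.mz.size and np.any(np.diff(self.mz) == 0):
            uniq, inv = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, self.intensities)
            self.mz, self.intensities = uniq, summed

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensities)]

    def replace(self, **kwargs) -> "Spectrum":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ChooserCriteria:
    """Window and adduct for reference-scan selection."""

    ppm_window: float = 10.0
    adduct: Adduct = ADDUCTS["[M+H]+"]

    def __post_init__(self) -> None:
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be positive")


# ---------------------------------------------------------------------------
# MGF

def _prescan_mgf(path: str | Path) -> None:
    """Validate BEGIN IONS / END IONS block structure, reporting line numbers."""
    depth = 0
    open_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if depth:
                    raise ValueError(
                        f"{path}: line {lineno}: BEGIN IONS inside unclosed block "
                        f"opened at line {open_line}"
                    )
                depth, open_line = 1, lineno
            elif token == "END IONS":
                if not depth:
                    raise ValueError(f"{path}: line {lineno}: END IONS without BEGIN IONS")
                depth = 0
    if depth:
        raise ValueError(f"{path}: BEGIN IONS at line {open_line} never closed")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file. TITLE carries the spectrum id; PEPMASS carries the
    precursor m/z and, optionally, the precursor intensity."""
    _prescan_mgf(path)
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for idx, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError(f"{path}: spectrum #{idx} lacks a PEPMASS line")
            pepmass = params["pepmass"]
            prec_mz = float(pepmass[0])
            prec_int = float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] else None
            charge = None
            if params.get("charge"):
                charge = int(params["charge"][0])
            spectra.append(Spectrum(
                spectrum_id=str(params.get("title", f"index={idx}")),
                precursor_mz=prec_mz,
                precursor_intensity=prec_int,
                charge=charge,
                mz=entry["m/z array"],
                intensities=entry["intensity array"],
                ms_level=2,
                source_file=str(params.get("source_file", Path(path).name)),
                scan_number=int(params.get("scans", idx)),
                instrument_tag=str(params.get("instrument", "other")),
            ))
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    if not spectra:
        raise ValueError("refusing to write an empty MGF")
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": (s.precursor_mz,) if s.precursor_intensity is None
            else (s.precursor_mz, s.precursor_intensity),
            "scans": s.scan_number,
            "source_file": s.source_file,
            "instrument": s.instrument_tag,
        }
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append({
            "params": params,
            "m/z array": s.mz,
            "intensity array": s.intensities,
        })
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Minimal mzML dialect
#
# A deliberately small subset of mzML: uncompressed or zlib-compressed,
# little-endian 64- or 32-bit float binary arrays, MS1/MS2 spectra with
# selected-ion records. Anything else raises rather than being skipped.

_ACC_MSLEVEL = "MS:1000511"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_PEAK_INTENSITY = "MS:1000042"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


class UnsupportedMzmlError(ValueError):
    """Raised for mzML content outside the supported minimal dialect."""


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_array(bda: ET.Element) -> np.ndarray:
    accessions = {cv.get("accession") for elem in bda.iter()
                  if _strip(elem.tag) == "cvParam" for cv in [elem]}
    if _ACC_64BIT in accessions:
        dtype = "<f8"
    elif _ACC_32BIT in accessions:
        dtype = "<f4"
    else:
        raise UnsupportedMzmlError(
            "binary array is neither 64- nor 32-bit float (unsupported dialect)")
    raw_el = next((e for e in bda.iter() if _strip(e.tag) == "binary"), None)
    raw = base64.b64decode(raw_el.text or "") if raw_el is not None else b""
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    elif _ACC_NOCOMP not in accessions:
        raise UnsupportedMzmlError(
            "binary array compression is neither zlib nor none (unsupported dialect)")
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_minimal(path: str | Path) -> list[Spectrum]:
    """Parse the minimal mzML dialect into spectra (MS1 and MS2)."""
    tree = ET.parse(path)
    spectra = []
    for idx, spec_el in enumerate(e for e in tree.iter() if _strip(e.tag) == "spectrum"):
        cvs = {cv.get("accession"): cv.get("value")
               for cv in spec_el.iter() if _strip(cv.tag) == "cvParam"}
        ms_level = int(cvs.get(_ACC_MSLEVEL, 1))
        native_id = spec_el.get("id", "")
        scan = idx
        for token in native_id.split():
            if token.startswith("scan="):
                scan = int(token[5:])
        prec_mz = prec_int = None
        for ion in (e for e in spec_el.iter() if _strip(e.tag) == "selectedIon"):
            ion_cvs = {cv.get("accession"): cv.get("value")
                       for cv in ion.iter() if _strip(cv.tag) == "cvParam"}
            if _ACC_SELECTED_MZ in ion_cvs:
                prec_mz = float(ion_cvs[_ACC_SELECTED_MZ])
            if _ACC_PEAK_INTENSITY in ion_cvs:
                prec_int = float(ion_cvs[_ACC_PEAK_INTENSITY])
        mz_arr = int_arr = None
        for bda in (e for e in spec_el.iter() if _strip(e.tag) == "binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter() if _strip(cv.tag) == "cvParam"}
            data = _decode_array(bda)
            if _ACC_MZ_ARRAY in accs:
                mz_arr = data
            elif _ACC_INT_ARRAY in accs:
                int_arr = data
        if mz_arr is None or int_arr is None:
            raise UnsupportedMzmlError(
                f"spectrum {native_id!r} lacks an m/z or intensity array")
        spectra.append(Spectrum(
            spectrum_id=native_id or f"index={idx}",
            precursor_mz=prec_mz,
            precursor_intensity=prec_int,
            mz=mz_arr,
            intensities=int_arr,
            ms_level=ms_level,
            source_file=Path(path).name,
            scan_number=scan,
        ))
    return spectra


def _encode_array(values: np.ndarray, compress: bool, bits: int) -> str:
    dtype = "<f8" if bits == 64 else "<f4"
    raw = np.asarray(values, dtype=dtype).tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def write_mzml_minimal(
    spectra: Sequence[Spectrum],
    path: str | Path,
    compress: bool = False,
    bits: int = 64,
) -> None:
    """Write spectra in the minimal mzML dialect (fixture-grade writer)."""
    if bits not in (64, 32):
        raise ValueError("bits must be 64 or 32")
    comp_acc, comp_name = (
        (_ACC_ZLIB, "zlib compression") if compress else (_ACC_NOCOMP, "no compression"))
    bit_acc, bit_name = (
        (_ACC_64BIT, "64-bit float") if bits == 64 else (_ACC_32BIT, "32-bit float"))

    def bda(acc: str, name: str, values: np.ndarray) -> str:
        payload = _encode_array(values, compress, bits)
        return (
            '<binaryDataArray encodedLength="{n}">'
            '<cvParam cvRef="MS" accession="{ba}" name="{bn}"/>'
            '<cvParam cvRef="MS" accession="{ca}" name="{cn}"/>'
            '<cvParam cvRef="MS" accession="{a}" name="{m}"/>'
            "<binary>{p}</binary></binaryDataArray>"
        ).format(n=len(payload), ba=bit_acc, bn=bit_name, ca=comp_acc,
                 cn=comp_name, a=acc, m=name, p=payload)

    parts = ['<?xml version="1.0" encoding="utf-8"?>',
             '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
             f'<run id="run"><spectrumList count="{len(spectra)}">']
    for idx, s in enumerate(spectra):
        scan = s.scan_number if s.scan_number >= 0 else idx
        parts.append(
            f'<spectrum index="{idx}" id="scan={scan}" defaultArrayLength="{s.n_peaks}">')
        parts.append(
            f'<cvParam cvRef="MS" accession="{_ACC_MSLEVEL}" name="ms level" '
            f'value="{s.ms_level}"/>')
        if s.ms_level == 2 and s.precursor_mz is not None:
            ion_cvs = (f'<cvParam cvRef="MS" accession="{_ACC_SELECTED_MZ}" '
                       f'name="selected ion m/z" value="{s.precursor_mz!r}"/>')
            if s.precursor_intensity is not None:
                ion_cvs += (f'<cvParam cvRef="MS" accession="{_ACC_PEAK_INTENSITY}" '
                            f'name="peak intensity" value="{s.precursor_intensity!r}"/>')
            parts.append(
                '<precursorList count="1"><precursor><selectedIonList count="1">'
                f"<selectedIon>{ion_cvs}</selectedIon>"
                "</selectedIonList></precursor></precursorList>")
        parts.append('<binaryDataArrayList count="2">')
        parts.append(bda(_ACC_MZ_ARRAY, "m/z array", s.mz))
        parts.append(bda(_ACC_INT_ARRAY, "intensity array", s.intensities))
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts))


# ---------------------------------------------------------------------------
# Normalization and reference-scan selection

def normalize_spectrum(s: Spectrum, mode: str = "base_peak") -> Spectrum:
    """Return a copy with normalized intensities.

    base_peak: max intensity 1; l2: unit Euclidean norm; sqrt_l2: square-root
    transform then unit Euclidean norm (the scaling used for cosine scoring).
    """
    if s.n_peaks == 0:
        raise ValueError("cannot normalize an empty spectrum")
    intens = s.intensities
    if not np.any(intens > 0):
        raise ValueError("cannot normalize all-zero intensities")
    if mode == "base_peak":
        out = intens / intens.max()
    elif mode == "l2":
        out = intens / np.linalg.norm(intens)
    elif mode == "sqrt_l2":
        root = np.sqrt(intens)
        out = root / np.linalg.norm(root)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return s.replace(intensities=out)


def choose_reference_spectrum(
    candidates: Iterable[Spectrum],
    target_mass: float,
    criteria: ChooserCriteria = ChooserCriteria(),
    fallback_to_fragment_sum: bool = False,
) -> Spectrum | None:
    """Select the reference MS/MS scan for a target neutral mass.

    Among MS2 candidates whose precursor m/z lies within ``ppm_window`` of
    the target's adduct m/z, returns the one with the most abundant
    precursor ion; ties break on smaller |ppm error|, then smaller scan
    number. Returns None when nothing passes the window.

    A passing candidate without a recorded precursor intensity raises,
    unless ``fallback_to_fragment_sum`` enables the degraded mode that
    ranks by summed fragment intensity instead.
    """
    target_mz = adduct_mz(target_mass, criteria.adduct)
    ranked = []
    for cand in candidates:
        if cand.ms_level != 2 or cand.precursor_mz is None:
            continue
        err = ppm_error(cand.precursor_mz, target_mz)
        if abs(err) > criteria.ppm_window:
            continue
        intensity = cand.precursor_intensity
        if intensity is None:
            if not fallback_to_fragment_sum:
                raise ValueError(
                    f"candidate {cand.spectrum_id!r} passes the ppm window but has "
                    "no precursor intensity to rank by")
            intensity = float(cand.intensities.sum())
        ranked.append((-intensity, abs(err), cand.scan_number, cand))
    if not ranked:
        return None
    ranked.sort(key=lambda t: t[:3])
    return ranked[0][3]
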