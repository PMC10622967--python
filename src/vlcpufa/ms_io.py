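"""Reading and writing centroided LC-MS runs.

The in-memory container is :class:`SpectrumRun`: an RT-ordered list of
centroided spectra.  Runs are exchanged as mzML (read through pyteomics;
written by a small PSI-CV-conformant writer here) or as a long-format TSV
dialect (rt_min, mz, intensity) convenient for text fixtures.  Retention
times are minutes everywhere; mzML scan times in seconds are converted on
read.
"""

from __future__ import annotations

import base64
import gzip
import os
import struct
import zlib
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence
from xml.sax.saxutils import quoteattr

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumRun",
    "MsIoError",
    "NoSpectraError",
    "read_mzml",
    "write_mzml",
    "read_tsv_run",
    "write_tsv_run",
]


class MsIoError(ValueError):
    """Malformed or unusable LC-MS input."""


class NoSpectraError(MsIoError):
    """A run contains no usable MS1 spectra."""


@dataclass
class Spectrum:
    """One centroided MS1 scan: retention time plus (m/z, intensity) pairs."""

    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise MsIoError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if not np.all(np.diff(self.mz) > 0):
                raise MsIoError("duplicate m/z values within one spectrum")
        if np.any(self.intensity < 0):
            raise MsIoError("negative intensities")


@dataclass
class SpectrumRun:
    """An RT-ordered collection of centroided spectra from one LC-MS run."""

    spectra: list[Spectrum]
    polarity: str = "negative"
    scan_range: Optional[tuple[float, float]] = None
    run_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise MsIoError(f"polarity must be negative/positive, got {self.polarity!r}")
        self.spectra = sorted(self.spectra, key=lambda s: s.rt_min)
        rts = [s.rt_min for s in self.spectra]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise MsIoError("duplicate retention times across spectra")
        if self.scan_range is not None:
            lo, hi = self.scan_range
            for s in self.spectra:
                if s.mz.size and (s.mz[0] < lo - 1e-9 or s.mz[-1] > hi + 1e-9):
                    raise MsIoError(
                        f"centroid m/z outside declared scan range ({lo}, {hi})"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def rt(self) -> np.ndarray:
        return np.array([s.rt_min for s in self.spectra])

    def tic(self) -> np.ndarray:
        """Total ion current per spectrum."""
        return np.array([float(s.intensity.sum()) for s in self.spectra])


def _centroid_profile(mz: np.ndarray, inten: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Naive local-maximum centroiding for profile data; approximate by design.
    if mz.size < 3:
        return mz, inten
    peaks = np.flatnonzero(
        (inten[1:-1] > 0)
        & (inten[1:-1] >= inten[:-2])
        & (inten[1:-1] > inten[2:])
    ) + 1
    return mz[peaks], inten[peaks]


# PSI-MS controlled-vocabulary accessions used on read/write
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEG_SCAN = "MS:1000129"
_ACC_POS_SCAN = "MS:1000130"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_accessions(elem) -> dict[str, dict]:
    """accession -> cvParam attributes for direct children of ``elem``."""
    out = {}
    for child in elem:
        if _localname(child.tag) == "cvParam":
            out[child.get("accession", "")] = child.attrib
    return out


def _decode_binary_array(bda) -> np.ndarray:
    accs = _cv_accessions(bda)
    b64 = ""
    for child in bda:
        if _localname(child.tag) == "binary":
            b64 = child.text or ""
    raw = base64.b64decode(b64)
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | os.PathLike, *, centroid_profile: bool = False) -> SpectrumRun:
    """Read MS1 spectra from an mzML file into a :class:`SpectrumRun`.

    Self-contained PSI-mzML parser: handles 32/64-bit float arrays, zlib
    or uncompressed encoding, second- or minute-valued scan start times,
    and ``.gz``-compressed files.  Profile-mode spectra are rejected
    unless ``centroid_profile`` is set, in which case a naive
    local-maximum centroider is applied (approximate by design).
    """
    from xml.etree import ElementTree as ET

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    spectra: list[Spectrum] = []
    polarity = "negative"
    saw_mzml_root = False
    try:
        with opener(path, "rb") as fh:
            for _event, elem in ET.iterparse(fh, events=("end",)):
                name = _localname(elem.tag)
                if name in ("mzML", "indexedmzML"):
                    saw_mzml_root = True
                if name != "spectrum":
                    continue
                accs = _cv_accessions(elem)
                level = accs.get(_ACC_MS_LEVEL, {}).get("value")
                if level is not None and int(level) != 1:
                    elem.clear()
                    continue
                rt_min = None
                for sub in elem.iter():
                    if _localname(sub.tag) == "scan":
                        scan_accs = _cv_accessions(sub)
                        if _ACC_SCAN_START in scan_accs:
                            p = scan_accs[_ACC_SCAN_START]
                            rt = float(p["value"])
                            unit = p.get("unitName", "minute")
                            rt_min = rt / 60.0 if unit.startswith("second") else rt
                        break
                if rt_min is None:
                    elem.clear()
                    continue
                if _ACC_NEG_SCAN in accs:
                    polarity = "negative"
                elif _ACC_POS_SCAN in accs:
                    polarity = "positive"
                mz = inten = None
                for bda in elem.iter():
                    if _localname(bda.tag) != "binaryDataArray":
                        continue
                    arr_accs = _cv_accessions(bda)
                    if _ACC_MZ_ARRAY in arr_accs:
                        mz = _decode_binary_array(bda)
                    elif _ACC_INT_ARRAY in arr_accs:
                        inten = _decode_binary_array(bda)
                if mz is None or inten is None:
                    elem.clear()
                    continue
                if _ACC_PROFILE in accs:
                    if not centroid_profile:
                        raise MsIoError(
                            f"{path}: profile-mode spectrum at {rt_min:.3f} min; "
                            "pass centroid_profile=True to centroid it"
                        )
                    mz, inten = _centroid_profile(mz, inten)
                spectra.append(Spectrum(rt_min=rt_min, mz=mz, intensity=inten))
                elem.clear()
    except ET.ParseError as exc:
        raise MsIoError(f"{path} is not well-formed XML: {exc}") from exc
    if not saw_mzml_root:
        raise MsIoError(f"{path} is not an mzML document")
    if not spectra:
        raise NoSpectraError(f"{path}: no MS1 spectra")
    run_id = os.path.basename(path)
    for suffix in (".gz", ".mzML", ".mzml"):
        if run_id.endswith(suffix):
            run_id = run_id[: -len(suffix)]
    return SpectrumRun(spectra=spectra, polarity=polarity, run_id=run_id)


def _encode_array(values: np.ndarray, compress: bool) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


_POLARITY_CV = {
    "negative": ("MS:1000129", "negative scan"),
    "positive": ("MS:1000130", "positive scan"),
}


def write_mzml(run: SpectrumRun, path: str | os.PathLike, *, compress: bool = True) -> None:
    """Write a run as centroided mzML (64-bit float arrays, zlib by default)."""
    if not len(run):
        raise NoSpectraError("refusing to write an empty run")
    path = os.fspath(path)
    pol_acc, pol_name = _POLARITY_CV[run.polarity]
    comp_cv = (
        ("MS:1000574", "zlib compression")
        if compress
        else ("MS:1000576", "no compression")
    )
    lines: list[str] = []
    w = lines.append
    w('<?xml version="1.0" encoding="utf-8"?>')
    w('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">')
    w('  <cvList count="2">')
    w('    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>')
    w('    <cv id="UO" fullName="Unit Ontology" URI="http://purl.obolibrary.org/obo/uo.obo"/>')
    w('  </cvList>')
    w('  <fileDescription>')
    w('    <fileContent>')
    w('      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>')
    w('      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
    w('    </fileContent>')
    w('  </fileDescription>')
    w('  <softwareList count="1">')
    w('    <software id="vlcpufa" version="0.1.0"/>')
    w('  </softwareList>')
    w('  <instrumentConfigurationList count="1">')
    w('    <instrumentConfiguration id="IC1"/>')
    w('  </instrumentConfigurationList>')
    w('  <dataProcessingList count="1">')
    w('    <dataProcessing id="DP1">')
    w('      <processingMethod order="1" softwareRef="vlcpufa">')
    w('        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>')
    w('      </processingMethod>')
    w('    </dataProcessing>')
    w('  </dataProcessingList>')
    w(f'  <run id={quoteattr(run.run_id or "run")} defaultInstrumentConfigurationRef="IC1">')
    w(f'    <spectrumList count="{len(run)}" defaultDataProcessingRef="DP1">')
    for i, s in enumerate(run.spectra):
        n = s.mz.size
        w(f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">')
        w('        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>')
        w('        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>')
        w('        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
        w(f'        <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>')
        if run.scan_range is not None:
            lo, hi = run.scan_range
            w(f'        <cvParam cvRef="MS" accession="MS:1000528" name="lowest observed m/z" value="{lo!r}"/>')
            w(f'        <cvParam cvRef="MS" accession="MS:1000527" name="highest observed m/z" value="{hi!r}"/>')
        w('        <scanList count="1">')
        w('          <scan>')
        w(f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt_min!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>')
        w('          </scan>')
        w('        </scanList>')
        w('        <binaryDataArrayList count="2">')
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            b64 = _encode_array(arr, compress)
            w(f'          <binaryDataArray encodedLength="{len(b64)}">')
            w('            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>')
            w(f'            <cvParam cvRef="MS" accession="{comp_cv[0]}" name="{comp_cv[1]}" value=""/>')
            w(f'            <cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>')
            w(f'            <binary>{b64}</binary>')
            w('          </binaryDataArray>')
        w('        </binaryDataArrayList>')
        w('      </spectrum>')
    w('    </spectrumList>')
    w('  </run>')
    w('</mzML>')
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _open_text(path: str, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode, encoding="utf-8")


def write_tsv_run(run: SpectrumRun, path: str | os.PathLike) -> None:
    """Write a run in the long-format TSV dialect (rt_min, mz, intensity)."""
    if not len(run):
        raise NoSpectraError("refusing to write an empty run")
    path = os.fspath(path)
    with _open_text(path, "w") as fh:
        fh.write("rt_min\tmz\tintensity\n")
        for s in run.spectra:
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{s.rt_min:.6f}\t{m:.6f}\t{i:.6f}\n")


def read_tsv_run(path: str | os.PathLike, *, run_id: str = "") -> SpectrumRun:
    """Read the long-format TSV dialect; rows with equal rt form one spectrum."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    groups: dict[str, tuple[float, list[float], list[float]]] = {}
    with _open_text(path, "r") as fh:
        header = fh.readline()
        if not header.strip():
            raise NoSpectraError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        if cols[:3] != ["rt_min", "mz", "intensity"]:
            raise MsIoError(f"{path}: expected header rt_min\\tmz\\tintensity")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise MsIoError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                rt, mz, inten = (float(p) for p in parts)
            except ValueError as exc:
                raise MsIoError(f"{path}:{lineno}: non-numeric cell") from exc
            key = parts[0]  # group on the exact decimal text of rt
            if key not in groups:
                groups[key] = (rt, [], [])
            groups[key][1].append(mz)
            groups[key][2].append(inten)
    if not groups:
        raise NoSpectraError(f"{path}: no spectra")
    spectra = [
        Spectrum(rt_min=rt, mz=np.array(mzs), intensity=np.array(ints))
        for rt, mzs, ints in groups.values()
    ]
    if not run_id:
        run_id = os.path.basename(path)
        for suffix in (".gz", ".tsv"):
            if run_id.endswith(suffix):
                run_id = run_id[: -len(suffix)]
    return SpectrumRun(spectra=spectra, run_id=run_id)
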