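"""Reading and writing of GC-MS raw data and spectral-library formats.

Raw runs are accepted as plain or indexed mzML and as ANDI-MS NetCDF
(netCDF3 classic); spectral libraries and the pipeline's spectrum output use
the NIST MSP dialect.  The final peak set is exported as a feature CSV and a
matching MSP file so that the results can be searched with standard library
software.

mzData is deliberately not supported (legacy format superseded by mzML);
asking for it raises ``UnsupportedFormatError``.
"""

from __future__ import annotations

import base64
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Scan",
    "RawRun",
    "SpectrumRecord",
    "ParseError",
    "UnsupportedFormatError",
    "read_raw",
    "write_mzml",
    "write_netcdf",
    "read_msp",
    "write_msp",
    "write_spectrum_records",
    "write_peak_csv",
]


class ParseError(ValueError):
    """Raised when an input file is structurally invalid."""


class UnsupportedFormatError(ValueError):
    """Raised for file formats the package intentionally does not read."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Scan:
    """A single MS scan: retention time plus parallel m/z / intensity arrays.

    m/z values are strictly ascending within the scan; intensities are
    non-negative 64-bit floats regardless of the on-disk encoding.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size:
            if np.any(np.diff(self.mz) <= 0):
                # merge duplicate m/z entries, then require strict order
                order = np.argsort(self.mz, kind="stable")
                mz, inv = np.unique(self.mz[order], return_inverse=True)
                inten = np.zeros_like(mz)
                np.add.at(inten, inv, self.intensity[order])
                self.mz, self.intensity = mz, inten
            if np.any(self.intensity < 0):
                raise ValueError("negative intensity in scan")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RawRun:
    """An RT-ordered sequence of scans from one GC-MS acquisition."""

    scans: list[Scan]
    sample_id: str = ""
    source_path: str = ""
    polarity: str | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        if len(self.scans) < 2:
            raise ValueError("a run needs at least 2 scans")
        rts = self.rts
        if np.any(np.diff(rts) <= 0):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=np.float64)

    @property
    def rt_range(self) -> tuple[float, float]:
        return float(self.scans[0].rt), float(self.scans[-1].rt)

    def tic(self) -> np.ndarray:
        return np.array([s.tic for s in self.scans], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class SpectrumRecord:
    """One spectral-library entry: name, optional retention index, peak list.

    Intensities are max-normalised to 1.0 on construction, whatever scale
    the source dialect used (999 for NIST, 100, or already-relative).
    """

    name: str
    peaks: list[tuple[float, float]]
    ri: float | None = None
    rt: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"spectrum record {self.name!r} has no peaks")
        top = max(i for _, i in self.peaks)
        if top <= 0:
            raise ValueError(f"spectrum record {self.name!r} has no positive intensity")
        self.peaks = [(float(m), float(i) / top) for m, i in self.peaks if i > 0]
        self.peaks.sort(key=lambda p: p[0])

    def mz_array(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    def intensity_array(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_NS = "http://psi.hupo.org/ms/mzml"

_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_RT = "MS:1000016"


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda, spectrum_id: str) -> tuple[str, np.ndarray]:
    accessions = set()
    text = None
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            accessions.add(child.get("accession"))
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text) if text else b""
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f8" if _ACC_F64 in accessions else "<f4"
    values = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if _ACC_MZ in accessions:
        kind = "mz"
    elif _ACC_INT in accessions:
        kind = "intensity"
    else:
        raise ParseError(
            f"binaryDataArray in spectrum {spectrum_id!r} declares neither "
            "an m/z array nor an intensity array"
        )
    return kind, values


def _read_mzml(path: Path) -> RawRun:
    scans: list[Scan] = []
    try:
        context = etree.iterparse(str(path), events=("end",),
                                  tag=f"{{{_NS}}}spectrum")
        for _, spectrum in context:
            spec_id = spectrum.get("id", f"index={spectrum.get('index')}")
            ms_level = 1
            rt = None
            arrays: dict[str, np.ndarray] = {}
            for el in spectrum.iter():
                name = _local(el.tag)
                if name == "cvParam":
                    acc = el.get("accession")
                    if acc == "MS:1000511":
                        ms_level = int(el.get("value") or 1)
                    elif acc == _ACC_RT:
                        rt = float(el.get("value"))
                        if (el.get("unitName") or "").startswith("minute"):
                            rt *= 60.0
                elif name == "binaryDataArray":
                    kind, values = _decode_binary_array(el, spec_id)
                    arrays[kind] = values
            if ms_level != 1:
                spectrum.clear()
                continue
            if rt is None:
                raise ParseError(f"spectrum {spec_id!r} has no scan start time")
            if "mz" not in arrays or "intensity" not in arrays:
                raise ParseError(f"spectrum {spec_id!r} lacks m/z or intensity array")
            if len(arrays["mz"]) != len(arrays["intensity"]):
                raise ParseError(
                    f"spectrum {spec_id!r}: m/z and intensity lengths differ"
                )
            scans.append(Scan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"]))
            spectrum.clear()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed mzML in {path.name}: {exc}") from exc
    if not scans:
        raise ParseError(f"no scans in {path.name}")
    scans.sort(key=lambda s: s.rt)
    return RawRun(scans=scans, sample_id=path.stem, source_path=str(path))


def write_mzml(run: RawRun, path: str | Path) -> None:
    """Write a run as plain (non-indexed) mzML 1.1 with 64-bit float arrays."""
    path = Path(path)
    parts: list[str] = []
    for i, scan in enumerate(run.scans):
        b_mz = base64.b64encode(scan.mz.astype("<f8").tobytes()).decode()
        b_in = base64.b64encode(scan.intensity.astype("<f8").tobytes()).decode()
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(b_mz)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f"<binary>{b_mz}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(b_in)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            f"<binary>{b_in}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<mzML xmlns="{_NS}" version="1.1.0">\n'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>\n"
        f'<run id="{run.sample_id or "run"}">\n'
        f'<spectrumList count="{len(run.scans)}">\n'
        + "\n".join(parts)
        + "\n</spectrumList>\n</run>\n</mzML>\n"
    )
    path.write_text(doc, encoding="utf-8")


# ---------------------------------------------------------------------------
# ANDI-MS NetCDF
# ---------------------------------------------------------------------------

def _read_netcdf(path: Path) -> RawRun:
    from scipy.io import netcdf_file

    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:  # scipy raises bare TypeError/ValueError on junk
        raise ParseError(f"cannot read NetCDF file {path.name}: {exc}") from exc
    try:
        try:
            rts = np.asarray(nc.variables["scan_acquisition_time"][:], dtype=np.float64)
            index = np.asarray(nc.variables["scan_index"][:], dtype=np.int64)
            mass = np.asarray(nc.variables["mass_values"][:], dtype=np.float64)
            inten = np.asarray(nc.variables["intensity_values"][:], dtype=np.float64)
        except KeyError as exc:
            raise ParseError(
                f"{path.name} is missing ANDI-MS variable {exc.args[0]!r}"
            ) from exc
        if rts.size == 0:
            raise ParseError(f"no scans in {path.name}")
        bounds = np.append(index, mass.size)
        scans = [
            Scan(rt=float(rts[i]), mz=mass[bounds[i]:bounds[i + 1]],
                 intensity=inten[bounds[i]:bounds[i + 1]])
            for i in range(rts.size)
        ]
    finally:
        nc.close()
    scans.sort(key=lambda s: s.rt)
    return RawRun(scans=scans, sample_id=path.stem, source_path=str(path))


def write_netcdf(run: RawRun, path: str | Path) -> None:
    """Write a run in ANDI-MS layout (netCDF3 classic)."""
    from scipy.io import netcdf_file

    path = Path(path)
    counts = np.array([s.mz.size for s in run.scans], dtype=np.int32)
    index = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int32)
    mass = np.concatenate([s.mz for s in run.scans]) if counts.sum() else np.empty(0)
    inten = np.concatenate([s.intensity for s in run.scans]) if counts.sum() else np.empty(0)

    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", len(run.scans))
        nc.createDimension("point_number", int(counts.sum()))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = run.rts
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = index
        v = nc.createVariable("point_count", "i", ("scan_number",))
        v[:] = counts
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = mass
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = inten


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_raw(path: str | Path, format: str = "auto") -> RawRun:
    """Read a raw GC-MS run from mzML or ANDI-MS NetCDF.

    Parameters
    ----------
    path:
        Input file. With ``format="auto"`` the format is resolved from the
        extension (``.mzml`` / ``.cdf`` / ``.nc``).
    format:
        ``"mzml"``, ``"netcdf"`` or ``"auto"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower()
        if ext == ".mzml":
            fmt = "mzml"
        elif ext in (".cdf", ".nc"):
            fmt = "netcdf"
        elif ext == ".mzdata":
            fmt = "mzdata"
        else:
            raise UnsupportedFormatError(f"cannot infer format from extension {ext!r}")
    if fmt == "mzml":
        return _read_mzml(path)
    if fmt == "netcdf":
        return _read_netcdf(path)
    if fmt == "mzdata":
        raise UnsupportedFormatError("unsupported format: mzData")
    raise UnsupportedFormatError(f"unsupported format: {format}")


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_RI_KEYS = {"retention_index", "retentionindex", "ri"}
_RT_KEYS = {"rt", "retention_time", "retentiontime"}


def read_msp(path: str | Path) -> list[SpectrumRecord]:
    """Parse a NIST-dialect MSP library.

    Intensities on any positive scale are accepted and max-normalised to 1.0.
    A record whose ``Num Peaks`` header disagrees with the number of listed
    pairs raises :class:`ParseError` naming the record.
    """
    path = Path(path)
    records: list[SpectrumRecord] = []
    name = None
    ri = rt = None
    declared = None
    meta: dict = {}
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, ri, rt, declared, meta, peaks
        if name is None and not peaks:
            return
        rec_name = name or f"record_{len(records) + 1}"
        if declared is not None and declared != len(peaks):
            raise ParseError(
                f"MSP record {rec_name!r}: Num Peaks declares {declared} "
                f"but {len(peaks)} pairs listed"
            )
        if not peaks:
            raise ParseError(f"MSP record {rec_name!r} has no peaks")
        records.append(SpectrumRecord(name=rec_name, peaks=peaks, ri=ri, rt=rt,
                                      metadata=meta))
        name, ri, rt, declared, meta, peaks = None, None, None, None, {}, []

    pair_re = re.compile(r"([\d.eE+-]+)[\s:]+([\d.eE+-]+)")
    for raw_line in path.read_text(encoding="utf-8").splitlines():
        line = raw_line.strip()
        if not line:
            flush()
            continue
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "_")
            value = value.strip()
            if key_norm == "name":
                name = value
            elif key_norm == "num_peaks":
                declared = int(value)
            elif key_norm in _RI_KEYS:
                ri = float(value)
            elif key_norm in _RT_KEYS:
                rt = float(value)
            else:
                meta[key.strip()] = value
        else:
            for m, i in pair_re.findall(line.replace(";", " ")):
                peaks.append((float(m), float(i)))
    flush()
    return records


def write_spectrum_records(records: Iterable[SpectrumRecord], path: str | Path) -> None:
    """Write records in NIST MSP dialect (intensities scaled to max 999)."""
    path = Path(path)
    blocks = []
    for rec in records:
        lines = [f"Name: {rec.name}"]
        if rec.rt is not None:
            lines.append(f"RT: {rec.rt:.3f}")
        if rec.ri is not None:
            lines.append(f"Retention_index: {rec.ri:.1f}")
        lines.append(f"Num Peaks: {len(rec.peaks)}")
        for mz, inten in rec.peaks:
            scaled = max(1, int(round(inten * 999)))
            lines.append(f"{mz:.4f} {scaled}")
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


def write_msp(peakset, path: str | Path, partition: str = "high") -> None:
    """Export one partition of a final peak set as an MSP file.

    Every feature must carry at least one (m/z, intensity) pair; an empty
    spectrum raises ``ValueError`` naming the feature.
    """
    records = []
    for feat in peakset.partition(partition):
        pairs = [(mz, h) for mz, h, _ in feat.mz_list if h > 0]
        if not pairs:
            raise ValueError(f"feature {feat.feature_id!r} has an empty spectrum")
        records.append(
            SpectrumRecord(name=feat.feature_id, peaks=pairs,
                           ri=feat.ri, rt=feat.rt_apex)
        )
    write_spectrum_records(records, path)


# ---------------------------------------------------------------------------
# feature CSV
# ---------------------------------------------------------------------------

def write_peak_csv(peakset, path: str | Path, partition: str = "high",
                   kind: str = "height") -> None:
    """Write one row per feature: identity, RT window, RI, class, provenance,
    then one absolute-intensity column per sample (apex height summed over the
    feature's m/z list by default; ``kind="area"`` switches to integrated
    areas)."""
    import pandas as pd

    path = Path(path)
    table = peakset.intensity_matrix(kind=kind)
    samples = list(table.columns)
    rows = []
    for feat in peakset.partition(partition):
        row = {
            "feature_id": feat.feature_id,
            "rt_apex_s": round(float(feat.rt_apex), 3),
            "rt_start_s": round(float(feat.rt_start), 3),
            "rt_end_s": round(float(feat.rt_end), 3),
            "ri": "" if feat.ri is None else round(float(feat.ri), 2),
            "n_mz": len(feat.mz_list),
            "class_label": feat.class_label,
            "source_algorithms": ";".join(sorted(feat.source_algorithms)),
        }
        for s in samples:
            row[s] = (
                table.loc[feat.feature_id, s]
                if feat.feature_id in table.index else 0.0
            )
        rows.append(row)
    columns = ["feature_id", "rt_apex_s", "rt_start_s", "rt_end_s", "ri",
               "n_mz", "class_label", "source_algorithms"] + samples
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
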