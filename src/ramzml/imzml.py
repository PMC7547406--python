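"""imzML writing, reading and validation.

imzML stores an imaging dataset as two linked files: an XML index
(``.imzML``) and a flat binary file (``.ibd``) whose first 16 bytes are a
UUID echoed in the XML. Spectral arrays live in the binary file and the
XML records, per spectrum, each array's *external offset* (byte position),
*external array length* (value count) and *external encoded length* (byte
size). Two layouts exist:

* **continuous** — the shared axis array is stored once, directly after the
  UUID, and each spectrum stores only its intensity array;
* **processed** — every spectrum stores its own axis and intensity arrays.

A Raman map always has a shared axis, so continuous is the default (and
halves the file size); processed mode is kept for generality. All arrays
are encoded as little-endian IEEE-754 32-bit floats, uncompressed. The
Raman-shift axis is written into the "m/z array" slot: the imzML controlled
vocabulary has no Raman terms, so only numeric imaging information survives
conversion — acquisition metadata (integration time, excitation wavelength,
laser power) is not preserved, by design.
"""

from __future__ import annotations

import hashlib
import os
import uuid as _uuid
import warnings
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np

from .errors import (ChecksumMismatch, ChecksumWarning, DimensionMismatch,
                     EmptyMap, IOFailure, MalformedXML, OffsetOutOfBounds,
                     UnknownDialect)
from .maps import GridMapping, RamanMap
from .vendor_text import ParseOptions, parse_renishaw, parse_witec, sniff_dialect

__all__ = [
    "BinaryIndex", "SpectrumEntry", "ImzMLPair", "ConversionReport",
    "ValidationReport", "Finding", "build_binary_index", "write_ibd",
    "write_imzml_xml", "read_imzml", "read_binary_index", "validate", "convert",
]

NS = "http://psi.hupo.org/ms/mzml"
_Q = "{%s}" % NS

BYTES_PER_VALUE = 4  # 32-bit float
UUID_HEADER_SIZE = 16

# controlled-vocabulary accessions (PSI-MS + imaging MS ontology)
CV_CONTINUOUS = "IMS:1000030"
CV_PROCESSED = "IMS:1000031"
CV_UUID = "IMS:1000080"
CV_SHA1 = "IMS:1000091"
CV_EXTERNAL_DATA = "IMS:1000101"
CV_EXTERNAL_OFFSET = "IMS:1000102"
CV_EXTERNAL_ARRAY_LENGTH = "IMS:1000103"
CV_EXTERNAL_ENCODED_LENGTH = "IMS:1000104"
CV_MAX_PIXELS_X = "IMS:1000042"
CV_MAX_PIXELS_Y = "IMS:1000043"
CV_PIXEL_SIZE_X = "IMS:1000046"
CV_PIXEL_SIZE_Y = "IMS:1000047"
CV_POSITION_X = "IMS:1000050"
CV_POSITION_Y = "IMS:1000051"
CV_MZ_ARRAY = "MS:1000514"
CV_INTENSITY_ARRAY = "MS:1000515"
CV_32BIT_FLOAT = "MS:1000521"
CV_NO_COMPRESSION = "MS:1000576"


@dataclass(frozen=True)
class SpectrumEntry:
    """Byte layout of one spectrum's arrays inside the .ibd file."""

    axis_offset: int
    axis_length: int
    axis_encoded_length: int
    intensity_offset: int
    intensity_length: int
    intensity_encoded_length: int


@dataclass
class BinaryIndex:
    """Computed .ibd layout: where every array lives and the total size."""

    mode: str
    uuid: bytes
    entries: list[SpectrumEntry]
    total_size: int

    def __post_init__(self):
        if self.mode not in ("continuous", "processed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.uuid) != UUID_HEADER_SIZE:
            raise ValueError("uuid must be 16 raw bytes")

    def __eq__(self, other):
        if not isinstance(other, BinaryIndex):
            return NotImplemented
        return (self.mode == other.mode and self.uuid == other.uuid
                and self.entries == other.entries
                and self.total_size == other.total_size)


@dataclass(frozen=True)
class ImzMLPair:
    """A written .imzML/.ibd pair plus its integrity identifiers."""

    xml_path: str
    ibd_path: str
    uuid: bytes
    sha1: str
    mode: str


@dataclass(frozen=True)
class ConversionReport:
    n_pixels: int
    n_channels: int
    axis_range: tuple[float, float]
    lost_metadata_note: str


LOST_METADATA_NOTE = (
    "Only numeric imaging information (pixel positions, Raman shift axis, "
    "intensity values) is preserved; acquisition metadata such as integration "
    "time and excitation wavelength is not carried into imzML."
)


def _coerce_uuid(value) -> bytes:
    if value is None:
        return _uuid.uuid4().bytes
    if isinstance(value, bytes):
        if len(value) != UUID_HEADER_SIZE:
            raise ValueError("uuid must be exactly 16 bytes")
        return value
    return _uuid.UUID(str(value)).bytes


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def build_binary_index(ramap: RamanMap, mode: str = "continuous",
                       uuid=None) -> BinaryIndex:
    """Compute exact byte offsets for every array in the .ibd file.

    Continuous layout: ``[UUID 16B][axis][intensity_1]...[intensity_n]``;
    processed layout: ``[UUID 16B][axis_1][intensity_1][axis_2]...``.
    Spectra follow the map's canonical row-major pixel order.
    """
    if mode not in ("continuous", "processed"):
        raise ValueError(f"unknown mode {mode!r}")
    n_ch = ramap.n_channels
    n_px = ramap.n_pixels
    if n_ch < 1 or n_px < 1:
        raise EmptyMap("cannot lay out an empty map")

    axis_bytes = BYTES_PER_VALUE * n_ch
    entries = []
    cursor = UUID_HEADER_SIZE
    if mode == "continuous":
        shared_axis_offset = cursor
        cursor += axis_bytes
        for _ in range(n_px):
            entries.append(SpectrumEntry(
                axis_offset=shared_axis_offset, axis_length=n_ch,
                axis_encoded_length=axis_bytes,
                intensity_offset=cursor, intensity_length=n_ch,
                intensity_encoded_length=axis_bytes))
            cursor += axis_bytes
    else:
        for _ in range(n_px):
            a_off = cursor
            cursor += axis_bytes
            i_off = cursor
            cursor += axis_bytes
            entries.append(SpectrumEntry(
                axis_offset=a_off, axis_length=n_ch,
                axis_encoded_length=axis_bytes,
                intensity_offset=i_off, intensity_length=n_ch,
                intensity_encoded_length=axis_bytes))
    return BinaryIndex(mode=mode, uuid=_coerce_uuid(uuid), entries=entries,
                       total_size=cursor)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _f32le(values: np.ndarray) -> bytes:
    return np.ascontiguousarray(values, dtype="<f4").tobytes()


def write_ibd(ramap: RamanMap, index: BinaryIndex, out) -> tuple[str, int]:
    """Write the binary half of the pair; returns (sha1 hex, byte count).

    Values are converted to little-endian IEEE-754 single precision
    (round-to-nearest). The SHA-1 covers the whole file, UUID header
    included.
    """
    own = isinstance(out, (str, os.PathLike))
    try:
        fh = open(out, "wb") if own else out
    except OSError as exc:
        raise IOFailure(f"cannot open {out}: {exc}") from exc
    digest = hashlib.sha1()
    written = 0

    def _emit(data: bytes):
        nonlocal written
        fh.write(data)
        digest.update(data)
        written += len(data)

    try:
        _emit(index.uuid)
        if index.mode == "continuous":
            _emit(_f32le(ramap.axis))
            for spectrum in ramap.intensities:
                _emit(_f32le(spectrum))
        else:
            axis_bytes = _f32le(ramap.axis)
            for spectrum in ramap.intensities:
                _emit(axis_bytes)
                _emit(_f32le(spectrum))
    except OSError as exc:
        raise IOFailure(f"write failed on {out}: {exc}") from exc
    finally:
        if own:
            fh.close()
    if written != index.total_size:
        raise IOFailure(f"wrote {written} bytes, index declares {index.total_size}")
    return digest.hexdigest(), written


def _cv(parent, cv_ref, accession, name, value="", **attrs):
    el = ET.SubElement(parent, _Q + "cvParam")
    el.set("cvRef", cv_ref)
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", str(value))
    for k, v in attrs.items():
        el.set(k, str(v))
    return el


def write_imzml_xml(ramap: RamanMap, index: BinaryIndex, sha1: str, out) -> None:
    """Write the XML half of the pair.

    Emits a minimal standards-conformant document: binary-mode term, UUID
    and SHA-1 in the file content; referenceable param groups declaring
    external uncompressed 32-bit float arrays; scan settings with the pixel
    grid dimensions and pixel sizes; and per spectrum the integer position
    and the three external-array terms for each of the two arrays. The
    ``<binary>`` elements are empty — all data is external.
    """
    ET.register_namespace("", NS)
    root = ET.Element(_Q + "mzML", version="1.1")

    cv_list = ET.SubElement(root, _Q + "cvList", count="3")
    for cid, full, uri in [
        ("MS", "Proteomics Standards Initiative Mass Spectrometry Ontology",
         "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
        ("UO", "Unit Ontology", "https://unit-ontology.googlecode.com/svn/trunk/unit.obo"),
        ("IMS", "Imaging MS Ontology",
         "https://ms-imaging.org/wp-content/uploads/2009/08/imagingMS.obo"),
    ]:
        ET.SubElement(cv_list, _Q + "cv", id=cid, fullName=full, URI=uri)

    fdesc = ET.SubElement(root, _Q + "fileDescription")
    fcontent = ET.SubElement(fdesc, _Q + "fileContent")
    if index.mode == "continuous":
        _cv(fcontent, "IMS", CV_CONTINUOUS, "continuous")
    else:
        _cv(fcontent, "IMS", CV_PROCESSED, "processed")
    _cv(fcontent, "IMS", CV_UUID, "universally unique identifier",
        "{%s}" % _uuid.UUID(bytes=index.uuid))
    _cv(fcontent, "IMS", CV_SHA1, "ibd SHA-1", sha1.lower())

    rpg_list = ET.SubElement(root, _Q + "referenceableParamGroupList", count="2")
    mz_group = ET.SubElement(rpg_list, _Q + "referenceableParamGroup", id="mzArray")
    _cv(mz_group, "MS", CV_MZ_ARRAY, "m/z array",
        unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
    _cv(mz_group, "MS", CV_32BIT_FLOAT, "32-bit float")
    _cv(mz_group, "MS", CV_NO_COMPRESSION, "no compression")
    _cv(mz_group, "IMS", CV_EXTERNAL_DATA, "external data", "true")
    int_group = ET.SubElement(rpg_list, _Q + "referenceableParamGroup",
                              id="intensityArray")
    _cv(int_group, "MS", CV_INTENSITY_ARRAY, "intensity array",
        unitCvRef="MS", unitAccession="MS:1000131", unitName="number of detector counts")
    _cv(int_group, "MS", CV_32BIT_FLOAT, "32-bit float")
    _cv(int_group, "MS", CV_NO_COMPRESSION, "no compression")
    _cv(int_group, "IMS", CV_EXTERNAL_DATA, "external data", "true")

    sw_list = ET.SubElement(root, _Q + "softwareList", count="1")
    sw = ET.SubElement(sw_list, _Q + "software", id="ramzml", version="0.1.0")
    _cv(sw, "MS", "MS:1000799", "custom unreleased software tool", "ramzml")

    ss_list = ET.SubElement(root, _Q + "scanSettingsList", count="1")
    ss = ET.SubElement(ss_list, _Q + "scanSettings", id="scanSettings1")
    _cv(ss, "IMS", CV_MAX_PIXELS_X, "max count of pixels x", ramap.grid.width)
    _cv(ss, "IMS", CV_MAX_PIXELS_Y, "max count of pixels y", ramap.grid.height)
    _cv(ss, "IMS", CV_PIXEL_SIZE_X, "pixel size (x)", ramap.grid.step_x,
        unitCvRef="UO", unitAccession="UO:0000017", unitName="micrometer")
    _cv(ss, "IMS", CV_PIXEL_SIZE_Y, "pixel size y", ramap.grid.step_y,
        unitCvRef="UO", unitAccession="UO:0000017", unitName="micrometer")

    ic_list = ET.SubElement(root, _Q + "instrumentConfigurationList", count="1")
    ic = ET.SubElement(ic_list, _Q + "instrumentConfiguration", id="IC1")
    ET.SubElement(ic, _Q + "componentList", count="0")

    dp_list = ET.SubElement(root, _Q + "dataProcessingList", count="1")
    dp = ET.SubElement(dp_list, _Q + "dataProcessing", id="export")
    pm = ET.SubElement(dp, _Q + "processingMethod", order="1", softwareRef="ramzml")
    _cv(pm, "MS", "MS:1000544", "Conversion to mzML")

    run = ET.SubElement(root, _Q + "run", id="run1",
                        defaultInstrumentConfigurationRef="IC1")
    sp_list = ET.SubElement(run, _Q + "spectrumList",
                            count=str(ramap.n_pixels),
                            defaultDataProcessingRef="export")
    for i, (entry, (col, row)) in enumerate(zip(index.entries, ramap.pixels)):
        sp = ET.SubElement(sp_list, _Q + "spectrum", index=str(i),
                           id=f"spectrum={i + 1}",
                           defaultArrayLength=str(ramap.n_channels))
        scan_list = ET.SubElement(sp, _Q + "scanList", count="1")
        _cv(scan_list, "MS", "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, _Q + "scan")
        _cv(scan, "IMS", CV_POSITION_X, "position x", int(col))
        _cv(scan, "IMS", CV_POSITION_Y, "position y", int(row))
        bda_list = ET.SubElement(sp, _Q + "binaryDataArrayList", count="2")
        for group, off, length, enc in (
                ("mzArray", entry.axis_offset, entry.axis_length,
                 entry.axis_encoded_length),
                ("intensityArray", entry.intensity_offset,
                 entry.intensity_length, entry.intensity_encoded_length)):
            bda = ET.SubElement(bda_list, _Q + "binaryDataArray",
                                encodedLength="0")
            ET.SubElement(bda, _Q + "referenceableParamGroupRef", ref=group)
            _cv(bda, "IMS", CV_EXTERNAL_OFFSET, "external offset", off)
            _cv(bda, "IMS", CV_EXTERNAL_ARRAY_LENGTH, "external array length", length)
            _cv(bda, "IMS", CV_EXTERNAL_ENCODED_LENGTH, "external encoded length", enc)
            ET.SubElement(bda, _Q + "binary")

    tree = ET.ElementTree(root)
    ET.indent(tree)
    try:
        tree.write(out, encoding="unicode" if hasattr(out, "write") else "utf-8",
                   xml_declaration=True)
    except OSError as exc:
        raise IOFailure(f"cannot write {out}: {exc}") from exc


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

@dataclass
class _XmlHeader:
    mode: str
    uuid: bytes
    sha1: str
    width: int
    height: int
    step_x: float
    step_y: float
    positions: np.ndarray          # (n, 2) 1-based (col, row)
    index: BinaryIndex
    mode_term_count: int = 1


def _find_cv(elem, accession):
    return elem.find(f'.//{_Q}cvParam[@accession="{accession}"]')


def _cv_value(elem, accession, default=None):
    node = _find_cv(elem, accession)
    return node.get("value") if node is not None else default


def _parse_xml_header(xml_path) -> _XmlHeader:
    try:
        root = ET.parse(xml_path).getroot()
    except (ET.ParseError, OSError) as exc:
        raise MalformedXML(f"cannot parse {xml_path}: {exc}") from exc

    fcontent = root.find(f"{_Q}fileDescription/{_Q}fileContent")
    if fcontent is None:
        raise MalformedXML("missing fileDescription/fileContent")
    mode_terms = [p.get("accession") for p in fcontent.findall(_Q + "cvParam")
                  if p.get("accession") in (CV_CONTINUOUS, CV_PROCESSED)]
    mode = "continuous"
    if mode_terms:
        mode = "continuous" if mode_terms[0] == CV_CONTINUOUS else "processed"
    uuid_str = _cv_value(fcontent, CV_UUID)
    if uuid_str is None:
        raise MalformedXML("missing UUID term in fileContent")
    uuid_bytes = _uuid.UUID(uuid_str.strip().strip("{}")).bytes
    sha1 = (_cv_value(fcontent, CV_SHA1) or "").strip().lower()

    ss_list = root.find(f"{_Q}scanSettingsList")
    width = height = None
    step_x = step_y = 1.0
    if ss_list is not None:
        w = _cv_value(ss_list, CV_MAX_PIXELS_X)
        h = _cv_value(ss_list, CV_MAX_PIXELS_Y)
        width = int(w) if w is not None else None
        height = int(h) if h is not None else None
        step_x = float(_cv_value(ss_list, CV_PIXEL_SIZE_X, 1.0))
        step_y = float(_cv_value(ss_list, CV_PIXEL_SIZE_Y, 1.0))

    spectra = root.findall(f"{_Q}run/{_Q}spectrumList/{_Q}spectrum")
    if not spectra:
        raise MalformedXML("no spectra in spectrumList")
    positions = []
    entries = []
    max_end = UUID_HEADER_SIZE
    for sp in spectra:
        scan = sp.find(f"{_Q}scanList/{_Q}scan")
        if scan is None:
            raise MalformedXML(f"spectrum {sp.get('id')} lacks a scan element")
        x = _cv_value(scan, CV_POSITION_X)
        y = _cv_value(scan, CV_POSITION_Y)
        if x is None or y is None:
            raise MalformedXML(f"spectrum {sp.get('id')} lacks position terms")
        positions.append((int(x), int(y)))

        arrays = {}
        for bda in sp.findall(f"{_Q}binaryDataArrayList/{_Q}binaryDataArray"):
            ref_el = bda.find(_Q + "referenceableParamGroupRef")
            ref = ref_el.get("ref") if ref_el is not None else None
            off = _cv_value(bda, CV_EXTERNAL_OFFSET)
            length = _cv_value(bda, CV_EXTERNAL_ARRAY_LENGTH)
            enc = _cv_value(bda, CV_EXTERNAL_ENCODED_LENGTH)
            if None in (ref, off, length, enc):
                raise MalformedXML(
                    f"spectrum {sp.get('id')}: incomplete external array terms")
            arrays[ref] = (int(off), int(length), int(enc))
        if "mzArray" not in arrays or "intensityArray" not in arrays:
            raise MalformedXML(
                f"spectrum {sp.get('id')}: missing m/z or intensity array")
        (ao, al, ae), (io_, il, ie) = arrays["mzArray"], arrays["intensityArray"]
        entries.append(SpectrumEntry(ao, al, ae, io_, il, ie))
        max_end = max(max_end, ao + ae, io_ + ie)

    index = BinaryIndex(mode=mode, uuid=uuid_bytes, entries=entries,
                        total_size=max_end)
    pos = np.asarray(positions, dtype=int)
    if width is None:
        width = int(pos[:, 0].max())
    if height is None:
        height = int(pos[:, 1].max())
    return _XmlHeader(mode=mode, uuid=uuid_bytes, sha1=sha1, width=width,
                      height=height, step_x=step_x, step_y=step_y,
                      positions=pos, index=index,
                      mode_term_count=len(mode_terms))


def read_binary_index(xml_path) -> BinaryIndex:
    """Re-parse the binary layout declared by an imzML document."""
    return _parse_xml_header(xml_path).index


def _sha1_of_file(path) -> str:
    digest = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def read_imzml(xml_path, ibd_path, *, strict_checksum: bool = False) -> RamanMap:
    """Read an imzML pair back into a :class:`RamanMap`.

    Values are returned exactly as stored (32-bit floats widened to float64,
    no precision invented). In continuous mode the shared axis is read once.
    A SHA-1 or UUID mismatch warns by default (:class:`ChecksumWarning`) and
    raises :class:`ChecksumMismatch` when ``strict_checksum`` is set.
    """
    header = _parse_xml_header(xml_path)
    file_size = os.path.getsize(ibd_path)
    with open(ibd_path, "rb") as fh:
        ibd_uuid = fh.read(UUID_HEADER_SIZE)

    def _integrity(problem: str):
        if strict_checksum:
            raise ChecksumMismatch(problem)
        warnings.warn(problem, ChecksumWarning, stacklevel=2)

    if ibd_uuid != header.uuid:
        _integrity("UUID in XML does not match the .ibd header")
    if header.sha1 and _sha1_of_file(ibd_path) != header.sha1:
        _integrity("SHA-1 in XML does not match the .ibd contents")

    for e in header.index.entries:
        for off, enc in ((e.axis_offset, e.axis_encoded_length),
                         (e.intensity_offset, e.intensity_encoded_length)):
            if off < UUID_HEADER_SIZE or off + enc > file_size:
                raise OffsetOutOfBounds(
                    f"region [{off}, {off + enc}) outside .ibd of {file_size} bytes")

    with open(ibd_path, "rb") as fh:
        data = fh.read()

    def _array(off, length):
        return np.frombuffer(data, dtype="<f4", count=length, offset=off).astype(np.float64)

    first = header.index.entries[0]
    axis = _array(first.axis_offset, first.axis_length)
    intensities = np.empty((len(header.index.entries), first.intensity_length))
    for i, e in enumerate(header.index.entries):
        if header.mode == "processed" and i > 0:
            sp_axis = _array(e.axis_offset, e.axis_length)
            if not np.array_equal(sp_axis, axis):
                raise MalformedXML(
                    "processed-mode spectra with differing axes cannot form a "
                    "shared-axis map")
        intensities[i] = _array(e.intensity_offset, e.intensity_length)

    grid = GridMapping(step_x=header.step_x, step_y=header.step_y,
                       width=header.width, height=header.height)
    return RamanMap(axis=axis, pixels=header.positions,
                    intensities=intensities, grid=grid, source_dialect="imzml")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    code: str
    severity: str
    detail: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]

    def add(self, code: str, detail: str, severity: str = "error"):
        self.findings.append(Finding(code, severity, detail))


def validate(xml_path, ibd_path) -> ValidationReport:
    """Structural integrity check of an imzML pair; findings, not exceptions.

    An empty findings list means the pair is valid: UUIDs match, the SHA-1
    matches, every declared region fits inside the file, encoded lengths
    equal 4 x array length, continuous mode shares one axis region, the mode
    term appears exactly once, and no data regions overlap.
    """
    report = ValidationReport()
    try:
        header = _parse_xml_header(xml_path)
    except (MalformedXML, ValueError) as exc:
        report.add("MALFORMED_XML", str(exc))
        return report

    if header.mode_term_count != 1:
        report.add("MODE_TERM_COUNT",
                   f"binary-mode term declared {header.mode_term_count} times "
                   "(expected exactly once)")

    try:
        file_size = os.path.getsize(ibd_path)
        with open(ibd_path, "rb") as fh:
            ibd_uuid = fh.read(UUID_HEADER_SIZE)
    except OSError as exc:
        report.add("MISSING_IBD", str(exc))
        return report

    if len(ibd_uuid) < UUID_HEADER_SIZE or ibd_uuid != header.uuid:
        report.add("UUID_MISMATCH", "XML UUID differs from the .ibd header")

    if header.sha1:
        actual = _sha1_of_file(ibd_path)
        if actual != header.sha1:
            report.add("CHECKSUM_MISMATCH",
                       f"ibd SHA-1 {actual} != declared {header.sha1}")
    else:
        report.add("CHECKSUM_MISSING", "no ibd SHA-1 term in fileContent",
                   severity="warning")

    axis_offsets = set()
    regions = []  # (offset, end, kind)
    for i, e in enumerate(header.index.entries):
        axis_offsets.add(e.axis_offset)
        for kind, off, length, enc in (
                ("axis", e.axis_offset, e.axis_length, e.axis_encoded_length),
                ("intensity", e.intensity_offset, e.intensity_length,
                 e.intensity_encoded_length)):
            if enc != BYTES_PER_VALUE * length:
                report.add("ENCODED_LENGTH_INCONSISTENT",
                           f"spectrum {i + 1} {kind} array: encoded length {enc} "
                           f"!= 4 x {length}")
            if off < UUID_HEADER_SIZE or off + enc > file_size:
                report.add("OFFSET_OUT_OF_BOUNDS",
                           f"spectrum {i + 1} {kind} region [{off}, {off + enc}) "
                           f"exceeds file size {file_size}")
            regions.append((off, off + enc, kind))

    if header.mode == "continuous" and len(axis_offsets) > 1:
        report.add("AXIS_OFFSET_NOT_SHARED",
                   f"continuous mode but {len(axis_offsets)} distinct axis offsets")

    # overlap check; in continuous mode the shared axis region appears once
    dedup = sorted(set(regions))
    for (s1, e1, k1), (s2, e2, k2) in zip(dedup, dedup[1:]):
        if s2 < e1:
            report.add("REGION_OVERLAP",
                       f"{k1} region [{s1}, {e1}) overlaps {k2} region [{s2}, {e2})")
    return report


# ---------------------------------------------------------------------------
# conversion pipeline
# ---------------------------------------------------------------------------

def convert(input_path, out_basename, *, vendor: str = "auto",
            mode: str = "continuous", witec_width: int | None = None,
            witec_height: int | None = None, witec_step: tuple[float, float] = (1.0, 1.0),
            fill_order: str = "row_major", uuid=None,
            opts: ParseOptions = ParseOptions()) -> tuple[ImzMLPair, ConversionReport]:
    """Convert a vendor text export into an imzML pair.

    Writes ``out_basename + '.imzML'`` and ``out_basename + '.ibd'``. The
    UUID is freshly generated unless given (pass one for reproducible
    output). The report records what survives conversion — numeric imaging
    information only.
    """
    if vendor == "auto":
        try:
            with open(input_path, "r", encoding="utf-8") as fh:
                sample = "".join(fh.readline() for _ in range(50))
        except OSError as exc:
            raise IOFailure(f"cannot read {input_path}: {exc}") from exc
        detected = sniff_dialect(sample, opts)
        if detected == "unknown":
            raise UnknownDialect(
                f"could not identify the text dialect of {input_path}; "
                "pass vendor='renishaw' or vendor='witec'")
        vendor = {"renishaw_long": "renishaw", "witec_wide": "witec"}[detected]

    if vendor == "renishaw":
        ramap = parse_renishaw(input_path, opts)
    elif vendor == "witec":
        if witec_width is None or witec_height is None:
            raise DimensionMismatch(
                "the wide WITec format carries no coordinates: map width and "
                "height are required (witec_width / witec_height)")
        ramap = parse_witec(input_path, witec_width, witec_height,
                            fill_order=fill_order, step_x=witec_step[0],
                            step_y=witec_step[1], opts=opts)
    else:
        raise ValueError(f"unknown vendor {vendor!r}")

    return write_pair(ramap, out_basename, mode=mode, uuid=uuid)


def write_pair(ramap: RamanMap, out_basename, *, mode: str = "continuous",
               uuid=None) -> tuple[ImzMLPair, ConversionReport]:
    """Write a RamanMap as an imzML pair (the output half of convert)."""
    out_basename = os.fspath(out_basename)
    xml_path = out_basename + ".imzML"
    ibd_path = out_basename + ".ibd"
    index = build_binary_index(ramap, mode=mode, uuid=uuid)
    sha1, _ = write_ibd(ramap, index, ibd_path)
    write_imzml_xml(ramap, index, sha1, xml_path)
    pair = ImzMLPair(xml_path=xml_path, ibd_path=ibd_path, uuid=index.uuid,
                     sha1=sha1, mode=mode)
    report = ConversionReport(n_pixels=ramap.n_pixels,
                              n_channels=ramap.n_channels,
                              axis_range=ramap.axis_range,
                              lost_metadata_note=LOST_METADATA_NOTE)
    return pair, report
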