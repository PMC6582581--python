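"""Minimal DICOM adapter for CT series, RT Dose and RT Structure Sets.

Only the Explicit VR Little Endian transfer syntax (1.2.840.10008.1.2.1) is
supported, uncompressed, with axis-aligned identity orientation.  This is an
adapter over the package's own types; the research MetaImage/JSON formats are
the primary interchange.  Writing exists to support round-trip testing and
phantom export, not to produce clinically complete objects.
"""

from __future__ import annotations

import os
import struct
from typing import Dict, List, Tuple

import numpy as np

from ..errors import FormatError, GeometryError
from .types import StructureSet, VoxelGrid

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_UID_ROOT = "1.2.826.0.1.3680043.10.1487"  # generic org root for generated UIDs

_SHORT_LENGTH_VRS = {
    "AE", "AS", "AT", "CS", "DA", "DS", "DT", "FL", "FD", "IS", "LO", "LT",
    "PN", "SH", "SL", "SS", "ST", "TM", "UI", "UL", "US",
}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UI"}

Tag = Tuple[int, int]
Dataset = Dict[Tag, "object"]

# -- tags used by this adapter ------------------------------------------------
SOP_CLASS_UID = (0x0008, 0x0016)
SOP_INSTANCE_UID = (0x0008, 0x0018)
MODALITY = (0x0008, 0x0060)
SERIES_INSTANCE_UID = (0x0020, 0x000E)
INSTANCE_NUMBER = (0x0020, 0x0013)
IMAGE_POSITION = (0x0020, 0x0032)
IMAGE_ORIENTATION = (0x0020, 0x0037)
SLICE_THICKNESS = (0x0018, 0x0050)
SAMPLES_PER_PIXEL = (0x0028, 0x0002)
PHOTOMETRIC = (0x0028, 0x0004)
NUMBER_OF_FRAMES = (0x0028, 0x0008)
ROWS = (0x0028, 0x0010)
COLUMNS = (0x0028, 0x0011)
PIXEL_SPACING = (0x0028, 0x0030)
BITS_ALLOCATED = (0x0028, 0x0100)
BITS_STORED = (0x0028, 0x0101)
HIGH_BIT = (0x0028, 0x0102)
PIXEL_REPRESENTATION = (0x0028, 0x0103)
RESCALE_INTERCEPT = (0x0028, 0x1052)
RESCALE_SLOPE = (0x0028, 0x1053)
DOSE_UNITS = (0x3004, 0x0002)
DOSE_TYPE = (0x3004, 0x0004)
DOSE_SUMMATION = (0x3004, 0x000A)
GRID_FRAME_OFFSETS = (0x3004, 0x000C)
DOSE_GRID_SCALING = (0x3004, 0x000E)
STRUCTURE_SET_ROI_SEQ = (0x3006, 0x0020)
ROI_NUMBER = (0x3006, 0x0022)
ROI_NAME = (0x3006, 0x0026)
ROI_CONTOUR_SEQ = (0x3006, 0x0039)
CONTOUR_SEQ = (0x3006, 0x0040)
CONTOUR_GEOMETRIC_TYPE = (0x3006, 0x0042)
NUM_CONTOUR_POINTS = (0x3006, 0x0046)
CONTOUR_DATA = (0x3006, 0x0050)
REFERENCED_ROI_NUMBER = (0x3006, 0x0084)
PIXEL_DATA = (0x7FE0, 0x0010)

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

_uid_counter = 0


def _new_uid() -> str:
    global _uid_counter
    _uid_counter += 1
    return f"{_UID_ROOT}.{os.getpid()}.{_uid_counter}"


# =============================================================================
# Parsing
# =============================================================================

class _Reader:
    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def eof(self) -> bool:
        return self.pos >= len(self.buf)

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise FormatError("truncated DICOM element")
        out = self.buf[self.pos:self.pos + n]
        self.pos += n
        return out

    def u16(self) -> int:
        return struct.unpack("<H", self.take(2))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]


def _decode_value(vr: str, raw: bytes):
    if vr in ("OB", "OW", "OF", "UN"):
        return raw
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw) // 2}H", raw))
    elif vr == "SS":
        vals = list(struct.unpack(f"<{len(raw) // 2}h", raw))
    elif vr == "UL":
        vals = list(struct.unpack(f"<{len(raw) // 4}I", raw))
    elif vr == "SL":
        vals = list(struct.unpack(f"<{len(raw) // 4}i", raw))
    elif vr == "FL":
        vals = list(struct.unpack(f"<{len(raw) // 4}f", raw))
    elif vr == "FD":
        vals = list(struct.unpack(f"<{len(raw) // 8}d", raw))
    elif vr in ("DS", "IS"):
        text = raw.decode("ascii").strip("\x00 ").strip()
        if not text:
            return []
        conv = float if vr == "DS" else int
        vals = [conv(part) for part in text.split("\\")]
    elif vr in _STRING_VRS:
        text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
        vals = text.split("\\") if "\\" in text else [text]
    else:
        return raw
    return vals[0] if len(vals) == 1 else vals


def _parse_sequence(reader: _Reader, length: int) -> List[Dataset]:
    items: List[Dataset] = []
    end = None if length == 0xFFFFFFFF else reader.pos + length
    while True:
        if end is not None and reader.pos >= end:
            break
        group, elem = reader.u16(), reader.u16()
        item_len = reader.u32()
        if (group, elem) == (0xFFFE, 0xE0DD):  # sequence delimiter
            break
        if (group, elem) != (0xFFFE, 0xE000):
            raise FormatError(f"unexpected tag {(group, elem)} inside sequence")
        if item_len == 0xFFFFFFFF:
            item, stop = _parse_dataset(reader, stop_at_item_delim=True)
        else:
            sub = _Reader(reader.take(item_len))
            item, _ = _parse_dataset(sub)
        items.append(item)
    return items


def _parse_dataset(reader: _Reader, stop_at_item_delim: bool = False):
    ds: Dataset = {}
    while not reader.eof():
        group, elem = reader.u16(), reader.u16()
        if stop_at_item_delim and (group, elem) == (0xFFFE, 0xE00D):
            reader.u32()
            return ds, True
        vr = reader.take(2).decode("ascii")
        if vr in _SHORT_LENGTH_VRS:
            length = reader.u16()
        else:
            reader.take(2)  # reserved
            length = reader.u32()
        if vr == "SQ":
            ds[(group, elem)] = _parse_sequence(reader, length)
        else:
            if length == 0xFFFFFFFF:
                raise FormatError("undefined-length non-SQ elements not supported")
            ds[(group, elem)] = _decode_value(vr, reader.take(length))
    return ds, False


def read_dicom_file(path: str) -> Dataset:
    """Parse one DICOM Part-10 file (Explicit VR LE) into a flat dataset."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic (not a Part-10 file)")
    reader = _Reader(buf, 132)
    # file meta group: always explicit VR LE
    meta: Dataset = {}
    while not reader.eof():
        mark = reader.pos
        group = struct.unpack("<H", buf[mark:mark + 2])[0]
        if group != 0x0002:
            break
        group, elem = reader.u16(), reader.u16()
        vr = reader.take(2).decode("ascii")
        if vr in _SHORT_LENGTH_VRS:
            length = reader.u16()
        else:
            reader.take(2)
            length = reader.u32()
        meta[(group, elem)] = _decode_value(vr, reader.take(length))
    tsuid = meta.get((0x0002, 0x0010))
    if tsuid != EXPLICIT_VR_LE:
        raise FormatError(f"{path}: unsupported transfer syntax {tsuid!r}")
    ds, _ = _parse_dataset(reader)
    return ds


# =============================================================================
# High-level readers
# =============================================================================

def _as_list(value) -> list:
    return value if isinstance(value, list) else [value]


def read_dicom_ct_series(dirpath: str) -> VoxelGrid:
    """Read a directory of single-frame CT slices into a HU grid.

    Slices are sorted by the z component of ImagePositionPatient; the slice
    spacing must be uniform to within 1e-3 mm.
    """
    files = sorted(
        os.path.join(dirpath, f) for f in os.listdir(dirpath) if f.lower().endswith(".dcm")
    )
    if not files:
        raise FormatError(f"{dirpath}: no .dcm files found")
    slices = []
    for path in files:
        ds = read_dicom_file(path)
        if ds.get(MODALITY) != "CT":
            raise FormatError(f"{path}: modality {ds.get(MODALITY)!r}, expected CT")
        ipp = [float(v) for v in _as_list(ds[IMAGE_POSITION])]
        slices.append((ipp[2], ipp, ds))
    slices.sort(key=lambda s: s[0])
    zs = np.array([s[0] for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-3 or np.any(dz <= 0):
            raise GeometryError(f"{dirpath}: inconsistent slice spacing {sorted(set(np.round(dz, 4)))}")
        sz = float(dz[0])
    else:
        sz = float(slices[0][2].get(SLICE_THICKNESS, 1.0))

    first = slices[0][2]
    iop = [float(v) for v in _as_list(first.get(IMAGE_ORIENTATION, [1, 0, 0, 0, 1, 0]))]
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0]):
        raise GeometryError(f"{dirpath}: oblique orientation not supported")
    rows, cols = int(first[ROWS]), int(first[COLUMNS])
    row_sp, col_sp = (float(v) for v in _as_list(first[PIXEL_SPACING]))
    planes = []
    for _, ipp, ds in slices:
        if int(ds[BITS_ALLOCATED]) != 16:
            raise FormatError("only 16-bit CT pixel data supported")
        signed = int(ds.get(PIXEL_REPRESENTATION, 1)) == 1
        dtype = "<i2" if signed else "<u2"
        stored = np.frombuffer(ds[PIXEL_DATA], dtype=dtype, count=rows * cols)
        stored = stored.reshape(rows, cols).astype(np.float64)
        slope = float(ds.get(RESCALE_SLOPE, 1.0))
        intercept = float(ds.get(RESCALE_INTERCEPT, 0.0))
        planes.append(stored * slope + intercept)
        if not np.allclose(ipp[:2], slices[0][1][:2], atol=1e-3):
            raise GeometryError(f"{dirpath}: slices are not stacked along z")
    volume = np.stack(planes, axis=-1)  # (rows=y, cols=x, z)
    values = np.ascontiguousarray(np.transpose(volume, (1, 0, 2)))  # (x, y, z)
    origin = (slices[0][1][0], slices[0][1][1], slices[0][0])
    return VoxelGrid(values, (col_sp, row_sp, sz), origin, unit="HU")


def read_dicom_dose(path: str) -> VoxelGrid:
    """Read a multi-frame RT Dose file into a Gy grid (grid scaling honored)."""
    ds = read_dicom_file(path)
    if ds.get(MODALITY) != "RTDOSE":
        raise FormatError(f"{path}: modality {ds.get(MODALITY)!r}, expected RTDOSE")
    if DOSE_GRID_SCALING not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling")
    scaling = float(ds[DOSE_GRID_SCALING])
    rows, cols = int(ds[ROWS]), int(ds[COLUMNS])
    nframes = int(ds.get(NUMBER_OF_FRAMES, 1))
    offsets = np.array([float(v) for v in _as_list(ds.get(GRID_FRAME_OFFSETS, [0.0]))])
    if nframes > 1:
        dz = np.diff(offsets)
        if np.ptp(dz) > 1e-3 or np.any(dz <= 0):
            raise GeometryError(f"{path}: non-uniform GridFrameOffsetVector")
        sz = float(dz[0])
    else:
        sz = 1.0
    bits = int(ds[BITS_ALLOCATED])
    dtype = {16: "<u2", 32: "<u4"}.get(bits)
    if dtype is None:
        raise FormatError(f"{path}: unsupported BitsAllocated {bits}")
    stored = np.frombuffer(ds[PIXEL_DATA], dtype=dtype, count=nframes * rows * cols)
    stored = stored.reshape(nframes, rows, cols).astype(np.float64) * scaling
    values = np.ascontiguousarray(np.transpose(stored, (2, 1, 0)))  # (x, y, z)
    ipp = [float(v) for v in _as_list(ds[IMAGE_POSITION])]
    row_sp, col_sp = (float(v) for v in _as_list(ds[PIXEL_SPACING]))
    origin = (ipp[0], ipp[1], ipp[2] + float(offsets[0]))
    return VoxelGrid(values, (col_sp, row_sp, sz), origin, unit="Gy")


def read_dicom_structures(path: str) -> StructureSet:
    """Read an RT Structure Set into named contour lists (mm, closed planar)."""
    ds = read_dicom_file(path)
    if ds.get(MODALITY) != "RTSTRUCT":
        raise FormatError(f"{path}: modality {ds.get(MODALITY)!r}, expected RTSTRUCT")
    names = {}
    for item in ds.get(STRUCTURE_SET_ROI_SEQ, []):
        names[int(item[ROI_NUMBER])] = str(item[ROI_NAME])
    structures: Dict[str, list] = {}
    for item in ds.get(ROI_CONTOUR_SEQ, []):
        number = int(item[REFERENCED_ROI_NUMBER])
        name = names.get(number, f"roi_{number}")
        contours = []
        for citem in item.get(CONTOUR_SEQ, []):
            data = np.asarray(_as_list(citem[CONTOUR_DATA]), dtype=float).reshape(-1, 3)
            contours.append(data)
        structures[name] = contours
    return StructureSet(structures=structures)


# =============================================================================
# Writing
# =============================================================================

def _encode_value(vr: str, value) -> bytes:
    if vr in ("OB", "OW", "OF", "UN"):
        raw = bytes(value)
    elif vr == "US":
        raw = struct.pack(f"<{len(_as_list(value))}H", *_as_list(value))
    elif vr == "UL":
        raw = struct.pack(f"<{len(_as_list(value))}I", *_as_list(value))
    elif vr in ("DS", "IS"):
        parts = []
        for v in _as_list(value):
            if vr == "IS":
                parts.append(str(int(v)))
            else:
                text = f"{float(v):.10G}"
                if len(text) > 16:
                    text = f"{float(v):.8G}"
                parts.append(text)
        raw = "\\".join(parts).encode("ascii")
    else:  # string VRs
        raw = "\\".join(str(v) for v in _as_list(value)).encode("ascii")
    if len(raw) % 2:
        raw += b"\x00" if vr in ("UI", "OB") else b" "
    return raw


def _encode_element(tag: Tag, vr: str, value) -> bytes:
    if vr == "SQ":
        body = b""
        for item in value:
            item_body = _encode_dataset(item)
            body += struct.pack("<HHI", 0xFFFE, 0xE000, len(item_body)) + item_body
        head = struct.pack("<HH", *tag) + b"SQ" + b"\x00\x00" + struct.pack("<I", len(body))
        return head + body
    raw = _encode_value(vr, value)
    if vr in _SHORT_LENGTH_VRS:
        if len(raw) > 0xFFFF:
            raise FormatError(f"value too long for short VR {vr}")
        head = struct.pack("<HH", *tag) + vr.encode("ascii") + struct.pack("<H", len(raw))
    else:
        head = struct.pack("<HH", *tag) + vr.encode("ascii") + b"\x00\x00" + struct.pack("<I", len(raw))
    return head + raw


def _encode_dataset(elements) -> bytes:
    if isinstance(elements, dict):
        elements = sorted(elements.items())
        elements = [(tag, vr_value[0], vr_value[1]) for tag, vr_value in elements]
    return b"".join(_encode_element(tag, vr, value) for tag, vr, value in elements)


def _write_part10(path: str, sop_class: str, sop_instance: str, elements) -> None:
    meta_elements = [
        ((0x0002, 0x0001), "OB", b"\x00\x01"),
        ((0x0002, 0x0002), "UI", sop_class),
        ((0x0002, 0x0003), "UI", sop_instance),
        ((0x0002, 0x0010), "UI", EXPLICIT_VR_LE),
    ]
    meta_body = _encode_dataset(meta_elements)
    meta = _encode_element((0x0002, 0x0000), "UL", len(meta_body)) + meta_body
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(meta)
        fh.write(_encode_dataset(elements))


def write_dicom_ct_series(dirpath: str, ct: VoxelGrid) -> List[str]:
    """Write a HU grid as one int16 CT slice file per z plane."""
    if ct.unit != "HU":
        raise GeometryError(f"expected HU grid, got unit {ct.unit!r}")
    os.makedirs(dirpath, exist_ok=True)
    series_uid = _new_uid()
    nx, ny, nz = ct.shape
    paths = []
    for iz in range(nz):
        plane = np.round(ct.values[:, :, iz]).astype(np.int16)  # HU, slope 1 intercept 0
        stored = np.ascontiguousarray(plane.T)  # (rows=y, cols=x)
        sop_instance = _new_uid()
        elements = [
            (SOP_CLASS_UID, "UI", CT_SOP_CLASS),
            (SOP_INSTANCE_UID, "UI", sop_instance),
            (MODALITY, "CS", "CT"),
            (SLICE_THICKNESS, "DS", ct.spacing[2]),
            (SERIES_INSTANCE_UID, "UI", series_uid),
            (INSTANCE_NUMBER, "IS", iz + 1),
            (IMAGE_POSITION, "DS", [ct.origin[0], ct.origin[1], ct.origin[2] + iz * ct.spacing[2]]),
            (IMAGE_ORIENTATION, "DS", [1, 0, 0, 0, 1, 0]),
            (SAMPLES_PER_PIXEL, "US", 1),
            (PHOTOMETRIC, "CS", "MONOCHROME2"),
            (ROWS, "US", ny),
            (COLUMNS, "US", nx),
            (PIXEL_SPACING, "DS", [ct.spacing[1], ct.spacing[0]]),
            (BITS_ALLOCATED, "US", 16),
            (BITS_STORED, "US", 16),
            (HIGH_BIT, "US", 15),
            (PIXEL_REPRESENTATION, "US", 1),
            (RESCALE_INTERCEPT, "DS", 0.0),
            (RESCALE_SLOPE, "DS", 1.0),
            (PIXEL_DATA, "OW", stored.astype("<i2").tobytes()),
        ]
        path = os.path.join(dirpath, f"ct_{iz:04d}.dcm")
        _write_part10(path, CT_SOP_CLASS, sop_instance, elements)
        paths.append(path)
    return paths


def write_dicom_dose(path: str, dose: VoxelGrid) -> None:
    """Write a Gy grid as a multi-frame uint32 RT Dose with grid scaling."""
    if dose.unit != "Gy":
        raise GeometryError(f"expected Gy grid, got unit {dose.unit!r}")
    nx, ny, nz = dose.shape
    max_dose = float(dose.values.max())
    scaling = max(max_dose, 1e-6) / (2**32 - 1)
    stored = np.round(dose.values / scaling).astype("<u4")
    frames = np.ascontiguousarray(np.transpose(stored, (2, 1, 0)))  # (z, rows=y, cols=x)
    sop_instance = _new_uid()
    elements = [
        (SOP_CLASS_UID, "UI", RTDOSE_SOP_CLASS),
        (SOP_INSTANCE_UID, "UI", sop_instance),
        (MODALITY, "CS", "RTDOSE"),
        (SERIES_INSTANCE_UID, "UI", _new_uid()),
        (IMAGE_POSITION, "DS", list(dose.origin)),
        (IMAGE_ORIENTATION, "DS", [1, 0, 0, 0, 1, 0]),
        (SAMPLES_PER_PIXEL, "US", 1),
        (PHOTOMETRIC, "CS", "MONOCHROME2"),
        (NUMBER_OF_FRAMES, "IS", nz),
        (ROWS, "US", ny),
        (COLUMNS, "US", nx),
        (PIXEL_SPACING, "DS", [dose.spacing[1], dose.spacing[0]]),
        (BITS_ALLOCATED, "US", 32),
        (BITS_STORED, "US", 32),
        (HIGH_BIT, "US", 31),
        (PIXEL_REPRESENTATION, "US", 0),
        (DOSE_UNITS, "CS", "GY"),
        (DOSE_TYPE, "CS", "PHYSICAL"),
        (DOSE_SUMMATION, "CS", "PLAN"),
        (GRID_FRAME_OFFSETS, "DS", [iz * dose.spacing[2] for iz in range(nz)]),
        (DOSE_GRID_SCALING, "DS", scaling),
        (PIXEL_DATA, "OW", frames.tobytes()),
    ]
    _write_part10(path, RTDOSE_SOP_CLASS, sop_instance, elements)


def write_dicom_structures(path: str, structures: StructureSet) -> None:
    """Write named contours as a minimal RT Structure Set."""
    roi_items = []
    contour_items = []
    for number, (name, contours) in enumerate(structures.structures.items(), start=1):
        roi_items.append([
            (ROI_NUMBER, "IS", number),
            (ROI_NAME, "LO", name),
        ])
        citems = []
        for contour in contours:
            open_pts = np.asarray(contour)[:-1]  # DICOM stores implicitly closed contours
            citems.append([
                (CONTOUR_GEOMETRIC_TYPE, "CS", "CLOSED_PLANAR"),
                (NUM_CONTOUR_POINTS, "IS", open_pts.shape[0]),
                (CONTOUR_DATA, "DS", [float(v) for v in open_pts.ravel()]),
            ])
        contour_items.append([
            (CONTOUR_SEQ, "SQ", citems),
            (REFERENCED_ROI_NUMBER, "IS", number),
        ])
    sop_instance = _new_uid()
    elements = [
        (SOP_CLASS_UID, "UI", RTSTRUCT_SOP_CLASS),
        (SOP_INSTANCE_UID, "UI", sop_instance),
        (MODALITY, "CS", "RTSTRUCT"),
        (SERIES_INSTANCE_UID, "UI", _new_uid()),
        (STRUCTURE_SET_ROI_SEQ, "SQ", roi_items),
        (ROI_CONTOUR_SEQ, "SQ", contour_items),
    ]
    _write_part10(path, RTSTRUCT_SOP_CLASS, sop_instance, elements)
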