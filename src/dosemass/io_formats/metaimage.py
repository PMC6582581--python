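"""Self-contained MetaImage (.mha) reader/writer.

Supports single-file uncompressed MetaImage volumes with 1 or 3 components
per voxel (scalar volumes and displacement fields).  The non-standard header
key ``ElementUnit`` carries the semantic unit tag; standard readers ignore it.
"""

from __future__ import annotations

import os
from typing import Tuple

import numpy as np

from ..errors import FormatError, GeometryError
from .types import VoxelGrid

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}

_IDENTITY_3X3 = "1 0 0 0 1 0 0 0 1"


def _read_raw(path: str) -> tuple[dict, bytes]:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise FormatError(f"{path}: truncated MetaImage header")
                if ch == b"\n":
                    break
                line += ch
            text = line.decode("ascii", errors="replace").strip()
            if "=" not in text:
                raise FormatError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
        datafile = header["ElementDataFile"]
        if datafile == "LOCAL":
            raw = fh.read()
        else:
            with open(os.path.join(os.path.dirname(path), datafile), "rb") as dfh:
                raw = dfh.read()
    return header, raw


def read_mha(path: str, unit: str | None = None) -> VoxelGrid:
    """Read an .mha volume (or field) into a :class:`VoxelGrid`.

    For 3-component fields the returned grid has ``values.ndim == 4`` with the
    component axis last; callers wanting a displacement field should use
    :func:`dosemass.registration.read_dvf` instead.
    """
    header, raw = _read_raw(path)
    if header.get("ObjectType", "Image") != "Image":
        raise FormatError(f"{path}: unsupported ObjectType {header.get('ObjectType')!r}")
    ndims = int(header.get("NDims", 3))
    if ndims != 3:
        raise FormatError(f"{path}: only 3-D volumes supported, got NDims={ndims}")
    if header.get("CompressedData", "False").lower() == "true":
        raise FormatError(f"{path}: compressed MetaImage not supported")
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        raise FormatError(f"{path}: big-endian MetaImage not supported")
    tm = header.get("TransformMatrix", _IDENTITY_3X3)
    if not np.allclose([float(v) for v in tm.split()], np.eye(3).ravel()):
        raise GeometryError(f"{path}: oblique TransformMatrix not supported")

    met_type = header.get("ElementType", "MET_DOUBLE")
    if met_type not in _MET_TO_DTYPE:
        raise FormatError(f"{path}: unsupported ElementType {met_type}")
    dtype = np.dtype(_MET_TO_DTYPE[met_type]).newbyteorder("<")
    shape = tuple(int(v) for v in header["DimSize"].split())
    ncomp = int(header.get("ElementNumberOfChannels", 1))
    spacing = tuple(float(v) for v in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())

    count = int(np.prod(shape)) * ncomp
    data = np.frombuffer(raw, dtype=dtype, count=count)
    if data.size != count:
        raise FormatError(f"{path}: expected {count} elements, found {data.size}")
    if ncomp == 1:
        values = data.reshape(shape, order="F")
    else:
        # components interleaved fastest, then x fastest
        values = data.reshape((ncomp,) + shape, order="F")
        values = np.moveaxis(values, 0, -1)
    file_unit = header.get("ElementUnit")
    resolved_unit = unit or file_unit or "1"
    values = np.ascontiguousarray(values)
    if values.ndim == 4:  # multi-component field: bypass scalar-grid validation
        grid = VoxelGrid.__new__(VoxelGrid)
        grid.values, grid.spacing, grid.origin, grid.unit = values, spacing, origin, resolved_unit
        return grid
    return VoxelGrid(values, spacing, origin, resolved_unit)


def write_mha(path: str, grid: VoxelGrid) -> None:
    """Write a grid (scalar or trailing-component 4-D) as uncompressed .mha."""
    values = np.asarray(grid.values)
    if values.ndim == 4:
        ncomp = values.shape[-1]
        shape = values.shape[:3]
        flat = np.moveaxis(values, -1, 0).ravel(order="F")
    elif values.ndim == 3:
        ncomp = 1
        shape = values.shape
        flat = values.ravel(order="F")
    else:
        raise FormatError(f"cannot write array of ndim {values.ndim}")
    native = values.dtype if values.dtype in _DTYPE_TO_MET else np.dtype(np.float64)
    dtype = native.newbyteorder("<")
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        f"TransformMatrix = {_IDENTITY_3X3}",
        "Offset = " + " ".join(repr(v) for v in grid.origin),
        "CenterOfRotation = 0 0 0",
        "AnatomicalOrientation = LPS",
        "ElementSpacing = " + " ".join(repr(v) for v in grid.spacing),
        f"DimSize = {shape[0]} {shape[1]} {shape[2]}",
        f"ElementNumberOfChannels = {ncomp}",
        f"ElementType = {_DTYPE_TO_MET[native]}",
        f"ElementUnit = {grid.unit}",
        "ElementDataFile = LOCAL",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n").encode("ascii"))
        fh.write(flat.astype(dtype, copy=False).tobytes())


def geometry_from_header(path: str) -> Tuple[tuple, tuple, tuple]:
    """Convenience: (shape, spacing, origin) without loading voxel data."""
    header, _ = _read_raw(path)
    shape = tuple(int(v) for v in header["DimSize"].split())
    spacing = tuple(float(v) for v in header.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
    return shape, spacing, origin
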