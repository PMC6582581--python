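"""Format-dispatching readers for volumes, dose grids and structure sets."""

from __future__ import annotations

import os

from ..errors import FormatError
from .types import StructureSet, VoxelGrid
from . import dicom as dicom_adapter
from .metaimage import read_mha, write_mha
from .structures import read_structures_json


def read_volume(path: str, format_hint: str | None = None, unit: str | None = None) -> VoxelGrid:
    """Read a scalar volume from a MetaImage file or a DICOM CT series dir.

    ``format_hint`` may be ``"mha"`` or ``"dicom"``; otherwise it is inferred
    from the path (directory -> DICOM series, ``.mha`` -> MetaImage).
    """
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file or directory")
    fmt = format_hint
    if fmt is None:
        if os.path.isdir(path):
            fmt = "dicom"
        elif path.lower().endswith(".mha"):
            fmt = "mha"
    if fmt == "dicom":
        return dicom_adapter.read_dicom_ct_series(path)
    if fmt == "mha":
        return read_mha(path, unit=unit)
    raise FormatError(f"{path}: unsupported volume format (hint={format_hint!r})")


def write_volume(path: str, grid: VoxelGrid) -> None:
    """Write a volume; ``.mha`` files or a directory of DICOM CT slices."""
    if path.lower().endswith(".mha"):
        write_mha(path, grid)
    elif grid.unit == "HU":
        dicom_adapter.write_dicom_ct_series(path, grid)
    else:
        raise FormatError(f"{path}: cannot infer output format")


def read_dose(path: str) -> VoxelGrid:
    """Read a dose grid in Gy from RT Dose or a Gy-tagged MetaImage volume."""
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file")
    if path.lower().endswith(".mha"):
        grid = read_mha(path)
        if grid.unit != "Gy":
            raise FormatError(f"{path}: volume is not tagged as Gy (unit={grid.unit!r})")
        return grid
    return dicom_adapter.read_dicom_dose(path)


def read_structures(path: str) -> StructureSet:
    """Read a structure set from research JSON or DICOM RT Structure Set."""
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file")
    if path.lower().endswith(".json"):
        return read_structures_json(path)
    return dicom_adapter.read_dicom_structures(path)
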