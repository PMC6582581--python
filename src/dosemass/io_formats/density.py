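"""HU -> mass density conversion: table I/O and voxelwise application."""

from __future__ import annotations

import csv

import numpy as np

from ..errors import FormatError, GeometryError
from .types import DensityTable, VoxelGrid

#: Default calibration breakpoints (air / lung / water / soft tissue / bone).
#: Densities are strictly increasing so the table is invertible, which the
#: synthetic phantoms rely on to derive HU from construction densities.
DEFAULT_BREAKPOINTS = (
    (-1000.0, 0.00121),
    (-800.0, 0.20),
    (-500.0, 0.50),
    (0.0, 1.00),
    (60.0, 1.06),
    (1000.0, 1.60),
    (3000.0, 2.80),
)


def default_density_table() -> DensityTable:
    hu, density = zip(*DEFAULT_BREAKPOINTS)
    return DensityTable(np.array(hu), np.array(density))


def read_density_csv(path: str) -> DensityTable:
    """Read a 2-column CSV with required header ``hu,density_g_cm3``."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty density table") from None
        cols = [c.strip().lower() for c in header]
        if cols[:2] != ["hu", "density_g_cm3"]:
            raise FormatError(f"{path}: expected header 'hu,density_g_cm3', got {header}")
        rows = [(float(r[0]), float(r[1])) for r in reader if r]
    if len(rows) < 2:
        raise FormatError(f"{path}: need >=2 breakpoints")
    hu, density = zip(*rows)
    return DensityTable(np.array(hu), np.array(density))


def write_density_csv(path: str, table: DensityTable) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["hu", "density_g_cm3"])
        for h, d in zip(table.hu, table.density):
            writer.writerow([repr(float(h)), repr(float(d))])


def hu_to_density(ct: VoxelGrid, table: DensityTable | None = None) -> VoxelGrid:
    """Map a HU volume to mass density (g/cm^3) by piecewise-linear lookup.

    Values outside the table range are clamped to the end densities.
    """
    if ct.unit != "HU":
        raise GeometryError(f"expected a HU grid, got unit {ct.unit!r}")
    table = table or default_density_table()
    return ct.with_values(table.lookup(ct.values), unit="g/cm3")
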