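"""JSON contour file reader/writer.

File layout::

    {
      "structures": {
        "left_lung": [ [[x, y, z], ...contour 1...], [[x, y, z], ...], ... ],
        "heart": [ ... ]
      }
    }

Coordinates are patient mm (LPS); each contour is planar (constant z).
"""

from __future__ import annotations

import json

import numpy as np

from ..errors import FormatError
from .types import StructureSet


def read_structures_json(path: str) -> StructureSet:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "structures" not in payload:
        raise FormatError(f"{path}: missing top-level 'structures' object")
    return StructureSet(structures=payload["structures"])


def write_structures_json(path: str, structures: StructureSet) -> None:
    payload = {
        "structures": {
            name: [np.asarray(c).tolist() for c in contours]
            for name, contours in structures.structures.items()
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
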