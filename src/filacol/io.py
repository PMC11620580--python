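"""Serialisation: colonies to CSV/JSON, masks to 1-bit PNG/TIFF."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .morphometry import BinaryImage
from .simulate import Colony, SimParams

__all__ = [
    "colony_to_frame",
    "save_colony",
    "load_colony_frame",
    "save_mask",
    "load_mask",
]


def colony_to_frame(colony: Colony) -> pd.DataFrame:
    """One row per cell: id, x, y, theta, type, mother_id."""
    return pd.DataFrame(
        {
            "id": [c.id for c in colony.cells],
            "x": [c.centre[0] for c in colony.cells],
            "y": [c.centre[1] for c in colony.cells],
            "theta": [c.orientation for c in colony.cells],
            "type": [c.type_params.label for c in colony.cells],
            "mother_id": [
                -1 if c.mother_id is None else c.mother_id for c in colony.cells
            ],
        }
    )


def _params_dict(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    d["domain"] = list(d["domain"])
    return d


def save_colony(colony: Colony, csv_path, params_path=None) -> None:
    """Write the cell table as CSV and (optionally) the parameters as JSON."""
    colony_to_frame(colony).to_csv(csv_path, index=False)
    if params_path is not None:
        Path(params_path).write_text(
            json.dumps(_params_dict(colony.params), indent=2) + "\n"
        )


def load_colony_frame(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def save_mask(img: BinaryImage, path) -> None:
    """Write a mask as a 1-bit image (colony black on white background)."""
    arr = np.where(img.pixels, 0, 255).astype(np.uint8)
    Image.fromarray(arr).convert("1").save(path)


def load_mask(path, px_size: float = 1.0) -> BinaryImage:
    """Read a mask image; dark pixels are occupied."""
    arr = np.asarray(Image.open(path).convert("L"))
    if arr.min() == arr.max():
        raise ValueError(f"constant image {path!r} cannot be a mask")
    thr = (int(arr.min()) + int(arr.max())) / 2.0
    return BinaryImage(arr <= thr, px_size=px_size)
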