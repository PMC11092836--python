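"""File IO: configs, cell tables, masks, velocity fields, movies."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .epithelium import CellMap, EpitheliumSpec
from .hydrodynamics import VelocityField
from .pattern_metrics import CiliationMask

__all__ = [
    "load_spec",
    "save_spec",
    "cellmap_to_table",
    "save_mask",
    "load_mask",
    "save_velocity_field",
    "load_velocity_field",
    "load_movie",
]


def load_spec(path) -> EpitheliumSpec:
    """Read an EpitheliumSpec from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return EpitheliumSpec(**data)


def save_spec(spec: EpitheliumSpec, path) -> None:
    path = Path(path)
    data = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def cellmap_to_table(cells: CellMap) -> pd.DataFrame:
    """Delimited-table view of a cell map (one row per cell)."""
    n = cells.centers.shape[0]
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x_um": cells.centers[:, 0],
            "y_um": cells.centers[:, 1],
            "ciliated": cells.ciliated if cells.ciliated is not None else np.zeros(n, bool),
            "theta_rad": cells.beat_angle if cells.beat_angle is not None else np.full(n, np.nan),
            "amplitude_um": cells.amplitude if cells.amplitude is not None else np.full(n, np.nan),
        }
    )


def save_mask(mask: CiliationMask, path) -> None:
    """Single-channel TIFF plus sidecar JSON with the pixel size."""
    path = Path(path)
    tifffile.imwrite(path, mask.image)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": mask.pixel_size, "fov_id": mask.fov_id}))


def load_mask(path, pixel_size: float | None = None) -> CiliationMask:
    path = Path(path)
    img = np.asarray(tifffile.imread(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    fov_id = ""
    if pixel_size is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = meta["pixel_size_um"]
        fov_id = meta.get("fov_id", "")
    if pixel_size is None:
        raise ValueError("pixel size not given and no sidecar found")
    return CiliationMask(image=(img > 0).astype(np.uint8), pixel_size=pixel_size, fov_id=fov_id)


def save_velocity_field(field: VelocityField, path) -> None:
    """Two-band TIFF (u, v) plus sidecar JSON with grid metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.stack([field.u, field.v]).astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "grid_spacing_um": field.grid_spacing,
                "extent_um": list(field.extent),
                "height_um": field.height,
                "units": "um_per_beat",
            }
        )
    )


def load_velocity_field(path) -> VelocityField:
    path = Path(path)
    bands = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return VelocityField(
        u=bands[0],
        v=bands[1],
        grid_spacing=meta["grid_spacing_um"],
        extent=tuple(meta["extent_um"]),
        height=meta["height_um"],
    )


def load_movie(path) -> np.ndarray:
    """Multi-frame TIFF as (frames, height, width)."""
    movie = np.asarray(tifffile.imread(path))
    if movie.ndim != 3:
        raise ValueError("expected a multi-frame single-channel TIFF")
    return movie
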