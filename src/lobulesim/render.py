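"""Snapshot rendering and run-artefact input/output.

Snapshots use the histology-inspired colour scheme: hepatocytes brown,
dead cells grey, myofibroblast-derived collagen blue, portal-fibroblast-
derived collagen green, with the vascular landmarks in dark red (portal)
and dark violet (central vein).  Rendering is a pure function of the grid
and style; the ``hide_hepatocytes`` flag blanks the parenchyma so the scar
pattern stands out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from . import lattice
from .config import SimulationConfig

DEFAULT_COLORS: dict[int, tuple[int, int, int]] = {
    lattice.EMPTY: (255, 255, 255),          # blank: white
    lattice.HEPATOCYTE: (165, 105, 60),      # brown
    lattice.DEAD_NECROTIC: (128, 128, 128),  # grey
    lattice.DEAD_APOPTOTIC: (128, 128, 128),
    lattice.COLLAGEN_MFB: (40, 80, 220),     # blue
    lattice.COLLAGEN_PF: (40, 170, 60),      # green
    lattice.PORTAL: (140, 20, 20),           # dark red
    lattice.VEIN: (90, 30, 120),             # dark violet
    lattice.SEPTA: (60, 60, 60),
}


@dataclass
class SnapshotStyle:
    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    scale: int = 4
    hide_hepatocytes: bool = False


def render_snapshot(grid_or_occupancy, style: SnapshotStyle | None = None) -> Image.Image:
    """Render an occupancy layer (or a grid) to a PIL image, one
    ``scale`` x ``scale`` pixel block per lattice site, row 0 at the top."""
    style = style or SnapshotStyle()
    occ = getattr(grid_or_occupancy, "occupancy", grid_or_occupancy)
    occ = np.asarray(occ)
    colors = dict(style.colors)
    if style.hide_hepatocytes:
        colors[lattice.HEPATOCYTE] = colors[lattice.EMPTY]
    lut = np.zeros((max(colors) + 1, 3), dtype=np.uint8)
    for code, rgb in colors.items():
        lut[code] = rgb
    rgb = lut[occ]
    if style.scale != 1:
        rgb = np.repeat(np.repeat(rgb, style.scale, axis=0), style.scale, axis=1)
    return Image.fromarray(rgb, mode="RGB")


# ---------------------------------------------------------------------------
# Run artefacts
# ---------------------------------------------------------------------------

def write_timecourse(tc: pd.DataFrame, path) -> None:
    tc.to_csv(path, index=False)


def read_timecourse(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed time-course file {path}: {err}") from err


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_from_manifest(manifest: dict) -> SimulationConfig:
    return SimulationConfig.from_dict(manifest["config"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
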