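"""MRC volume and STAR metadata I/O.

Volumes are MRC2014 mode-2 (float32); in memory they are numpy arrays indexed
``(z, y, x)`` with X fastest on disk, as MRC prescribes.  Project metadata
lives in RELION-style STAR files (one ``data_``/``loop_`` block per file) with
``_iso``-prefixed column names, so the files open in any STAR-aware tool.

Both formats are handled through :mod:`gemmi`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Tomogram",
    "read_mrc",
    "write_mrc",
    "read_star",
    "write_star",
    "prepare_star",
    "TOMOGRAM_COLUMNS",
]

#: default columns of a tomogram table (values stored as strings in STAR)
TOMOGRAM_COLUMNS = [
    "TomoName",
    "PixelSize",
    "Defocus",
    "NumberSubtomo",
    "MaskName",
    "DeconvName",
]


@dataclass
class Tomogram:
    """A 3D voxel grid with physical pixel size.

    data : float array indexed (z, y, x)
    pixel_size : Angstrom per voxel
    origin : voxel offset triple (z, y, x), informational
    name : source identifier (usually the file stem)
    """

    data: np.ndarray
    pixel_size: float = 1.0
    origin: tuple = (0, 0, 0)
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"tomogram must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not np.isfinite(self.data).all():
            raise ValueError("tomogram contains non-finite voxels")

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray, suffix: str = "") -> "Tomogram":
        return Tomogram(data, self.pixel_size, self.origin, self.name + suffix)


def read_mrc(path) -> Tomogram:
    """Read an MRC2014 volume; pixel size is taken from the cell/grid header."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"malformed MRC file {path}: {e}") from e
    arr = np.array(m.grid, copy=True)  # gemmi axes are (x, y, z)
    if arr.ndim != 3 or min(arr.shape) < 2:
        raise ValueError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    # per-axis spacing; voxels are taken as cubic, X spacing is authoritative
    ps = float(m.grid.spacing[0])
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    return Tomogram(data, pixel_size=ps, name=path.stem)


def write_mrc(vol: Tomogram, path, overwrite: bool = True) -> None:
    """Write a volume as MRC2014 mode 2 (float32) with the pixel size header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    if not np.isfinite(vol.data).all():
        raise ValueError("refusing to write non-finite voxel values")
    nz, ny, nx = vol.data.shape
    m = gemmi.Ccp4Map()
    arr_xyz = np.asfortranarray(vol.data.transpose(2, 1, 0).astype(np.float32))
    m.grid = gemmi.FloatGrid(arr_xyz)
    ps = float(vol.pixel_size)
    m.grid.unit_cell = gemmi.UnitCell(nx * ps, ny * ps, nz * ps, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_star(table: pd.DataFrame, path, block: str = "tomograms") -> None:
    """Write a DataFrame as a single-block RELION-style STAR loop."""
    doc = gemmi.cif.Document()
    b = doc.add_new_block(block)
    loop = b.init_loop("_iso", [str(c) for c in table.columns])
    for _, row in table.iterrows():
        loop.add_row([_quote(v) for v in row])
    doc.write_file(str(path))


def _quote(v) -> str:
    s = str(v)
    if s == "" or any(ch.isspace() for ch in s):
        return gemmi.cif.quote(s if s else " ")
    return s


def read_star(path) -> pd.DataFrame:
    """Read the sole loop block of a STAR file into a DataFrame (string cells)."""
    doc = gemmi.cif.read_file(str(path))
    b = doc.sole_block()
    cols = {}
    for item in b:
        if item.loop is not None:
            loop = item.loop
            width = loop.width()
            vals = list(loop.values)
            for j, tag in enumerate(loop.tags):
                name = tag.split("_iso", 1)[1] if tag.startswith("_iso") else tag.lstrip("_")
                cols[name] = [gemmi.cif.as_string(v) for v in vals[j::width]]
            break
    return pd.DataFrame(cols)


def prepare_star(folder, pixel_size: float | None = None,
                 number_subtomo: int = 100) -> pd.DataFrame:
    """Build a tomogram table from a folder of MRC files.

    One row per ``.mrc``/``.rec``/``.map`` file; the pixel size is read from
    each header unless overridden.  A header pixel size of zero (unset) with
    no override is an error rather than a silent 1 A assumption.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"{folder} is not a directory")
    rows = []
    for p in sorted(folder.iterdir()):
        if p.suffix.lower() not in (".mrc", ".rec", ".map"):
            continue
        if pixel_size is not None:
            ps = pixel_size
        else:
            ps = float(gemmi.read_ccp4_map(str(p)).grid.spacing[0])
            if not ps > 0:
                raise ValueError(
                    f"{p}: pixel size not set in header; pass pixel_size explicitly"
                )
        rows.append({
            "TomoName": str(p),
            "PixelSize": f"{ps:g}",
            "Defocus": "0.0",
            "NumberSubtomo": str(number_subtomo),
            "MaskName": "None",
            "DeconvName": "None",
        })
    if not rows:
        warnings.warn(f"no MRC-like files found in {folder}; empty table")
        return pd.DataFrame(columns=TOMOGRAM_COLUMNS)
    return pd.DataFrame(rows, columns=TOMOGRAM_COLUMNS)
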