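"""File formats: MRC micrographs, STAR coordinate tables, YAML configs.

Conventions used across the package (and documented here once):

* Images are 2D ``float32`` arrays indexed ``[y, x]`` (row-major, first
  axis is y / the MRC slow axis).
* Particle coordinates are ``(x, y)`` pixel positions of particle
  CENTERS, 0-based floats.
* STAR coordinate loops carry ``rlnMicrographName``, ``rlnCoordinateX``,
  ``rlnCoordinateY`` and optionally a nonstandard ``maepickScore``
  column that standard STAR consumers will ignore.  Coordinates are
  written 0-based; some cryo-EM tools expect 1-based integers, so shift
  on import if needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("maepick")

COORD_COLUMNS = ("rlnMicrographName", "rlnCoordinateX", "rlnCoordinateY")
SCORE_COLUMN = "maepickScore"  # nonstandard on purpose


@dataclass
class Micrograph:
    """A single 2D grayscale micrograph."""

    image: np.ndarray  # (H, W) float32, [y, x]
    micrograph_id: str = "micrograph"
    pixel_size: float | None = None  # Angstrom / pixel, if known

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError(f"micrograph image must be 2D, got shape {self.image.shape}")

    @property
    def shape(self) -> tuple:
        return self.image.shape


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_micrograph(path: str | Path) -> Micrograph:
    """Read a 2D micrograph from an MRC file (modes 0/1/2/6) or, for
    convenience in tests and demos, from a plain image file.

    Raises ``ValueError`` for genuine 3D volumes/stacks.
    """
    path = Path(path)
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=np.float32)
        if img.ndim == 3:  # collapse RGB(A)
            img = img[..., :3].mean(axis=-1)
        return Micrograph(img, micrograph_id=path.stem)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse MRC file {path}: {exc}") from None
    arr = np.array(ccp4.grid, copy=False)  # axes (nx, ny, nz)
    arr = arr.transpose(2, 1, 0)  # -> (nz, ny, nx)
    if arr.shape[0] != 1:
        raise ValueError(
            f"{path} holds a 3D volume/stack of shape (z,y,x)={arr.shape}; "
            "only single 2D micrographs are supported"
        )
    img = np.ascontiguousarray(arr[0], dtype=np.float32)
    nx = ccp4.grid.nu
    cell_a = ccp4.grid.unit_cell.a
    pixel_size = float(cell_a / nx) if cell_a > 0 else None
    if pixel_size == 1.0:
        pixel_size = None  # our writer's placeholder cell
    return Micrograph(img, micrograph_id=path.stem, pixel_size=pixel_size)


def write_micrograph(mic: Micrograph, path: str | Path) -> Path:
    """Write a 2D micrograph as a mode-2 (float32) MRC file."""
    path = Path(path)
    img = np.asarray(mic.image, dtype=np.float32)
    h, w = img.shape
    grid_arr = np.ascontiguousarray(img.T)[:, :, None]  # (nx, ny, nz=1)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(grid_arr)
    apix = mic.pixel_size if mic.pixel_size else 1.0
    ccp4.grid.unit_cell = gemmi.UnitCell(w * apix, h * apix, apix, 90.0, 90.0, 90.0)
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
    return path


# ---------------------------------------------------------------------------
# STAR
# ---------------------------------------------------------------------------


@dataclass
class StarTable:
    """One ``data_`` block with one ``loop_`` of typed columns."""

    name: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.table)


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return df


def read_star(path: str | Path, block: str | None = None) -> StarTable:
    """Read a STAR file's loop into a typed DataFrame.

    Comments and blank lines are tolerated; unknown columns are kept.
    """
    path = Path(path)
    doc = gemmi.cif.read_file(str(path))
    if block is None:
        blk = doc[0] if len(doc) else None
    else:
        blk = doc.find_block(block)
    if blk is None:
        raise ValueError(f"no data_ block {block or ''!r} found in {path}")
    prefix = None
    for item in blk:
        if item.loop is not None:
            loop = item.loop
            tags = [t.lstrip("_") for t in loop.tags]
            ncol = loop.width()
            vals = [gemmi.cif.as_string(v) for v in loop.values]
            rows = [vals[i * ncol : (i + 1) * ncol] for i in range(loop.length())]
            df = pd.DataFrame(rows, columns=tags)
            return StarTable(blk.name, _coerce_numeric(df))
    raise ValueError(f"no loop_ found in {path} (block {blk.name!r})")


def write_star(star: StarTable, path: str | Path) -> Path:
    """Write a StarTable as a single data_ block with one loop_."""
    path = Path(path)
    doc = gemmi.cif.Document()
    blk = doc.add_new_block(star.name or "particles")
    df = star.table
    loop = blk.init_loop("_", [str(c) for c in df.columns])
    for _, row in df.iterrows():
        loop.add_row([_star_str(v) for v in row])
    doc.write_file(str(path))
    return path


def _star_str(v) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".6f")
    s = str(v)
    return s if s and " " not in s else f'"{s}"'


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read particle coordinates from a STAR (or CSV) file.

    Returns a DataFrame with at least ``rlnCoordinateX``/``rlnCoordinateY``;
    raises a schema error listing the columns found when they are absent.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
    else:
        df = read_star(path).table
    missing = [c for c in ("rlnCoordinateX", "rlnCoordinateY") if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path} lacks coordinate column(s) {missing}; found {list(df.columns)}"
        )
    return df


def write_coordinates(
    path: str | Path,
    centers: np.ndarray,
    micrograph_name: str,
    scores: np.ndarray | None = None,
    block_name: str = "particles",
) -> Path:
    """Write (x, y) particle centers (and optional scores) to a STAR file."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        centers = centers.reshape(0, 2)
    data = {
        "rlnMicrographName": [micrograph_name] * len(centers),
        "rlnCoordinateX": centers[:, 0],
        "rlnCoordinateY": centers[:, 1],
    }
    if scores is not None:
        data[SCORE_COLUMN] = np.asarray(scores, dtype=float)
    return write_star(StarTable(block_name, pd.DataFrame(data)), path)
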