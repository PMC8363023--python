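"""Raster I/O: 8-bit RGB orthophotos and {0,255} single-band trail masks.

Supported formats are PNG and (Geo)TIFF. Georeferencing travels as an
ESRI world file next to the raster (``.pgw``/``.tfw``): six lines holding
the affine transform (x-scale, y-skew, x-skew, y-scale, then the world
coordinates of the centre of the top-left pixel). The transform is passed
through untouched by every processing stage.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .core import Orthophoto, as_bool_mask, mask_to_uint8

_WORLD_EXT = {".png": ".pgw", ".tif": ".tfw", ".tiff": ".tfw"}


class UnsupportedRasterFormat(ValueError):
    """The file extension is not a supported raster format."""


class CorruptRasterError(IOError):
    """The file exists but cannot be decoded as a raster."""


def _world_path(path: Path) -> Path:
    return path.with_suffix(_WORLD_EXT[path.suffix.lower()])


def write_world_file(path: Path, transform: tuple[float, ...]) -> None:
    if len(transform) != 6:
        raise ValueError("world transform must have 6 elements")
    _world_path(path).write_text("".join(f"{v:.10f}\n" for v in transform))


def read_world_file(path: Path) -> tuple[float, ...] | None:
    wp = _world_path(path)
    if not wp.exists():
        return None
    values = [float(line) for line in wp.read_text().split()]
    if len(values) != 6:
        raise CorruptRasterError(f"world file {wp} does not hold 6 numbers")
    return tuple(values)


def write_raster(path: str | Path, array: np.ndarray,
                 transform: tuple[float, ...] | None = None) -> None:
    """Write an RGB or single-band uint8 raster (+ optional world file)."""
    path = Path(path)
    if path.suffix.lower() not in _WORLD_EXT:
        raise UnsupportedRasterFormat(f"unsupported raster extension: {path.suffix}")
    array = np.asarray(array, dtype=np.uint8)
    if path.suffix.lower() == ".png":
        Image.fromarray(array).save(path)
    else:
        tifffile.imwrite(path, array)
    if transform is not None:
        write_world_file(path, transform)


def read_raster(path: str | Path) -> tuple[np.ndarray, tuple[float, ...] | None]:
    """Read a raster and its world transform (if a world file is present)."""
    path = Path(path)
    if path.suffix.lower() not in _WORLD_EXT:
        raise UnsupportedRasterFormat(f"unsupported raster extension: {path.suffix}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() == ".png":
            array = np.asarray(Image.open(path))
        else:
            array = tifffile.imread(path)
    except (UnidentifiedImageError, tifffile.TiffFileError, ValueError) as exc:
        raise CorruptRasterError(f"cannot decode {path}: {exc}") from exc
    return array, read_world_file(path)


def write_orthophoto(path: str | Path, photo: Orthophoto) -> None:
    write_raster(path, photo.pixels, photo.transform)


def read_orthophoto(path: str | Path, resolution_cm_per_px: float,
                    date: str | None = None) -> Orthophoto:
    array, transform = read_raster(path)
    if array.ndim != 3 or array.shape[2] < 3:
        raise CorruptRasterError(f"{path} is not an RGB raster")
    return Orthophoto(array[..., :3], resolution_cm_per_px, date=date,
                      transform=transform)


def write_mask(path: str | Path, mask: np.ndarray,
               transform: tuple[float, ...] | None = None) -> None:
    """Store a boolean mask as a {0, 255} single-band raster."""
    write_raster(path, mask_to_uint8(mask), transform)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} single-band mask raster; other values are rejected."""
    array, _ = read_raster(path)
    if array.ndim != 2:
        raise CorruptRasterError(f"{path} is not single-band")
    vals = np.unique(array)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask raster {path} holds values other than 0/255: "
                         f"{vals[:10]}")
    return as_bool_mask(array)
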