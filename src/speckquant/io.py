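"""Micrograph input/output.

Reads paired nuclear-stain (e.g. DAPI) and ASC-immunostain channels from
grayscale TIFF or PNG files, normalises intensities to [0, 1] for
depth-independent thresholding, and exports 8-bit PNG copies of each
channel (the batch equivalent of an acquisition-software file converter).

Coordinate convention: 0-based (row, col); array shape is (rows, cols),
so a camera frame advertised as 1392 x 1040 (width x height) loads with
shape (1040, 1392).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: A channel source: a single-channel image file, or (path, page) into a
#: multi-page TIFF. Page order is never guessed.
ChannelSource = Union[str, Path, tuple]

MANIFEST_COLUMNS = ["sample_id", "condition", "field_id", "nuclear_path", "asc_path"]


class ShapeMismatchError(ValueError):
    """Nuclear and ASC rasters do not have identical dimensions."""


class ChannelAmbiguityError(ValueError):
    """An input image has a colour/channel axis; a grayscale raster is required."""


@dataclass(frozen=True)
class ChannelConfig:
    """Where to find the two channels of one field."""

    nuclear_source: ChannelSource
    asc_source: ChannelSource


@dataclass
class ImageField:
    """One two-channel micrograph: the unit of detection.

    Attributes
    ----------
    field_id : str
        Identifier for this field of view.
    nuclear, asc : ndarray
        2-D intensity rasters in native integer units.
    bit_depth : int
        8 or 16, inferred from the file dtype.
    pixel_size_um : float
        Microns per pixel (default 0.5, a 20x/0.5 NA widefield setup).
    """

    field_id: str
    nuclear: np.ndarray
    asc: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear)
        self.asc = np.asarray(self.asc)
        if self.nuclear.shape != self.asc.shape:
            raise ShapeMismatchError(
                f"nuclear shape {self.nuclear.shape} != asc shape {self.asc.shape}"
            )
        if self.nuclear.ndim != 2:
            raise ChannelAmbiguityError(
                f"expected 2-D rasters, got {self.nuclear.ndim}-D"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lim = 2**self.bit_depth - 1
        for name, arr in (("nuclear", self.nuclear), ("asc", self.asc)):
            if arr.size and (arr.min() < 0 or arr.max() > lim):
                raise ValueError(
                    f"{name} intensities outside [0, {lim}] for declared "
                    f"{self.bit_depth}-bit depth"
                )

    @property
    def shape(self) -> tuple:
        return self.nuclear.shape


def _read_channel(source: ChannelSource) -> np.ndarray:
    """Read one grayscale raster from a file or a (path, page) pair."""
    if isinstance(source, tuple):
        path, page = source
        arr = tifffile.imread(str(path), key=int(page))
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ChannelAmbiguityError(
            f"{source}: image has shape {arr.shape}; colour/multi-channel input "
            "is ambiguous — supply single-channel grayscale files or an explicit "
            "(path, page) source for multi-page TIFFs"
        )
    if arr.ndim != 2:
        raise ChannelAmbiguityError(f"{source}: expected a 2-D raster, got {arr.ndim}-D")
    return arr


def _infer_bit_depth(*arrays: np.ndarray) -> int:
    for arr in arrays:
        if arr.dtype.itemsize > 1:
            return 16
    return 8


def load_field(
    config: ChannelConfig,
    field_id: str = "",
    pixel_size_um: float = 0.5,
) -> ImageField:
    """Load one two-channel field.

    Bit depth is inferred from dtype (uint8 -> 8, wider -> 16); intensities
    are kept in native units with no rescaling.
    """
    nuclear = _read_channel(config.nuclear_source)
    asc = _read_channel(config.asc_source)
    if nuclear.shape != asc.shape:
        raise ShapeMismatchError(
            f"nuclear {config.nuclear_source} shape {nuclear.shape} != "
            f"asc {config.asc_source} shape {asc.shape}"
        )
    if not field_id:
        src = config.nuclear_source
        field_id = Path(src[0] if isinstance(src, tuple) else src).stem
    return ImageField(
        field_id=field_id,
        nuclear=nuclear,
        asc=asc,
        bit_depth=_infer_bit_depth(nuclear, asc),
        pixel_size_um=pixel_size_um,
    )


def normalize_channel(raster: np.ndarray, bit_depth: int) -> np.ndarray:
    """Scale an integer raster to [0, 1] by its declared bit depth.

    Division is by ``2**bit_depth - 1`` so relative thresholds mean the
    same thing on 8- and 16-bit input. Negative values (should not occur
    in real data) are clipped to 0 with a warning.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.size and raster.min() < 0:
        warnings.warn("negative intensities clipped to 0", stacklevel=2)
        raster = np.clip(raster, 0, None)
    return raster / (2**bit_depth - 1)


def export_png(field: ImageField, out_dir: Union[str, Path]) -> tuple:
    """Write each channel as an 8-bit PNG; returns (nuclear_path, asc_path).

    Intensities are linearly rescaled from [0, 2**bit_depth - 1] to
    [0, 255] and rounded half-up, so an 8-bit field round-trips losslessly.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"output directory does not exist: {out_dir}")
    lim = 2**field.bit_depth - 1
    paths = []
    for suffix, arr in (("nuclear", field.nuclear), ("asc", field.asc)):
        scaled = np.floor(arr.astype(np.float64) * 255.0 / lim + 0.5)
        out = out_dir / f"{field.field_id}_{suffix}.png"
        iio.imwrite(out, np.clip(scaled, 0, 255).astype(np.uint8))
        paths.append(out)
    return tuple(paths)


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sample manifest CSV.

    Required columns: sample_id, condition (unstimulated|stimulated),
    field_id, nuclear_path, asc_path. Five replicate fields per
    sample/condition is the assay's nominal design.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    if df.empty:
        raise ValueError(f"manifest {path} has no rows")
    bad = set(df["condition"]) - {"unstimulated", "stimulated"}
    if bad:
        raise ValueError(f"manifest {path}: unknown conditions {sorted(bad)}")
    return df
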