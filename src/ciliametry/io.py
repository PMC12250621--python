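"""Image and table I/O, configuration, and record types.

Images are 2D single-channel intensity rasters (8- or 16-bit scale) with a
required micrometers-per-pixel calibration and a hemisphere label.  RGB
inputs are collapsed to grayscale by Rec. 601 luminance.  Tabular outputs
are plain UTF-8 CSV with '.' decimals.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

logger = logging.getLogger("ciliametry")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

HEMISPHERES = ("left", "right")
CHANNELS = ("ADCY3", "DAPI", "other")

#: Rec. 601 luminance weights used to collapse RGB to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

CILIA_CSV_COLUMNS = [
    "id", "section_id", "region_label", "hemisphere", "zt",
    "length_um", "width_um", "angle_deg",
    "base_x", "base_y", "centroid_x", "centroid_y",
]

CELL_CSV_COLUMNS = ["id", "centroid_x", "centroid_y", "area_px2", "circularity"]


@dataclass(frozen=True)
class Image2D:
    """A calibrated single-channel 2D intensity image."""

    pixels: np.ndarray
    pixel_size_um: float
    hemisphere: str = "right"
    channel: str = "other"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class CiliumRecord:
    """One detected cilium.

    ``angle_deg`` is the base-to-tip orientation in degrees, measured in the
    hemisphere-adjusted circular convention (0 = image right, counter-
    clockwise for the right hemisphere, mirrored for the left), in [0, 360).
    Coordinates are pixel (x, y) with x = column, y = row.
    """

    id: int
    length_um: float
    width_um: float
    angle_deg: float
    base_xy: tuple[float, float]
    centroid_xy: tuple[float, float]
    section_id: str = ""
    region_label: str = ""
    hemisphere: str = "right"
    zt: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg < 360.0:
            raise ValueError(f"angle_deg must lie in [0, 360), got {self.angle_deg}")
        if self.length_um < 0 or self.width_um < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class CellRecord:
    """One detected (DAPI) cell after hull merging and filtering."""

    id: int
    hull: np.ndarray          # (k, 2) convex hull vertices, (x, y)
    centroid_xy: tuple[float, float]
    area_px2: float
    perimeter_px: float
    circularity: float


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to grayscale by luminance; pass 2D through."""
    px = np.asarray(pixels)
    if px.ndim == 2:
        return px
    if px.ndim == 3 and px.shape[2] in (3, 4):
        gray = px[..., :3].astype(np.float64) @ _LUMA
        if np.issubdtype(px.dtype, np.integer):
            return np.round(gray).astype(px.dtype)
        return gray
    raise ValueError(f"unsupported raster shape {px.shape}")


def read_image(path, pixel_size_um: float, hemisphere: str = "right",
               channel: str = "other") -> Image2D:
    """Read a TIFF/PNG raster into a calibrated :class:`Image2D`.

    RGB inputs are converted to grayscale by luminance weighting.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if not np.isfinite(pixel_size_um) or pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        px = tifffile.imread(p)
    elif suffix == ".png":
        px = iio.imread(p)
    else:
        raise ValueError(f"unsupported image format: {suffix!r} (expected TIFF or PNG)")
    return Image2D(to_grayscale(px), pixel_size_um, hemisphere, channel)


def write_image(image: Image2D, path) -> None:
    """Write an image to TIFF or PNG (lossless round trip for integer data)."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(p, image.pixels)
    elif suffix == ".png":
        iio.imwrite(p, image.pixels)
    else:
        raise ValueError(f"unsupported image format: {suffix!r}")


def write_cilia_csv(records: Sequence[CiliumRecord], path) -> None:
    """Write one CSV row per cilium (header always present)."""
    rows = [
        {
            "id": r.id,
            "section_id": r.section_id,
            "region_label": r.region_label,
            "hemisphere": r.hemisphere,
            "zt": r.zt,
            "length_um": r.length_um,
            "width_um": r.width_um,
            "angle_deg": r.angle_deg,
            "base_x": r.base_xy[0],
            "base_y": r.base_xy[1],
            "centroid_x": r.centroid_xy[0],
            "centroid_y": r.centroid_xy[1],
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CILIA_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_cilia_csv(path) -> list[CiliumRecord]:
    df = pd.read_csv(path, dtype={"section_id": str, "region_label": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(CiliumRecord(
            id=int(row.id),
            length_um=float(row.length_um),
            width_um=float(row.width_um),
            angle_deg=float(row.angle_deg),
            base_xy=(float(row.base_x), float(row.base_y)),
            centroid_xy=(float(row.centroid_x), float(row.centroid_y)),
            section_id="" if pd.isna(row.section_id) else str(row.section_id),
            region_label="" if pd.isna(row.region_label) else str(row.region_label),
            hemisphere=str(row.hemisphere),
            zt=float(row.zt),
        ))
    return records


def write_cells_csv(records: Sequence[CellRecord], path) -> None:
    rows = [
        {
            "id": r.id,
            "centroid_x": r.centroid_xy[0],
            "centroid_y": r.centroid_xy[1],
            "area_px2": r.area_px2,
            "circularity": r.circularity,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CELL_CSV_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def load_config(path) -> dict:
    """Load a flat ``key=value`` config file; values parsed as numbers when possible."""
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        try:
            cfg[key] = int(value)
        except ValueError:
            try:
                cfg[key] = float(value)
            except ValueError:
                cfg[key] = value
    return cfg
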