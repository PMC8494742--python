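"""Core raster containers and lossless raster I/O.

All images in this package live on a square pixel grid with a physical pixel
pitch in micrometres.  Angiograms are 16-bit scalar grids (one capillary
plexus each), scalar maps carry decoded physical quantities (retinal
thickness in µm, vessel density in %), and region masks are named binary
grids.  Coordinates are 0-based, row-major, origin at the top-left pixel;
the continuous position of pixel (i, j) is (x, y) = (j + 0.5, i + 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import GridMismatchError

FULL_SCALE_16 = 65535
#: default scan geometry: a fovea-centered 6 x 6 mm macula scan on a
#: 600 x 600 grid, i.e. 10 um per pixel.
SCAN_WIDTH_MM = 6.0
GRID_SIZE = 600

#: controlled vocabulary of named regions.  A = abnormal vascular region,
#: N = normal region, C = capillary congestion, FAZ = foveal avascular zone,
#: TZ = transitional zone (abnormal DCP under normal SCP).
REGION_NAMES = (
    "SCP-A", "SCP-N", "SCP-C", "SCP-FAZ",
    "DCP-A", "DCP-N", "DCP-C", "DCP-FAZ",
    "TZ", "DCP-C-in-TZ", "DCP-C-under-SCP-A",
    "TOTAL", "TOTAL-SCP", "TOTAL-DCP", "ME-territory",
)


def pixel_pitch_um(scan_width_mm: float = SCAN_WIDTH_MM,
                   n_pixels: int = GRID_SIZE) -> float:
    """Physical pixel pitch (µm/px) of a scan of given width and resolution."""
    if scan_width_mm <= 0 or n_pixels <= 0:
        raise ValueError("scan width and pixel count must be positive")
    return scan_width_mm * 1000.0 / n_pixels


def _require_same_grid(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise GridMismatchError(f"rasters live on different grids: {sorted(shapes)}")


@dataclass
class EnFaceAngiogram:
    """A 16-bit en-face OCTA flow image of one capillary plexus."""

    pixels: np.ndarray
    layer: str = "DCP"  # "SCP" or "DCP"
    pixel_pitch_um: float = 10.0
    slab_definition: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("angiogram must be a square 2-D grid")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.pixels.dtype != np.uint16:
            if self.pixels.min() < 0 or self.pixels.max() > FULL_SCALE_16:
                raise ValueError("pixel values must lie in [0, 65535]")
            self.pixels = self.pixels.astype(np.uint16)
        if self.layer not in ("SCP", "DCP"):
            raise ValueError("layer must be 'SCP' or 'DCP'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ScalarMap:
    """A decoded physical scalar grid (thickness in 'um' or vessel density in '%')."""

    values: np.ndarray
    units: str
    pixel_pitch_um: float = 10.0
    valid: np.ndarray | None = None  # companion validity mask (True = usable)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("scalar map must be 2-D")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            _require_same_grid(self.values, self.valid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RegionMask:
    """A named binary region on the case grid."""

    name: str
    pixels: np.ndarray
    pixel_pitch_um: float = 10.0

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(
                f"unknown region name {self.name!r}; expected one of {REGION_NAMES}")
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# lossless raster I/O
# ---------------------------------------------------------------------------

def save_angiogram(img: EnFaceAngiogram, path: str | Path) -> None:
    iio.imwrite(Path(path), img.pixels)


def load_angiogram(path: str | Path, layer: str = "DCP",
                   pixel_pitch_um: float = 10.0,
                   slab_definition: str = "") -> EnFaceAngiogram:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    return EnFaceAngiogram(arr.astype(np.uint16), layer=layer,
                           pixel_pitch_um=pixel_pitch_um,
                           slab_definition=slab_definition)


def save_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a mask as 8-bit single-channel PNG, 0 = FALSE, 255 = TRUE."""
    iio.imwrite(Path(path), np.where(mask.pixels, 255, 0).astype(np.uint8))


def load_mask(path: str | Path, name: str, pixel_pitch_um: float = 10.0,
              expected_shape: tuple[int, int] | None = None) -> RegionMask:
    """Read a binary mask raster; any nonzero pixel reads as TRUE."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # tolerate gray saved with redundant channels
        arr = arr[..., 0]
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise GridMismatchError(
            f"{path}: mask shape {arr.shape} != expected {tuple(expected_shape)}")
    return RegionMask(name, arr != 0, pixel_pitch_um=pixel_pitch_um)


def save_scalar_map(smap: ScalarMap, path: str | Path) -> None:
    """Write a scalar map as 16-bit PNG plus a JSON sidecar for unit recovery.

    The PNG stores a linear quantization of ``values`` over [vmin, vmax];
    the sidecar records units, range and pitch so the map can be restored.
    """
    path = Path(path)
    vmin = float(np.nanmin(smap.values))
    vmax = float(np.nanmax(smap.values))
    span = vmax - vmin
    if span == 0:
        q = np.zeros_like(smap.values, dtype=np.uint16)
    else:
        q = np.round((smap.values - vmin) / span * FULL_SCALE_16).astype(np.uint16)
    iio.imwrite(path, q)
    sidecar = {
        "units": smap.units,
        "vmin": vmin,
        "vmax": vmax,
        "pixel_pitch_um": smap.pixel_pitch_um,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_scalar_map(path: str | Path) -> ScalarMap:
    path = Path(path)
    q = np.asarray(iio.imread(path), dtype=np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    span = meta["vmax"] - meta["vmin"]
    values = meta["vmin"] + q / FULL_SCALE_16 * span if span else np.full_like(q, meta["vmin"])
    return ScalarMap(values, units=meta["units"],
                     pixel_pitch_um=meta["pixel_pitch_um"])
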