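"""Codec between 24-bit color-coded maps and physical scalar grids.

Review OCT software exports retinal-thickness and vessel-density maps as
24-bit color rasters.  Quantitative work needs the underlying scalars, so
this module converts color maps to scalar grids and back through an explicit
lookup table (LUT): an ordered list of (scalar, RGB) control points with
piecewise-linear interpolation in RGB between them.  The device vendor's own
conversion table is proprietary; a documented rainbow-style default is
shipped and any user LUT can be supplied as CSV.  Correctness is defined by
the round-trip contract: |decode(encode(x)) − x| ≤ one quantization step.

Decoding inverts the LUT by exhaustive nearest-neighbour search over a
densely sampled color path (Euclidean RGB distance, ties toward the lower
scalar).  Pixels farther than ``max_path_distance`` from the path are marked
invalid in a companion validity mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DecodeError, LutError
from .images import ScalarMap

DEFAULT_PATH_SAMPLES = 4096


@dataclass
class ColorLut:
    """Piecewise-linear scalar→RGB lookup table.

    ``scalars`` must be strictly increasing and the interpolated RGB path
    must be injective (no two well-separated scalars share a color within
    quantization) — both are checked at construction.
    """

    scalars: np.ndarray          # (K,) strictly increasing
    colors: np.ndarray           # (K, 3) in [0, 255]
    units: str = "um"
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _samples: np.ndarray | None = field(default=None, repr=False, compare=False)
    _sample_scalars: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scalars = np.asarray(self.scalars, dtype=np.float64)
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.scalars.ndim != 1 or len(self.scalars) < 2:
            raise LutError("LUT needs at least two control points")
        if self.colors.shape != (len(self.scalars), 3):
            raise LutError("colors must be (K, 3)")
        if np.any(np.diff(self.scalars) <= 0):
            raise LutError("LUT scalars must be strictly increasing")
        if self.colors.min() < 0 or self.colors.max() > 255:
            raise LutError("RGB channels must lie in [0, 255]")
        self._build_path()
        self._check_injective()

    # -- path machinery -----------------------------------------------------

    def _build_path(self, n_samples: int = DEFAULT_PATH_SAMPLES) -> None:
        s = np.linspace(self.scalars[0], self.scalars[-1], n_samples)
        rgb = np.column_stack(
            [np.interp(s, self.scalars, self.colors[:, c]) for c in range(3)])
        self._sample_scalars = s
        self._samples = rgb
        self._tree = cKDTree(rgb)

    def _check_injective(self) -> None:
        # colors close in RGB must be close in scalar: query each path sample's
        # neighbourhood and reject the LUT if a far-away scalar reuses a color.
        step = self.quantization_step
        pairs = self._tree.query_pairs(r=1.0, output_type="ndarray")
        if len(pairs):
            gap = np.abs(self._sample_scalars[pairs[:, 0]]
                         - self._sample_scalars[pairs[:, 1]])
            if np.any(gap > 4 * step):
                raise LutError("LUT color path is not injective within quantization")

    @property
    def scalar_range(self) -> tuple[float, float]:
        return float(self.scalars[0]), float(self.scalars[-1])

    @property
    def quantization_step(self) -> float:
        """Smallest scalar increment the codec can resolve.

        The RGB path advances by its total L1 length over the scalar span, so
        one 8-bit RGB unit corresponds to span/path_length scalar units, and
        the dense path sampling snaps decodes to a grid of span/(n_samples−1);
        their sum bounds the decode movement caused by a one-unit color change.
        """
        span = self.scalars[-1] - self.scalars[0]
        path_len = float(np.abs(np.diff(self.colors, axis=0)).sum())
        if path_len == 0:
            raise LutError("LUT path has zero length")
        return span / path_len + span / (len(self._sample_scalars) - 1)

    # -- CSV I/O ------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, units: str = "um") -> "ColorLut":
        """Load a LUT from CSV with required header ``scalar,R,G,B``."""
        path = Path(path)
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header != ["scalar", "r", "g", "b"]:
            raise LutError(f"{path}: expected header 'scalar,R,G,B', got {lines[0]!r}")
        rows = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
        return cls(rows[:, 0], rows[:, 1:4], units=units)

    def to_csv(self, path: str | Path) -> None:
        lines = ["scalar,R,G,B"]
        for s, (r, g, b) in zip(self.scalars, self.colors):
            lines.append(f"{s},{r:g},{g:g},{b:g}")
        Path(path).write_text("\n".join(lines) + "\n")


def default_thickness_lut(vmin: float = 0.0, vmax: float = 500.0) -> ColorLut:
    """Rainbow-style LUT for retinal thickness (µm), blue → red."""
    knots = np.linspace(vmin, vmax, 5)
    colors = np.array([
        [0, 0, 255], [0, 255, 255], [0, 255, 0], [255, 255, 0], [255, 0, 0]],
        dtype=float)
    return ColorLut(knots, colors, units="um")


def default_vd_lut() -> ColorLut:
    """Rainbow-style LUT for vessel density (0–100 %)."""
    lut = default_thickness_lut(0.0, 100.0)
    lut.units = "%"
    return lut


def encode_scalar_map(smap: ScalarMap, lut: ColorLut) -> np.ndarray:
    """Render a scalar map as a 24-bit color image through the LUT.

    Out-of-range values are clamped to the LUT range (with a warning).
    """
    lo, hi = lut.scalar_range
    values = smap.values
    n_clipped = int(((values < lo) | (values > hi)).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} px outside LUT range [{lo}, {hi}]; clamped",
                      stacklevel=2)
        values = np.clip(values, lo, hi)
    rgb = np.stack(
        [np.interp(values, lut.scalars, lut.colors[:, c]) for c in range(3)],
        axis=-1)
    return np.round(rgb).astype(np.uint8)


def decode_color_map(image: np.ndarray, lut: ColorLut,
                     pixel_pitch_um: float = 10.0,
                     max_path_distance: float = 8.0,
                     max_invalid_frac: float = 0.05) -> ScalarMap:
    """Invert a 24-bit color map to scalars by nearest color on the LUT path.

    Each pixel maps to the scalar of its nearest densely-sampled path color
    (Euclidean RGB distance, ties toward the lower scalar).  Pixels farther
    than ``max_path_distance`` RGB units from the path are marked invalid;
    more than ``max_invalid_frac`` invalid pixels raises ``DecodeError``
    naming the worst offending colors.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 color image")
    flat = image.reshape(-1, 3).astype(np.float64)
    dist, idx = lut._tree.query(flat, k=2)
    # break exact distance ties toward the lower scalar (lower sample index)
    tie = np.isclose(dist[:, 0], dist[:, 1])
    best = np.where(tie, np.minimum(idx[:, 0], idx[:, 1]), idx[:, 0])
    scalars = lut._sample_scalars[best].reshape(image.shape[:2])
    valid = (dist[:, 0] <= max_path_distance).reshape(image.shape[:2])
    invalid_frac = 1.0 - valid.mean()
    if invalid_frac > max_invalid_frac:
        worst_order = np.argsort(dist[:, 0])[::-1][:5]
        offenders = [
            (tuple(int(c) for c in flat[i]), float(dist[i, 0]))
            for i in worst_order]
        raise DecodeError(
            f"{invalid_frac:.1%} of pixels are farther than "
            f"{max_path_distance} RGB units from the LUT path; "
            f"worst offenders (color, distance): {offenders}")
    return ScalarMap(scalars, units=lut.units,
                     pixel_pitch_um=pixel_pitch_um, valid=valid)
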