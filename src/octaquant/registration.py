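"""Control-point affine registration between visits.

Baseline and follow-up scans are aligned by a 3×3 homogeneous affine
transform solved in least squares from manually selected vessel-bifurcation
control points, then follow-up maps are resampled onto the baseline grid by
inverse mapping with bilinear interpolation.

Coordinate convention: points are continuous (x, y) with pixel (i, j)
centered at (j + 0.5, i + 0.5); this avoids half-pixel drift between the
point files and the resampler.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .exceptions import RegistrationError
from .images import ScalarMap


@dataclass
class ControlPointSet:
    """Paired (source x,y; target x,y) control points in pixel coordinates."""

    src: np.ndarray  # (N, 2)
    dst: np.ndarray  # (N, 2)

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=np.float64)
        self.dst = np.asarray(self.dst, dtype=np.float64)
        if self.src.shape != self.dst.shape or self.src.ndim != 2 \
                or self.src.shape[1] != 2:
            raise RegistrationError("src and dst must both be (N, 2)")
        if len(self.src) < 3:
            raise RegistrationError("need at least 3 control-point pairs")
        # collinearity test: the centered source cloud must span the plane
        centered = self.src - self.src.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-8 * max(1.0, sv[0]):
            raise RegistrationError("source control points are collinear")

    def __len__(self) -> int:
        return len(self.src)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlPointSet":
        """Read pairs from CSV with header ``src_x,src_y,dst_x,dst_y``."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()
                 if ln.strip()]
        header = [h.strip().lower() for h in lines[0].split(",")]
        if header != ["src_x", "src_y", "dst_x", "dst_y"]:
            raise RegistrationError(
                f"{path}: expected header 'src_x,src_y,dst_x,dst_y'")
        rows = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
        return cls(rows[:, :2], rows[:, 2:4])

    def to_csv(self, path: str | Path) -> None:
        lines = ["src_x,src_y,dst_x,dst_y"]
        for (sx, sy), (dx, dy) in zip(self.src, self.dst):
            lines.append(f"{sx},{sy},{dx},{dy}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class AffineTransform2D:
    """Homogeneous 2-D affine transform with last row (0, 0, 1)."""

    matrix: np.ndarray
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (3, 3):
            raise RegistrationError("affine matrix must be 3x3")
        if not np.allclose(self.matrix[2], [0, 0, 1]):
            raise RegistrationError("last row must be (0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise RegistrationError("affine transform is degenerate")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) source points to target coordinates."""
        pts = np.asarray(points, dtype=np.float64)
        homo = np.column_stack([pts, np.ones(len(pts))])
        return (homo @ self.matrix.T)[:, :2]

    def inverse(self) -> "AffineTransform2D":
        return AffineTransform2D(np.linalg.inv(self.matrix))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"matrix": self.matrix.tolist(),
             "rms_residual_px": self.rms_residual_px}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        data = json.loads(Path(path).read_text())
        return cls(np.array(data["matrix"]),
                   rms_residual_px=data.get("rms_residual_px", 0.0))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, rotation_deg: float = 0.0, scale: float = 1.0,
                    translation: tuple[float, float] = (0.0, 0.0),
                    center: tuple[float, float] = (0.0, 0.0)
                    ) -> "AffineTransform2D":
        """Similarity transform rotating/scaling about ``center`` then translating."""
        th = np.deg2rad(rotation_deg)
        r = scale * np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
        cx, cy = center
        t = np.array([cx, cy]) - r @ np.array([cx, cy]) + np.asarray(translation)
        m = np.eye(3)
        m[:2, :2] = r
        m[:2, 2] = t
        return cls(m)


def fit_affine(points: ControlPointSet,
               residual_ceiling_px: float | None = None) -> AffineTransform2D:
    """Least-squares affine transform mapping source → target points.

    Solves the overdetermined linear system [x y 1]·Aᵀ = [x' y'] by least
    squares; with exactly 3 non-collinear pairs the solution interpolates.
    The RMS point residual is reported on the result, and a warning is
    emitted if it exceeds ``residual_ceiling_px``.
    """
    design = np.column_stack([points.src, np.ones(len(points))])
    coef, *_ = np.linalg.lstsq(design, points.dst, rcond=None)
    m = np.eye(3)
    m[:2, :] = coef.T
    transform = AffineTransform2D(m)
    resid = transform.apply(points.src) - points.dst
    transform.rms_residual_px = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    if residual_ceiling_px is not None \
            and transform.rms_residual_px > residual_ceiling_px:
        warnings.warn(
            f"registration residual {transform.rms_residual_px:.3f} px exceeds "
            f"ceiling {residual_ceiling_px} px", stacklevel=2)
    return transform


def warp_map(smap: ScalarMap, transform: AffineTransform2D,
             out_shape: tuple[int, int] | None = None,
             order: str = "bilinear") -> tuple[ScalarMap, np.ndarray]:
    """Resample a source map onto the target grid under a source→target affine.

    Inverse mapping: each target pixel center is pulled back through the
    transform inverse and the source map is sampled there (bilinear by
    default, nearest-neighbour for label maps via ``order="nearest"``).
    Target pixels whose pull-back falls outside the source raster are NaN in
    the returned map and False in the overlap validity mask.
    """
    if order not in ("bilinear", "nearest"):
        raise ValueError("order must be 'bilinear' or 'nearest'")
    out_shape = out_shape or smap.shape
    h, w = out_shape
    inv = transform.inverse()
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    centers = np.column_stack([jj.ravel() + 0.5, ii.ravel() + 0.5])
    src_xy = inv.apply(centers)
    cols = src_xy[:, 0] - 0.5
    rows = src_xy[:, 1] - 0.5
    sh, sw = smap.shape
    valid = ((rows >= 0) & (rows <= sh - 1)
             & (cols >= 0) & (cols <= sw - 1)).reshape(out_shape)
    sampled = ndi.map_coordinates(
        smap.values, [rows, cols],
        order=1 if order == "bilinear" else 0, mode="nearest")
    warped = sampled.reshape(out_shape)
    warped[~valid] = np.nan
    if smap.valid is not None:
        src_valid = ndi.map_coordinates(
            smap.valid.astype(np.float64), [rows, cols], order=0,
            mode="constant", cval=0.0).reshape(out_shape) > 0.5
        valid = valid & src_valid
    return (ScalarMap(warped, units=smap.units,
                      pixel_pitch_um=smap.pixel_pitch_um, valid=valid),
            valid)
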