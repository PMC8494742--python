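"""Ratio of increased retinal thickness (RIRT) and the macular-edema territory.

After registering the follow-up thickness map onto the baseline grid, the
RIRT at each overlapping pixel is follow-up thickness divided by baseline
thickness.  The macular-edema (ME) territory is the strict superlevel set
RIRT > 1.1 — thickening of more than 10 % over baseline — with its boundary
traced by marching squares.  Apexes (local RIRT maxima inside the territory)
are localized on a lightly smoothed copy of the field and labeled by where
they fall: FAZ, NPA/abnormal region, or elsewhere.

The eye-level recurrence rule uses the *inclusive* form of the same cut:
an eye recurs when central subfield macular thickness rises by 10 % or more
from baseline.  Both threshold semantics are deliberate and unit-tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .exceptions import RirtError
from .images import RegionMask, ScalarMap, _require_same_grid

ME_THRESHOLD = 1.1


def compute_rirt(baseline: ScalarMap, warped_followup: ScalarMap,
                 overlap: np.ndarray | None = None,
                 max_zero_frac: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel follow-up/baseline thickness ratio on the overlap.

    Returns (rirt, valid): the ratio map (NaN where undefined) and the
    validity mask.  Zero/negative-baseline pixels inside the overlap are
    excluded with a warning; more than ``max_zero_frac`` of them raises.
    """
    _require_same_grid(baseline.values, warped_followup.values)
    if overlap is None:
        overlap = np.ones(baseline.shape, dtype=bool)
    else:
        overlap = np.asarray(overlap, dtype=bool)
        _require_same_grid(baseline.values, overlap)
    if warped_followup.valid is not None:
        overlap = overlap & warped_followup.valid
    if baseline.valid is not None:
        overlap = overlap & baseline.valid
    finite = np.isfinite(baseline.values) & np.isfinite(warped_followup.values)
    overlap = overlap & finite
    nonpos = overlap & (baseline.values <= 0)
    n_overlap = int(overlap.sum())
    if n_overlap and nonpos.sum() / n_overlap > max_zero_frac:
        raise RirtError(
            f"{nonpos.sum()} of {n_overlap} overlap px have non-positive "
            "baseline thickness")
    if nonpos.any():
        warnings.warn(f"excluding {int(nonpos.sum())} zero-baseline px",
                      stacklevel=2)
    valid = overlap & ~nonpos
    rirt = np.full(baseline.shape, np.nan)
    rirt[valid] = warped_followup.values[valid] / baseline.values[valid]
    return rirt, valid


def me_territory(rirt: np.ndarray, valid: np.ndarray,
                 threshold: float = ME_THRESHOLD
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Strict superlevel set {RIRT > threshold} ∩ overlap, plus its contours.

    Contours are closed polylines at the threshold level from marching
    squares, in (row, col) coordinates.  A pixel exactly at the threshold is
    excluded (the territory is *more than* a 10 % increase).
    """
    if threshold <= 1:
        raise ValueError("territory threshold must exceed 1")
    territory = np.zeros(rirt.shape, dtype=bool)
    territory[valid] = rirt[valid] > threshold
    work = np.where(valid, rirt, threshold - 1.0)
    contours = measure.find_contours(work, level=threshold)
    return territory, contours


@dataclass
class Apex:
    """A local RIRT maximum inside the ME territory."""

    row: int
    col: int
    value: float
    label: str  # "FAZ", "NPA" or "other"


def locate_apexes(rirt: np.ndarray, valid: np.ndarray, territory: np.ndarray,
                  faz: RegionMask, abnormal: RegionMask,
                  sigma_px: float = 2.0) -> list[Apex]:
    """Local maxima of the (smoothed) RIRT field inside the territory.

    A Gaussian of ``sigma_px`` suppresses single-pixel noise maxima.  Each
    apex is labeled FAZ if it falls inside the deep-plexus FAZ, else NPA if
    inside the abnormal region, else "other".  Apexes are ranked by value;
    exact ties break by raster order, and a flat plateau yields one apex at
    its first raster pixel.
    """
    _require_same_grid(rirt, faz.pixels, abnormal.pixels)
    if not territory.any():
        return []
    smoothed = ndi.gaussian_filter(np.where(valid, rirt, 1.0), sigma=sigma_px)
    local_max = (smoothed == ndi.maximum_filter(smoothed, size=5)) & territory
    if not local_max.any():
        return []
    # one apex per connected plateau, at its first raster pixel
    labels, n = ndi.label(local_max, structure=np.ones((3, 3)))
    apexes = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        k = np.lexsort((cols, rows))[0]
        r, c = int(rows[k]), int(cols[k])
        if faz.pixels[r, c]:
            tag = "FAZ"
        elif abnormal.pixels[r, c]:
            tag = "NPA"
        else:
            tag = "other"
        apexes.append(Apex(r, c, float(rirt[r, c]), tag))
    apexes.sort(key=lambda a: (-a.value, a.row, a.col))
    return apexes


@dataclass
class RirtSummary:
    """Mean/max RIRT over the ME territory and over DCP-C (NaN = undefined)."""

    mean_territory: float
    max_territory: float
    mean_dcp_c: float
    max_dcp_c: float


def rirt_summary(rirt: np.ndarray, valid: np.ndarray, territory: np.ndarray,
                 dcp_c: RegionMask) -> RirtSummary:
    _require_same_grid(rirt, valid, territory, dcp_c.pixels)

    def _stats(mask: np.ndarray) -> tuple[float, float]:
        sel = mask & valid
        if not sel.any():
            return math.nan, math.nan
        vals = rirt[sel]
        return float(vals.mean()), float(vals.max())

    mt, xt = _stats(territory)
    mc, xc = _stats(dcp_c.pixels)
    return RirtSummary(mt, xt, mc, xc)


@dataclass
class RirtResult:
    """Full RIRT analysis of one baseline/recurrence pair."""

    rirt_map: np.ndarray
    overlap: np.ndarray
    territory: np.ndarray
    contours: list[np.ndarray]
    apexes: list[Apex]
    summary: RirtSummary
    threshold: float = ME_THRESHOLD
    smoothing_sigma_px: float = 2.0


def analyze_rirt(baseline: ScalarMap, warped_followup: ScalarMap,
                 dcp_c: RegionMask, faz: RegionMask, abnormal: RegionMask,
                 overlap: np.ndarray | None = None,
                 threshold: float = ME_THRESHOLD,
                 sigma_px: float = 2.0) -> RirtResult:
    """Convenience pipeline: ratio → territory → apexes → summary."""
    rirt, valid = compute_rirt(baseline, warped_followup, overlap)
    territory, contours = me_territory(rirt, valid, threshold)
    apexes = locate_apexes(rirt, valid, territory, faz, abnormal, sigma_px)
    summary = rirt_summary(rirt, valid, territory, dcp_c)
    return RirtResult(rirt, valid, territory, contours, apexes, summary,
                      threshold=threshold, smoothing_sigma_px=sigma_px)


def classify_recurrence(csmt_baseline_um: float, csmt_followup_um: float,
                        min_increase_frac: float = 0.10) -> bool:
    """Eye-level recurrence: CSMT increased by 10 % *or more* from baseline.

    Inclusive at the boundary (300 → 330 µm recurs).  A relative epsilon
    absorbs binary floating point at the exact boundary.
    """
    if csmt_baseline_um <= 0 or csmt_followup_um <= 0:
        raise ValueError("CSMT values must be positive")
    cut = csmt_baseline_um * (1.0 + min_increase_frac)
    return csmt_followup_um >= cut - 1e-9 * csmt_baseline_um


def render_contour_plot(result: RirtResult, dcp_c: RegionMask,
                        path, title: str = "ME territory"):
    """Contour plot of the ME territory with the DCP-C boundary overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    shown = np.where(result.territory, result.rirt_map, np.nan)
    levels = np.linspace(result.threshold,
                         max(np.nanmax(shown) if np.isfinite(shown).any()
                             else result.threshold + 0.1,
                             result.threshold + 1e-3), 8)
    im = ax.contourf(shown, levels=levels, cmap="plasma")
    fig.colorbar(im, ax=ax, label="RIRT")
    for contour in measure.find_contours(dcp_c.pixels.astype(float), 0.5):
        ax.plot(contour[:, 1], contour[:, 0], color="blue", lw=1.0)
    for apex in result.apexes:
        ax.plot(apex.col, apex.row, "k^", ms=6)
    ax.set_title(title)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    fig.savefig(path, dpi=120)
    plt.close(fig)
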