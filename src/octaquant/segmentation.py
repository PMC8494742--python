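"""Capillary congestion detection from pixel rules on en-face angiograms.

Capillary congestion presents on en-face OCTA as expanded, bright, coarse
capillary networks bridging the affected and normal vasculature.  At a 10 µm
pixel pitch a normal capillary (5–13 µm) spans at most two pixels, which
grounds three per-component pixel rules on the gamma-corrected image:

* expanded — some skeleton-point caliber exceeds ``expanded_caliber_px``
  (default 2 px, strict);
* bright   — component median gray level at or above ``bright_threshold``
  (default 32768, i.e. 50 % of 16-bit full scale);
* coarse   — within-component caliber range exceeds
  ``coarse_fluctuation_px`` (default 2 px, strict).

Calibers are estimated at skeleton points as 2·d − 1 px, where d is the
Euclidean distance to the nearest background pixel (d overshoots the vessel
half-width by about half a pixel on each side, so a 5-px ribbon reads ≈5 px
and a 1-px line reads ≈1 px).  Qualifying components must additionally lie
within ``boundary_band_px`` of the abnormal/normal interface, and the FAZ is
always excluded.  Connectivity is 8-neighbour throughout.

Manually drawn congestion masks are supported through the same raster
round-trip as every other mask (see :mod:`octaquant.images`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import disk, remove_small_objects, skeletonize

from .images import FULL_SCALE_16, EnFaceAngiogram, RegionMask, _require_same_grid
# re-exported: mask raster I/O lives with the other raster codecs
from .images import load_mask, save_mask  # noqa: F401

RULE_MODES = ("bright_and_expanded_or_coarse", "all", "any")


@dataclass
class CongestionParams:
    """Tunable parameters of the congestion detector (defaults documented above)."""

    gamma: float = 3.0
    bright_threshold: int = 32768
    expanded_caliber_px: float = 2.0
    coarse_fluctuation_px: float = 2.0
    vessel_threshold: int = 24000
    speckle_min_px: int = 10
    rule_mode: str = "bright_and_expanded_or_coarse"
    boundary_band_px: float = 20.0
    bright_on_raw: bool = False   # judge brightness on the raw image instead
    bright_stat: str = "median"   # or "mean"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (0 < self.bright_threshold <= FULL_SCALE_16):
            raise ValueError("bright_threshold must lie in (0, 65535]")
        if self.expanded_caliber_px <= 0 or self.coarse_fluctuation_px <= 0:
            raise ValueError("caliber thresholds must be positive")
        if self.vessel_threshold < 0:
            raise ValueError("vessel_threshold must be non-negative")
        if self.rule_mode not in RULE_MODES:
            raise ValueError(f"rule_mode must be one of {RULE_MODES}")
        if self.bright_stat not in ("median", "mean"):
            raise ValueError("bright_stat must be 'median' or 'mean'")


def gamma_correct(img: EnFaceAngiogram | np.ndarray,
                  gamma: float = 3.0) -> EnFaceAngiogram | np.ndarray:
    """Gamma correction: out = round(FS · (in/FS)^(1/γ)).

    Monotone and endpoint-preserving; γ > 1 brightens mid-range flow signal,
    which is what makes the congestion boundary conspicuous.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    arr = img.pixels if isinstance(img, EnFaceAngiogram) else np.asarray(img)
    out = np.round(FULL_SCALE_16 *
                   (arr.astype(np.float64) / FULL_SCALE_16) ** (1.0 / gamma))
    out = out.astype(np.uint16)
    if isinstance(img, EnFaceAngiogram):
        return EnFaceAngiogram(out, layer=img.layer,
                               pixel_pitch_um=img.pixel_pitch_um,
                               slab_definition=img.slab_definition)
    return out


def extract_vessels(img: EnFaceAngiogram,
                    params: CongestionParams | None = None) -> np.ndarray:
    """Binary vessel mask: gamma-corrected pixels ≥ vessel_threshold,
    speckle components below ``speckle_min_px`` removed."""
    params = params or CongestionParams()
    corrected = gamma_correct(img, params.gamma)
    mask = corrected.pixels >= params.vessel_threshold
    if params.speckle_min_px > 1 and not mask.all():
        mask = remove_small_objects(mask, max_size=params.speckle_min_px - 1,
                                    connectivity=2)
    if not mask.any():
        warnings.warn("vessel extraction produced an empty mask", stacklevel=2)
    return mask


def estimate_calibers(vessels: np.ndarray) -> np.ndarray:
    """Per-skeleton-pixel caliber map (px); NaN off the skeleton.

    Caliber at a skeleton point = 2·EDT − 1 where EDT is the Euclidean
    distance to the nearest background pixel (see module docstring).
    """
    vessels = np.asarray(vessels, dtype=bool)
    if not vessels.any():
        raise ValueError("vessel mask is empty")
    skel = skeletonize(vessels)
    edt = ndi.distance_transform_edt(vessels)
    calibers = np.full(vessels.shape, np.nan)
    calibers[skel] = 2.0 * edt[skel] - 1.0
    return calibers


def _interface_band(abnormal: np.ndarray, faz: np.ndarray,
                    band_px: float) -> np.ndarray:
    """Pixels within ``band_px`` of the abnormal/normal interface."""
    normal = ~abnormal & ~faz
    r = max(int(round(band_px)), 1)
    selem = disk(r)
    return (ndi.binary_dilation(abnormal, structure=selem)
            & ndi.binary_dilation(normal, structure=selem))


def detect_congestion(img: EnFaceAngiogram, abnormal: RegionMask,
                      faz: RegionMask,
                      params: CongestionParams | None = None) -> RegionMask:
    """Automatic congestion mask from the expanded/bright/coarse pixel rules.

    Connected vessel components (8-connectivity) are scored against the
    three criteria and combined per ``rule_mode`` (default: bright AND
    (expanded OR coarse)); qualifying components must intersect the
    abnormal/normal boundary band and are returned as hole-filled
    footprints with FAZ pixels removed.
    """
    params = params or CongestionParams()
    _require_same_grid(img.pixels, abnormal.pixels, faz.pixels)
    vessels = extract_vessels(img, params)
    name = f"{img.layer}-C"
    pitch = img.pixel_pitch_um
    if not vessels.any():
        return RegionMask(name, vessels, pixel_pitch_um=pitch)

    corrected = gamma_correct(img, params.gamma)
    intensity = (img.pixels if params.bright_on_raw else corrected.pixels)
    calibers = estimate_calibers(vessels)
    labels = label(vessels, connectivity=2)
    band = _interface_band(abnormal.pixels, faz.pixels, params.boundary_band_px)

    out = np.zeros(vessels.shape, dtype=bool)
    stat = np.median if params.bright_stat == "median" else np.mean
    for comp in range(1, labels.max() + 1):
        sel = labels == comp
        cal = calibers[sel]
        cal = cal[np.isfinite(cal)]
        expanded = bool(cal.size) and float(cal.max()) > params.expanded_caliber_px
        coarse = (bool(cal.size)
                  and float(cal.max() - cal.min()) > params.coarse_fluctuation_px)
        bright = float(stat(intensity[sel])) >= params.bright_threshold
        if params.rule_mode == "all":
            ok = bright and expanded and coarse
        elif params.rule_mode == "any":
            ok = bright or expanded or coarse
        else:
            ok = bright and (expanded or coarse)
        if ok and bool((sel & band).any()):
            out |= sel
    out = ndi.binary_fill_holes(out)
    out &= ~faz.pixels
    return RegionMask(name, out, pixel_pitch_um=pitch)
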