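"""Mask algebra deriving the named region system from primitive masks.

The region system: the manually (or automatically) segmented abnormal
vascular region (A) and foveal avascular zone (FAZ) of each plexus define
the normal region N = NOT(A OR FAZ), so {A, N, FAZ} partitions the frame.
The transitional zone TZ — abnormal deep plexus under normal superficial
plexus — is the elementwise (Hadamard) product of SCP-N and DCP-A.  The deep
congestion mask DCP-C is partitioned into the part inside TZ, the part under
SCP-A, and a residual that is empty whenever DCP-C ⊆ DCP-A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import RegionMask, _require_same_grid


def normal_region(abnormal: RegionMask, faz: RegionMask,
                  name: str | None = None) -> RegionMask:
    """Complement of (abnormal OR FAZ): the normal capillary region.

    If the abnormal mask overlaps the FAZ, FAZ pixels are removed from the
    abnormal set first (FAZ wins) and a warning is emitted; the returned
    normal region is unaffected either way since N = NOT(A OR FAZ).
    """
    _require_same_grid(abnormal.pixels, faz.pixels)
    overlap = int((abnormal.pixels & faz.pixels).sum())
    if overlap:
        warnings.warn(
            f"abnormal mask {abnormal.name!r} overlaps FAZ on {overlap} px; "
            "FAZ takes precedence", stacklevel=2)
    if name is None:
        layer = abnormal.name.split("-")[0]
        name = f"{layer}-N"
    return RegionMask(name, ~(abnormal.pixels | faz.pixels),
                      pixel_pitch_um=abnormal.pixel_pitch_um)


def repair_abnormal(abnormal: RegionMask, faz: RegionMask) -> RegionMask:
    """Abnormal mask with FAZ pixels removed, so {A, N, FAZ} partitions the frame."""
    _require_same_grid(abnormal.pixels, faz.pixels)
    return RegionMask(abnormal.name, abnormal.pixels & ~faz.pixels,
                      pixel_pitch_um=abnormal.pixel_pitch_um)


def transitional_zone(scp_n: RegionMask, dcp_a: RegionMask) -> RegionMask:
    """TZ = SCP-N ⊙ DCP-A (elementwise AND of the two binary matrices)."""
    _require_same_grid(scp_n.pixels, dcp_a.pixels)
    return RegionMask("TZ", scp_n.pixels & dcp_a.pixels,
                      pixel_pitch_um=dcp_a.pixel_pitch_um)


@dataclass
class DcpCongestionPartition:
    """DCP-C split into its TZ part, its part under SCP-A, and a residual."""

    in_tz: RegionMask
    under_scp_a: RegionMask
    residual: RegionMask

    @property
    def residual_fraction(self) -> float:
        total = self.in_tz.count() + self.under_scp_a.count() + self.residual.count()
        return self.residual.count() / total if total else 0.0


def partition_dcp_congestion(dcp_c: RegionMask, tz: RegionMask,
                             scp_a: RegionMask,
                             dcp_a: RegionMask | None = None,
                             ) -> DcpCongestionPartition:
    """Classify every DCP-C pixel as in-TZ, under-SCP-A, or residual.

    TZ takes precedence (TZ and SCP-A are disjoint by construction when TZ
    was derived from SCP-N, so precedence only matters for free-form input).
    The residual collects DCP-C pixels in neither; with masks derived per
    the region definitions it is empty whenever DCP-C ⊆ DCP-A, and a
    nonzero residual fraction flags inconsistent input masks.
    """
    _require_same_grid(dcp_c.pixels, tz.pixels, scp_a.pixels)
    if dcp_a is not None:
        _require_same_grid(dcp_c.pixels, dcp_a.pixels)
        outside = int((dcp_c.pixels & ~dcp_a.pixels).sum())
        if outside:
            warnings.warn(f"{outside} DCP-C px fall outside DCP-A", stacklevel=2)
    pitch = dcp_c.pixel_pitch_um
    in_tz = dcp_c.pixels & tz.pixels
    under = dcp_c.pixels & ~tz.pixels & scp_a.pixels
    residual = dcp_c.pixels & ~tz.pixels & ~scp_a.pixels
    return DcpCongestionPartition(
        in_tz=RegionMask("DCP-C-in-TZ", in_tz, pixel_pitch_um=pitch),
        under_scp_a=RegionMask("DCP-C-under-SCP-A", under, pixel_pitch_um=pitch),
        residual=RegionMask("DCP-C", residual, pixel_pitch_um=pitch),
    )
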