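"""Region morphometry: area, mean vessel density, mean retinal thickness.

These are the per-region quantities tabulated for each eye: physical area in
mm² (and % of the scanned frame), the mean of the decoded vessel-density map
over the region (VD, %), and the mean of the decoded retinal-thickness map
over the region (MRT, µm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .images import RegionMask, ScalarMap, _require_same_grid

#: deterministic row order for the per-eye metrics table.
REGION_ORDER = (
    "TOTAL-SCP", "SCP-A", "SCP-N", "SCP-C", "SCP-FAZ",
    "TOTAL-DCP", "DCP-A", "DCP-N", "DCP-C", "DCP-FAZ",
    "TZ", "DCP-C-in-TZ", "DCP-C-under-SCP-A",
)


def region_area(mask: RegionMask, pitch_um: float | None = None
                ) -> tuple[float, float]:
    """Physical area of a mask: (mm², percent of full frame)."""
    pitch = mask.pixel_pitch_um if pitch_um is None else pitch_um
    if pitch <= 0:
        raise ValueError("pixel pitch must be positive")
    count = mask.count()
    area_mm2 = count * (pitch / 1000.0) ** 2
    area_pct = count / mask.pixels.size * 100.0
    return area_mm2, area_pct


def mean_over_mask(smap: ScalarMap, mask: RegionMask) -> tuple[float, int]:
    """Arithmetic mean of the map over TRUE pixels, in map units.

    Pixels flagged invalid by the map's validity mask are excluded.  Returns
    (mean, n_excluded); the mean is NaN (undefined) for an empty effective
    mask — callers must treat NaN as "metric undefined", never as a value.
    """
    _require_same_grid(smap.values, mask.pixels)
    sel = mask.pixels
    n_excluded = 0
    if smap.valid is not None:
        n_excluded = int((sel & ~smap.valid).sum())
        sel = sel & smap.valid
    if not sel.any():
        return math.nan, n_excluded
    return float(smap.values[sel].mean()), n_excluded


@dataclass
class RegionMetrics:
    """One row of the per-eye metrics table."""

    region: str
    pixel_count: int
    area_mm2: float
    area_pct: float
    mean_vd_pct: float  # NaN = undefined
    mrt_um: float       # NaN = undefined
    undefined: bool
    missing_input: bool = False


def _metrics_row(region: str, mask: RegionMask | None,
                 vd: ScalarMap | None, thickness: ScalarMap | None
                 ) -> RegionMetrics:
    if mask is None:
        return RegionMetrics(region, 0, math.nan, math.nan, math.nan,
                             math.nan, undefined=True, missing_input=True)
    area_mm2, area_pct = region_area(mask)
    vd_mean = mean_over_mask(vd, mask)[0] if vd is not None else math.nan
    mrt = mean_over_mask(thickness, mask)[0] if thickness is not None else math.nan
    return RegionMetrics(region, mask.count(), area_mm2, area_pct,
                         vd_mean, mrt, undefined=mask.count() == 0)


def metrics_table(masks: dict[str, RegionMask],
                  thickness: ScalarMap | None = None,
                  vd_scp: ScalarMap | None = None,
                  vd_dcp: ScalarMap | None = None,
                  eye_id: str = "case") -> pd.DataFrame:
    """Per-region metrics for all named regions, in deterministic order.

    Total-frame rows (TOTAL-SCP / TOTAL-DCP) cover every pixel of the frame
    including the FAZ.  A region absent from ``masks`` yields a row flagged
    ``missing_input``.  The VD map is chosen per region by its plexus (TZ and
    the DCP-C partition rows read the DCP map).
    """
    grids = [m.shape for m in masks.values()]
    if grids and len(set(grids)) > 1:
        raise ValueError("all masks must share one grid")
    rows = []
    for region in REGION_ORDER:
        vd = vd_scp if region.startswith(("SCP", "TOTAL-SCP")) else vd_dcp
        if region.startswith("TOTAL"):
            template = next(iter(masks.values()), None)
            if template is None:
                mask = None
            else:
                mask = RegionMask(region, np.ones(template.shape, dtype=bool),
                                  pixel_pitch_um=template.pixel_pitch_um)
        else:
            mask = masks.get(region)
        rows.append(_metrics_row(region, mask, vd, thickness))
    df = pd.DataFrame([asdict(r) for r in rows])
    df.insert(0, "eye_id", eye_id)
    return df


def write_metrics(df: pd.DataFrame, csv_path: str | Path) -> None:
    """Write the metrics table as CSV with a JSON mirror alongside."""
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, default=float))
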