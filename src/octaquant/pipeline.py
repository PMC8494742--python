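"""End-to-end orchestration: phantom → decode → segment → algebra → metrics →
register → RIRT, and the cohort statistical report.

Each run writes its artifacts plus a JSON report carrying the seed, per-stage
SHA-256 checksums of the key arrays, and every derived number, so any value
in the report is traceable to exactly one stage output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import colormap, masks as mask_ops, metrics as metrics_mod
from .exceptions import OctaquantError
from .images import RegionMask, save_mask, save_scalar_map
from .registration import fit_affine, warp_map
from .rirt import analyze_rirt, render_contour_plot
from .segmentation import CongestionParams, detect_congestion
from .stats import (compare_groups, logistic_fit, or_derivations,
                    recurrence_percentage, select_univariate_terms)
from .synthetic import (CohortSimConfig, PhantomConfig, generate_phantom_case,
                        simulate_cohort, write_case)
from .metrics import write_metrics

log = logging.getLogger("octaquant.pipeline")


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _stage(report: dict, name: str, t0: float, **payload) -> None:
    report["stages"][name] = {"duration_s": round(time.time() - t0, 3),
                              **payload}
    log.info("stage %-12s done in %.2fs", name, time.time() - t0)


@dataclass
class RunConfig:
    """Configuration of one end-to-end case run."""

    outdir: str = "octaquant_run"
    seed: int = 0
    phantom: dict = field(default_factory=dict)        # PhantomConfig overrides
    congestion: dict = field(default_factory=dict)     # CongestionParams overrides
    with_followup: bool = True
    render: bool = False


def run_case(config: RunConfig) -> dict:
    """Execute the full single-case pipeline on a phantom; returns the report.

    Stages: phantom generation, colormap encode/decode round trip of the
    thickness and VD maps, congestion detection on the deep plexus, mask
    algebra (normal regions, TZ, DCP-C partition), region metrics, and —
    when a follow-up visit is present — control-point registration and RIRT
    territory mapping.  Deterministic for a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # phantom ---------------------------------------------------------------
    t0 = time.time()
    pcfg = PhantomConfig(seed=config.seed, **config.phantom)
    case = generate_phantom_case(pcfg)
    write_case(case, outdir / "case")
    _stage(report, "phantom", t0,
           checksum_dcp=_checksum(case.dcp.pixels),
           checksum_scp=_checksum(case.scp.pixels))

    # colormap round trip (device-style export → decoded scalars) -----------
    t0 = time.time()
    th_lut = colormap.default_thickness_lut()
    vd_lut = colormap.default_vd_lut()
    th_color = colormap.encode_scalar_map(case.thickness_baseline, th_lut)
    thickness = colormap.decode_color_map(th_color, th_lut,
                                          pixel_pitch_um=pcfg.pixel_pitch_um)
    vd_color = colormap.encode_scalar_map(case.vd_dcp, vd_lut)
    vd_dcp = colormap.decode_color_map(vd_color, vd_lut,
                                       pixel_pitch_um=pcfg.pixel_pitch_um)
    vd_scp_color = colormap.encode_scalar_map(case.vd_scp, vd_lut)
    vd_scp = colormap.decode_color_map(vd_scp_color, vd_lut,
                                       pixel_pitch_um=pcfg.pixel_pitch_um)
    max_roundtrip_err = float(np.nanmax(np.abs(
        thickness.values - np.clip(case.thickness_baseline.values,
                                   *th_lut.scalar_range))))
    _stage(report, "decode", t0,
           checksum_thickness=_checksum(thickness.values),
           max_roundtrip_err_um=max_roundtrip_err,
           quantization_step_um=th_lut.quantization_step)

    # congestion detection ---------------------------------------------------
    t0 = time.time()
    params = CongestionParams(**config.congestion)
    truth_masks = case.truth.masks
    dcp_c_det = detect_congestion(case.dcp, truth_masks["DCP-A"],
                                  truth_masks["DCP-FAZ"], params)
    save_mask(dcp_c_det, outdir / "dcp_c_detected.png")
    gt = truth_masks["DCP-C"].pixels
    det = dcp_c_det.pixels
    union = int((gt | det).sum())
    iou = (gt & det).sum() / union if union else math.nan
    _stage(report, "segment", t0, checksum=_checksum(det),
           iou_vs_truth=float(iou))

    # mask algebra ----------------------------------------------------------
    t0 = time.time()
    scp_n = mask_ops.normal_region(truth_masks["SCP-A"], truth_masks["SCP-FAZ"])
    tz = mask_ops.transitional_zone(scp_n, truth_masks["DCP-A"])
    part = mask_ops.partition_dcp_congestion(dcp_c_det, tz,
                                             truth_masks["SCP-A"],
                                             truth_masks["DCP-A"])
    _stage(report, "algebra", t0, checksum_tz=_checksum(tz.pixels),
           dcp_c_in_tz_px=part.in_tz.count(),
           dcp_c_under_scp_a_px=part.under_scp_a.count(),
           residual_fraction=part.residual_fraction)

    # metrics ----------------------------------------------------------------
    t0 = time.time()
    all_masks = dict(truth_masks)
    all_masks["DCP-C"] = dcp_c_det
    all_masks["TZ"] = tz
    all_masks["DCP-C-in-TZ"] = part.in_tz
    all_masks["DCP-C-under-SCP-A"] = part.under_scp_a
    table = metrics_mod.metrics_table(all_masks, thickness=thickness,
                                      vd_scp=vd_scp, vd_dcp=vd_dcp,
                                      eye_id=f"phantom-{config.seed}")
    write_metrics(table, outdir / "metrics.csv")
    dcp_c_row = table[table.region == "DCP-C"].iloc[0]
    _stage(report, "metrics", t0,
           dcp_c_mrt_um=float(dcp_c_row.mrt_um),
           dcp_c_area_mm2=float(dcp_c_row.area_mm2),
           dcp_c_vd_pct=float(dcp_c_row.mean_vd_pct))

    # registration + RIRT ----------------------------------------------------
    if config.with_followup:
        t0 = time.time()
        transform = fit_affine(case.control_points)
        transform.to_json(outdir / "affine.json")
        warped, overlap = warp_map(case.thickness_followup, transform)
        save_scalar_map(
            type(warped)(np.nan_to_num(warped.values), units=warped.units,
                         pixel_pitch_um=warped.pixel_pitch_um),
            outdir / "thickness_followup_warped.png")
        _stage(report, "register", t0,
               rms_residual_px=transform.rms_residual_px,
               max_affine_err=float(np.abs(
                   transform.matrix - case.truth.true_affine.matrix).max()))

        t0 = time.time()
        result = analyze_rirt(case.thickness_baseline, warped,
                              dcp_c=dcp_c_det,
                              faz=truth_masks["DCP-FAZ"],
                              abnormal=truth_masks["DCP-A"],
                              overlap=overlap)
        import tifffile
        tifffile.imwrite(outdir / "rirt.tif",
                         result.rirt_map.astype(np.float32))
        save_mask(RegionMask("ME-territory", result.territory,
                             pixel_pitch_um=pcfg.pixel_pitch_um),
                  outdir / "me_territory.png")
        rirt_json = {
            "threshold": result.threshold,
            "smoothing_sigma_px": result.smoothing_sigma_px,
            "territory_px": int(result.territory.sum()),
            "apexes": [asdict(a) for a in result.apexes],
            "summary": asdict(result.summary),
        }
        (outdir / "rirt.json").write_text(
            json.dumps(rirt_json, indent=2, default=float))
        if config.render:
            render_contour_plot(result, dcp_c_det, outdir / "contours.png")
        _stage(report, "rirt", t0, checksum=_checksum(result.territory),
               **{k: v for k, v in rirt_json.items() if k != "apexes"})

    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=float))
    return report


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------

#: candidate covariates screened for the multivariate recurrence model
CANDIDATE_TERMS = ["age", "period_to_baseline_months", "n_injections_total",
                   "n_anti_vegf", "n_steroid", "dcp_c_mrt_um"]

#: numeric covariates compared between outcome groups (Mann-Whitney U)
NUMERIC_COMPARISONS = ["age", "bcva_logmar", "csmt_um",
                       "period_to_baseline_months", "n_injections_total",
                       "dcp_c_mrt_um"]


def run_cohort(table: pd.DataFrame | None = None,
               sim_config: CohortSimConfig | None = None,
               outdir: str | Path = "octaquant_cohort",
               alpha: float = 0.05,
               candidates: list[str] | None = None) -> dict:
    """Cohort statistical report: group comparisons, logistic model, ORs.

    Provide either an existing per-eye ``table`` or a simulation config.
    The multivariate model takes the terms passing univariate screening at
    ``alpha`` (the rule is recorded in the report).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = simulate_cohort(sim_config or CohortSimConfig())
    missing = [c for c in ("recurrent",) if c not in table.columns]
    if missing:
        raise OctaquantError(f"cohort table lacks columns: {missing}")
    table = table.copy()
    table["recurrent"] = table["recurrent"].astype(int)
    if table["recurrent"].nunique() < 2:
        raise OctaquantError("grouping variable 'recurrent' has a single level")
    table.to_csv(outdir / "cohort.csv", index=False)

    report: dict = {"n_eyes": int(len(table)),
                    "recurrence_pct": recurrence_percentage(table)}
    comparisons = {}
    for var in NUMERIC_COMPARISONS:
        if var in table.columns:
            cmp = compare_groups(table, var, "recurrent", "mann_whitney")
            comparisons[var] = {"test": cmp.test, "statistic": cmp.statistic,
                                "p": cmp.p_value}
    report["group_comparisons"] = comparisons

    candidates = [t for t in (candidates or CANDIDATE_TERMS)
                  if t in table.columns]
    uni = logistic_fit(table, "recurrent", candidates, mode="univariate")
    report["univariate"] = {
        t: {"or": fit.terms[0].odds_ratio,
            "ci": [fit.terms[0].ci_low, fit.terms[0].ci_high],
            "p": fit.terms[0].p_value,
            "converged": fit.converged}
        for t, fit in uni.items()}
    selected = select_univariate_terms(table, "recurrent", candidates,
                                       alpha=alpha)
    # the total injection count is the sum of the anti-VEGF and steroid
    # counts; keep the total (the final model's term) and drop the parts
    if "n_injections_total" in selected:
        selected = [t for t in selected
                    if t not in ("n_anti_vegf", "n_steroid")]
    report["term_selection_rule"] = (
        f"univariate p < {alpha}; injection subtotals folded into the total")
    report["selected_terms"] = selected
    if selected:
        multi = logistic_fit(table, "recurrent", selected, mode="multivariate")
        report["multivariate"] = {
            t.term: {"or": t.odds_ratio, "ci": [t.ci_low, t.ci_high],
                     "p": t.p_value}
            for t in multi.terms}
        report["multivariate_converged"] = multi.converged
        derivations = {}
        for t in multi.terms:
            if t.odds_ratio > 1.0:
                d = or_derivations(t.odds_ratio)
                derivations[t.term] = {
                    "pct_increase_per_unit": d.pct_increase_per_unit,
                    "doubling_units": d.doubling_units}
        report["or_derivations"] = derivations
    (outdir / "cohort_report.json").write_text(
        json.dumps(report, indent=2, default=float))
    return report
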