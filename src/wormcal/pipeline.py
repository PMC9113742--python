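"""Stage orchestration: run each analysis on files or fully synthetic inputs.

The ``demo`` entry point generates every synthetic modality under one global
seed, runs every downstream stage, and writes a machine-readable JSON report
of recovered-versus-true parameters — the same parameter-recovery contract
the test suite enforces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import conservation as cons
from . import kymograph as kymo
from . import leak as leakmod
from . import segment as seg
from . import stats as st
from . import survival as surv
from . import synth
from .config import PipelineConfig

__all__ = ["run_video_pipeline", "run_demo"]


def run_video_pipeline(video: synth.VideoStack, cfg: PipelineConfig,
                       t_caffeine: float | None = None) -> dict:
    """Segment, register, kymograph, normalise and detect on one video.

    Returns a dict with the contour sequence, kymograph, ΔF/F0 grid,
    transient set, peak summary and (if ``t_caffeine``) caffeine response.
    """
    contours = [
        seg.extract_contour(seg.segment_frame(frame, cfg.segmentation), i,
                            cfg.segmentation)
        for i, frame in enumerate(video.frames)
    ]
    sequence = seg.register_contours(contours)
    k = kymo.build_kymograph(video, sequence, band_width=cfg.kymograph.band_width,
                             inset=cfg.kymograph.inset)
    dff, f0 = kymo.compute_dff(k, f0_method=cfg.kymograph.f0_method,
                               percentile=cfg.kymograph.f0_percentile,
                               detrend=cfg.kymograph.detrend)
    transients = kymo.detect_transients(
        dff, f0, k.frame_interval,
        k_thresh=cfg.kymograph.k_thresh,
        min_duration=cfg.kymograph.min_duration,
        merge_radius=cfg.kymograph.merge_radius,
        merge_gap=cfg.kymograph.merge_gap,
        min_amplitude=cfg.kymograph.min_amplitude,
    )
    out = {
        "contours": sequence,
        "kymograph": k,
        "dff": dff,
        "f0": f0,
        "transients": transients,
        "peak_summary": kymo.average_peak(transients),
        "recording_max": kymo.recording_max(dff),
    }
    if t_caffeine is not None:
        out["caffeine"] = kymo.caffeine_response(
            dff, k.frame_interval, t_caffeine,
            window=cfg.kymograph.caffeine_window,
            k_thresh=cfg.kymograph.caffeine_k_thresh,
        )
    return out


def _demo_video(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    params = cfg.video
    params.seed = cfg.seed
    video, gt = synth.gen_worm_video(params)
    synth.write_video_dataset(video, gt, outdir / "video")
    res = run_video_pipeline(video, cfg)
    res["kymograph"].to_tiff(outdir / "kymograph.tif")
    res["transients"].to_frame().to_csv(outdir / "transients.csv", index=False)
    peak = res["peak_summary"]
    report["calcium_transients"] = {
        "true_amplitude": params.transient_amplitude,
        "recovered_mean_peak": peak.mean_peak,
        "n_true_events": len(gt.event_times),
        "n_detected_events": peak.n_events,
        "recording_max_dff": res["recording_max"],
    }


def _demo_caffeine(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    params = synth.WormVideoParams(
        **{**_params_dict(cfg.video), "duration": 15.0, "transient_rate": 0.0,
           "caffeine_time": 5.0, "seed": cfg.seed + 1}
    )
    video, _ = synth.gen_worm_video(params)
    res = run_video_pipeline(video, cfg, t_caffeine=5.0)
    caff = res["caffeine"]
    report["caffeine_response"] = {
        "responder": caff.responder,
        "latency_s": caff.latency,
        "peak_post_dff": caff.peak_post,
        "baseline_dff": caff.baseline,
    }


def _params_dict(params: synth.WormVideoParams) -> dict:
    import dataclasses

    return dataclasses.asdict(params)


def _demo_leak(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    fits = {}
    for grp, slope, off in (("WT", 2.0, 0), ("KO", 4.0, 100)):
        group_fits = []
        for rep in range(3):
            trace, gt = synth.gen_leak_trace(
                s_leak=slope, noise_sd=5.0, seed=cfg.seed + off + rep)
            group_fits.append(leakmod.fit_leak(
                trace, leakmod.segment_phases(trace, settle=cfg.leak.settle,
                                              tol_frac=cfg.leak.tol_frac)))
        fits[grp] = (group_fits, gt)
    comparison = leakmod.compare_leak(fits["WT"][0], fits["KO"][0])
    report["leak_assay"] = {
        "true_normalized_leak_wt": fits["WT"][1].scalars["normalized_leak"],
        "true_normalized_leak_ko": fits["KO"][1].scalars["normalized_leak"],
        "recovered_wt": float(np.mean([f.normalized_leak for f in fits["WT"][0]])),
        "recovered_ko": float(np.mean([f.normalized_leak for f in fits["KO"][0]])),
        "comparison": comparison,
    }


def _demo_behavior(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    wt, gt_wt = synth.gen_behavior_events(bend_rate=60, curl_prob=0.1,
                                          group="WT", seed=cfg.seed + 10)
    ko, gt_ko = synth.gen_behavior_events(bend_rate=40, curl_prob=0.3,
                                          group="KO", seed=cfg.seed + 11)
    table = pd.concat([wt, ko], ignore_index=True)
    table.to_csv(outdir / "behavior.csv", index=False)
    res = beh.group_behavior(table, value="curl_pct", alpha=cfg.stats.alpha)
    report["behavior"] = {
        "true_curl_pct": {"WT": 100 * gt_wt.scalars["curl_prob"],
                          "KO": 100 * gt_ko.scalars["curl_prob"]},
        "recovered": {g: s["mean"] for g, s in res["groups"].items()},
        "p_value": res["test"]["p_value"],
    }


def _demo_survival(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    wt, _ = synth.gen_survival_cohort(scale=20.0, group="WT", seed=cfg.seed + 20)
    ko, _ = synth.gen_survival_cohort(scale=15.5, group="KO", seed=cfg.seed + 21)
    cohort = pd.concat([wt, ko], ignore_index=True)
    cohort.to_csv(outdir / "survival.csv", index=False)
    surv.survival_curve(cohort, "WT").to_csv(outdir / "survival_curve_wt.csv", index=False)
    surv.survival_curve(cohort, "KO").to_csv(outdir / "survival_curve_ko.csv", index=False)
    res = surv.gehan_breslow_wilcoxon(cohort, "WT", "KO",
                                      method=cfg.survival.method,
                                      n_perm=cfg.survival.n_perm,
                                      seed=cfg.seed)
    report["survival"] = {
        "mean_lifespan_wt": surv.mean_survival(cohort, "WT")["mean"],
        "mean_lifespan_ko": surv.mean_survival(cohort, "KO")["mean"],
        "gbw_statistic": res.statistic,
        "gbw_p": res.p_value,
    }


def _demo_densitometry(cfg: PipelineConfig, outdir: Path, report: dict) -> None:
    table, gt = synth.gen_densitometry(group_means={"WT": 1.0, "KO": 0.3},
                                       seed=cfg.seed + 30)
    table = st.band_ratio_table(table, log=cfg.stats.log_ratio)
    table.to_csv(outdir / "densitometry.csv", index=False)
    wt = table.loc[table["group"] == "WT", "ratio"]
    ko = table.loc[table["group"] == "KO", "ratio"]
    t, p = st.t_test(wt, ko)
    report["densitometry"] = {
        "true_means": gt.scalars["group_means"],
        "recovered_means": {"WT": float(wt.mean()), "KO": float(ko.mean())},
        "t": t,
        "p_value": p,
    }


def run_demo(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Generate all synthetic modalities, run every stage, write report.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    for stage in (_demo_video, _demo_caffeine, _demo_leak, _demo_behavior,
                  _demo_survival, _demo_densitometry):
        stage(cfg, outdir, report)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
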