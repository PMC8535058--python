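"""Study orchestration: specimen processing, summary table, statistics.

`run_specimen` turns one (volume, mask) pair into tidy rows of
(specimen, configuration, ROI, metric, value): ligament length, per-ROI
T2 summary statistics, texture features for the ligament and its
subregions, and insertion-box T2 summaries. `run_study` aggregates a
paired cohort, runs the statistical battery (paired t-test on length,
Wilcoxon signed-rank per ROI x metric, Friedman + Dunn across the
subregions per configuration), and optionally writes report CSVs in the
layout of the study's summary tables plus per-specimen unloaded/loaded
T2 histogram overlays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    InsertionSite,
    central_pcl_slice,
    compute_centerline,
    measure_length,
    partition_subregions,
    place_insertion_box,
)
from .io import Configuration, LabelMask, MultiEchoVolume
from .phantom import SpecimenData
from .relaxometry import FitConfig, fit_t2_pixelwise, summarize_roi
from .stats import ALPHA_DEFAULT, friedman_dunn, paired_ttest, wilcoxon_paired
from .texture import GlcmConfig, accumulate_glcm, texture_features

__all__ = ["PipelineConfig", "StudyResult", "run_specimen", "run_study"]

SUBREGION_ROIS = ("PR", "CR", "DR")
OPTIONAL_ROIS = ("ACL", "MENISCUS_AM", "MENISCUS_PM", "MENISCUS_AL", "MENISCUS_PL")


@dataclass
class PipelineConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    alpha: float = ALPHA_DEFAULT
    hist_range: tuple[float, float] = (0.0, 80.0)
    hist_bin_width: float = 1.0
    subregion_boundaries: tuple[float, float] = (0.25, 0.75)
    include_texture: bool = True
    include_insertion: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "fit" in d:
            cfg.fit = FitConfig(**d["fit"])
        if "glcm" in d:
            cfg.glcm = GlcmConfig(**d["glcm"])
        for key in ("alpha", "include_texture", "include_insertion", "hist_bin_width"):
            if key in d:
                setattr(cfg, key, d[key])
        return cfg


def _summary_rows(rows: list, sid: str, cfg_name: str, roi: str, summary) -> None:
    rows.append((sid, cfg_name, roi, "t2_mean", summary.mean))
    rows.append((sid, cfg_name, roi, "t2_sd", summary.sd))
    rows.append((sid, cfg_name, roi, "t2_median", summary.median))
    rows.append((sid, cfg_name, roi, "n_valid", float(summary.n_valid)))


def run_specimen(
    volume: MultiEchoVolume,
    mask: LabelMask,
    cfg: PipelineConfig | None = None,
    with_histogram: bool = False,
):
    """Process one acquisition into tidy StudyTable rows.

    Requires the PCL label; other structures are summarized when present
    and silently omitted otherwise. Only valid-fit voxels contribute to
    any statistic. With ``with_histogram`` also returns the entire-PCL
    T2 histogram ``(counts, edges)``.
    """
    cfg = cfg or PipelineConfig()
    sid = volume.specimen_id or "specimen"
    cfg_name = volume.configuration.value
    pcl = mask.mask_for("PCL")
    if not pcl.any():
        raise ValueError(
            f"PCL label missing from mask; found structures: {mask.structures_present()}"
        )
    spacing = volume.voxel_spacing

    # fit only voxels a downstream ROI can touch
    fit_roi = mask.labels > 0 if cfg.include_insertion else pcl.copy()
    if not cfg.include_insertion:
        for name in OPTIONAL_ROIS:
            fit_roi |= mask.mask_for(name)
    t2map = fit_t2_pixelwise(volume, fit_roi, cfg.fit)

    femur = mask.mask_for("FEMUR")
    prox_ref = None
    if femur.any():
        prox_ref = np.argwhere(femur).mean(axis=0) * np.asarray(spacing)
    cl = compute_centerline(pcl, spacing, proximal_reference=prox_ref)
    part = partition_subregions(pcl, cl, spacing, cfg.subregion_boundaries)

    rows: list = []
    rows.append((sid, cfg_name, "PCL_ENTIRE", "length_mm", measure_length(cl)))

    roi_masks: dict[str, np.ndarray] = {"PCL_ENTIRE": pcl}
    for name in SUBREGION_ROIS:
        roi_masks[name] = part.mask_for(name)
    for name in OPTIONAL_ROIS:
        m = mask.mask_for(name)
        if m.any():
            roi_masks[name] = m

    histogram = None
    for name, roi in roi_masks.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_roi(t2map, roi, cfg.hist_range, cfg.hist_bin_width)
        _summary_rows(rows, sid, cfg_name, name, s)
        if name == "PCL_ENTIRE":
            histogram = (s.hist_counts, s.hist_edges)
        if cfg.include_texture and name in ("PCL_ENTIRE",) + SUBREGION_ROIS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc = accumulate_glcm(t2map, roi, cfg.glcm)
            if not acc.empty:
                for metric, value in texture_features(acc, cfg.glcm.log_base).as_dict().items():
                    rows.append((sid, cfg_name, name, metric, value))

    if cfg.include_insertion:
        slice_idx = central_pcl_slice(pcl)
        for site, bone_name, roi_name in (
            (InsertionSite.FEMORAL, "FEMUR", "FEM_INSERTION"),
            (InsertionSite.TIBIAL, "TIBIA", "TIB_INSERTION"),
        ):
            bone = mask.mask_for(bone_name)
            if not bone.any():
                continue
            box = place_insertion_box(pcl, bone, site, spacing,
                                      slice_index=slice_idx, centerline=cl)
            enclosed = box.enclosed_mask(pcl.shape, spacing)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = summarize_roi(t2map, enclosed, cfg.hist_range, cfg.hist_bin_width)
            _summary_rows(rows, sid, cfg_name, roi_name, s)

    df = pd.DataFrame(rows, columns=["specimen_id", "configuration", "roi", "metric", "value"])
    if with_histogram:
        return df, histogram
    return df


@dataclass
class StudyResult:
    table: pd.DataFrame        # tidy per-specimen rows
    stats: pd.DataFrame        # one row per statistical comparison
    histograms: dict           # specimen -> {config -> (counts, edges)}

    def pivot_means(self) -> pd.DataFrame:
        """Cohort mean +/- SD per (roi, metric, configuration)."""
        g = self.table.groupby(["roi", "metric", "configuration"])["value"]
        out = g.agg(["mean", "std", "median", "count"]).reset_index()
        return out


def _stats_battery(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    wide = table.pivot_table(index=["specimen_id", "roi", "metric"],
                             columns="configuration", values="value").reset_index()
    recs: list[dict] = []

    # paired t on length
    lg = wide[(wide.roi == "PCL_ENTIRE") & (wide.metric == "length_mm")].dropna()
    if len(lg) >= 2:
        r = paired_ttest(lg["d0"].to_numpy(), lg["d1"].to_numpy(), alpha)
        recs.append({"test": "paired_t", "roi": "PCL_ENTIRE", "metric": "length_mm",
                     "configuration": "d1-d0", "statistic": r.statistic,
                     "p_value": r.p_value, "n": r.n, "significant": r.significant})

    # Wilcoxon per roi x metric (T2 summaries and texture)
    for (roi, metric), grp in wide.groupby(["roi", "metric"]):
        if metric in ("length_mm", "n_valid", "t2_median"):
            continue
        grp = grp.dropna(subset=["d0", "d1"])
        if len(grp) < 5:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = wilcoxon_paired(grp["d0"].to_numpy(), grp["d1"].to_numpy(), alpha)
        recs.append({"test": "wilcoxon", "roi": roi, "metric": metric,
                     "configuration": "d1-d0", "statistic": r.statistic,
                     "p_value": r.p_value, "n": r.n, "significant": r.significant})

    # Friedman + Dunn across subregions, per configuration and metric
    sub = table[table.roi.isin(SUBREGION_ROIS)]
    for (config, metric), grp in sub.groupby(["configuration", "metric"]):
        if metric in ("length_mm", "n_valid", "t2_median"):
            continue
        blocks = grp.pivot_table(index="specimen_id", columns="roi", values="value")
        blocks = blocks.reindex(columns=list(SUBREGION_ROIS)).dropna()
        if len(blocks) < 2:
            continue
        overall, pairwise = friedman_dunn(blocks.to_numpy(), SUBREGION_ROIS, alpha)
        recs.append({"test": "friedman", "roi": "PR/CR/DR", "metric": metric,
                     "configuration": config, "statistic": overall.statistic,
                     "p_value": overall.p_value, "n": overall.n,
                     "significant": overall.significant})
        for dr in pairwise:
            recs.append({"test": "dunn", "roi": f"{dr.pair[0]} vs {dr.pair[1]}",
                         "metric": metric, "configuration": config,
                         "statistic": dr.z, "p_value": dr.p_bonferroni,
                         "n": overall.n, "significant": dr.p_bonferroni <= alpha,
                         "p_uncorrected": dr.p_uncorrected})
    return pd.DataFrame.from_records(recs)


def run_study(
    specimens: list[SpecimenData],
    cfg: PipelineConfig | None = None,
    out_dir: Path | str | None = None,
) -> StudyResult:
    """Run the full paired analysis over an in-memory cohort.

    Validates pairing up front, processes every acquisition, runs the
    statistics, and (with ``out_dir``) writes the tidy table, cohort
    summary, statistics CSVs and per-specimen histogram overlays.
    """
    cfg = cfg or PipelineConfig()
    if not specimens:
        raise ValueError("empty cohort")
    for s in specimens:
        if s.d0 is None or s.d1 is None:
            raise ValueError(f"specimen {s.specimen_id} is not paired")

    frames = []
    histograms: dict = {}
    for s in specimens:
        histograms[s.specimen_id] = {}
        for cfg_name, (vol, msk, _gt) in (("d0", s.d0), ("d1", s.d1)):
            df, hist = run_specimen(vol, msk, cfg, with_histogram=True)
            frames.append(df)
            histograms[s.specimen_id][cfg_name] = hist
    table = pd.concat(frames, ignore_index=True)
    stats = _stats_battery(table, cfg.alpha)
    result = StudyResult(table=table, stats=stats, histograms=histograms)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "study_table.csv", index=False)
        stats.to_csv(out / "statistics.csv", index=False)
        result.pivot_means().to_csv(out / "cohort_summary.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(
            {"alpha": cfg.alpha, "r2_threshold": cfg.fit.r2_threshold,
             "n_specimens": len(specimens)}, indent=1))
        _write_histograms(histograms, out)
    return result


def _write_histograms(histograms: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "histograms"
    fig_dir.mkdir(exist_ok=True)
    for sid, configs in histograms.items():
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for cfg_name, (counts, edges) in configs.items():
            centers = (edges[:-1] + edges[1:]) / 2
            label = "unloaded (d0)" if cfg_name == "d0" else "loaded (d1)"
            ax.step(centers, counts, where="mid", label=label)
        ax.set_xlabel("T2 (ms)")
        ax.set_ylabel("pixel count")
        ax.set_title(f"{sid}: PCL T2 distribution")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(fig_dir / f"{sid}_t2_hist.png", dpi=120)
        plt.close(fig)
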