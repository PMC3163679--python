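"""End-to-end pipeline: simulate → normalize → fit → integrate → … → report.

Each stage can be toggled; downstream stages that need a disabled
stage's output refuse with a clear error.  The report is a plain JSON
object of per-stage counts and statistics so reruns with the same seed
are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import array_processing as ap
from . import decay_kinetics as dk
from . import enrichment as en
from . import integration as it
from . import motif_scan as ms
from . import mpv_compare as mc
from . import synthetic_data as sd
from . import io as dio

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "fit", "call_guts", "integrate",
              "enrich", "scan_motifs", "compare_mpv")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ALL_STAGES
    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    filter: ap.FilterConfig = field(default_factory=ap.FilterConfig)
    design_mode: str = "per-timepoint-reference"
    # synthetic slides are already on a common scale; "median" is for
    # real data with per-array channel imbalance
    normalize_method: str = "none"
    gut_threshold_min: float = dk.GUT_THRESHOLD_MIN
    ln2_constant: float = dk.LN2_ROUNDED
    mpv_alpha: float = 0.05
    max_mpv_genes: int = 100   # cap on per-gene qPCR contrasts in one run
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.gut_threshold_min <= 0:
            raise ValueError("gut_threshold_min must be positive")


def _require(report: dict, stage: str, needed: str) -> None:
    if needed not in report:
        raise RuntimeError(
            f"stage '{stage}' needs output of disabled stage '{needed}'")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages in order and return the JSON-able report."""
    report: dict = {"seed": config.simulation.seed, "stages_run": []}
    state: dict = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](config, state, report)
        report["stages_run"].append(stage)
        report.setdefault("timings_s", {})[stage] = round(
            time.perf_counter() - t0, 3)
        log.info("stage %-12s done in %.2fs", stage,
                 time.perf_counter() - t0)

    if outdir:
        manifest = {}
        if "dataset" in state and "simulate" in config.stages:
            manifest = {k: str(v) for k, v in
                        sd.write_dataset(state["dataset"], outdir).items()}
        if "fits" in state:
            p = outdir / "fits.tsv"
            dio.write_tsv(state["fits"], p)
            manifest["fits"] = str(p)
        report["files"] = manifest
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _stage_simulate(config, state, report):
    dataset = sd.simulate(config.simulation)
    state["dataset"] = dataset
    state["genes"] = dataset.genes
    report["simulate"] = {
        "n_genes": len(dataset.genes),
        "n_unstable_true": sum(g.is_unstable for g in dataset.genes),
        "n_nonadditive_true": sum(g.nonadditive for g in dataset.genes),
        "n_spot_rows": int(len(dataset.spot_table)),
    }


def _stage_normalize(config, state, report):
    _require(report, "normalize", "simulate")
    obs = ap.normalize_arrays(state["dataset"].spot_table,
                              method=config.normalize_method)
    changes = ap.temporal_ratios(obs, mode=config.design_mode)
    # significance from all replicate slides pooled; the fold-change
    # reproducibility rule is applied per biological dataset
    pooled = ap.summarize_genes_fast(changes, config.filter)
    pooled_p = pooled.set_index(["gene_id", "timepoint_min"])["p"]
    summaries = []
    import math as _math

    for _, grp in changes.groupby("bio_rep"):
        s = ap.summarize_genes_fast(grp, config.filter)
        p = pooled_p.reindex(
            pd.MultiIndex.from_frame(s[["gene_id", "timepoint_min"]])
        ).to_numpy()
        s["p"] = p
        s["passed"] = (p <= config.filter.alpha) & (
            s["mean_log2_ratio"].abs() >= _math.log2(config.filter.min_fold))
        summaries.append(s)
    state["changes"] = changes
    state["summaries"] = summaries
    retained = ap.filter_reproducible(summaries, config.filter)
    state["retained"] = retained
    report["normalize"] = {
        "n_observations": int(len(obs)),
        "n_datasets": len(summaries),
        "n_retained_genes": int(retained["gene_id"].nunique()),
    }


def _stage_fit(config, state, report):
    _require(report, "fit", "normalize")
    changes = state["changes"]
    mean_changes = (changes.groupby(["gene_id", "timepoint_min"], sort=True)
                    ["log2_change"].mean().reset_index())
    mean_changes["ratio"] = 2.0 ** mean_changes["log2_change"]
    t0 = mean_changes[["gene_id"]].drop_duplicates()
    t0["timepoint_min"] = 0.0
    t0["ratio"] = 1.0
    ratios = pd.concat([t0, mean_changes[["gene_id", "timepoint_min", "ratio"]]],
                       ignore_index=True)
    fits = dk.fit_many(ratios, ln2_constant=config.ln2_constant)
    state["fits_frame"] = fits
    n_cens = int(fits["censored"].sum())
    finite = fits.loc[~fits["censored"], "t_half_min"]
    report["fit"] = {
        "n_fits": int(len(fits)),
        "n_censored": n_cens,
        "median_t_half_min": float(finite.median()) if len(finite) else None,
    }


def _stage_call_guts(config, state, report):
    _require(report, "call_guts", "fit")
    fits = state["fits_frame"]
    calls = dk.call_guts(fits, config.gut_threshold_min)
    guts = sorted(c.gene_id for c in calls if c.is_gut)
    # genome-wide discovery additionally requires the reproducibility filter
    if "retained" in state:
        retained_ids = set(state["retained"]["gene_id"])
        filtered_guts = sorted(set(guts) & retained_ids)
    else:
        filtered_guts = guts
    fits = fits.assign(is_gut=[c.is_gut for c in calls])
    state["fits"] = fits
    state["guts"] = guts
    state["filtered_guts"] = filtered_guts
    report["call_guts"] = {
        "threshold_min": config.gut_threshold_min,
        "n_guts": len(guts),
        "n_guts_after_filter": len(filtered_guts),
    }


def _stage_integrate(config, state, report):
    _require(report, "integrate", "call_guts")
    genes = state["genes"]
    universe = [g.gene_id for g in genes]
    nonadd = [g.gene_id for g in genes if g.nonadditive]
    overlap = it.intersect_gene_sets(state["guts"], nonadd, universe)
    entry = {
        "n_overlap": overlap.n_overlap,
        "n_guts": overlap.n_set_a,
        "n_nonadditive": overlap.n_set_b,
        "chi_square": None,
        "chi_square_p": None,
        "spearman_rho": None,
        "spearman_p": None,
    }
    if min(overlap.n_set_a, overlap.n_set_b) > 0 and \
            max(overlap.n_set_a, overlap.n_set_b) < overlap.n_universe:
        assoc = it.chi_square_association(overlap)
        entry["chi_square"] = round(assoc.chi_square, 3)
        entry["chi_square_p"] = assoc.p_value
    else:
        log.warning("degenerate GUT/nonadditive sets; association skipped")
    expr = {g.gene_id: g.expression_log2_ratio for g in genes}
    fits = state["fits"]
    k = fits.loc[~fits["censored"]].set_index("gene_id")["k_per_min"]
    gut_k = k[k.index.isin(state["guts"])]
    if len(gut_k) >= 3 and gut_k.nunique() > 1:
        corr = it.correlate_expression_decay(
            pd.Series(expr), gut_k, method="spearman")
        entry["spearman_rho"] = round(corr.rho, 4)
        entry["spearman_p"] = corr.p_value
    report["integrate"] = entry
    state["overlap"] = overlap


def _stage_enrich(config, state, report):
    _require(report, "enrich", "call_guts")
    genes = state["genes"]
    ann = en.CategoryAnnotation(
        {g.gene_id: g.categories for g in genes if g.categories},
        background_size=len(genes),
    )
    rows = en.fold_enrichment(state["guts"], ann) if state["guts"] else []
    report["enrich"] = {
        "n_categories": len(rows),
        "top": [
            {"category": r.category, "fold": round(r.fold, 3)}
            for r in rows[:5]
        ],
    }
    state["enrichment"] = rows


def _stage_scan_motifs(config, state, report):
    _require(report, "scan_motifs", "call_guts")
    genes = state["genes"]
    target = state["overlap"].members_overlap if "overlap" in state else state["guts"]
    promoters = {g.gene_id: g.promoter for g in genes
                 if g.gene_id in set(target)}
    if not promoters:
        report["scan_motifs"] = {"n_genes": 0, "n_with_hit": 0,
                                 "fraction": None}
        return
    hits = ms.scan_promoters(promoters)
    n_hit, frac = ms.summarize_presence(hits, promoters)
    report["scan_motifs"] = {
        "n_genes": len(promoters),
        "n_with_hit": n_hit,
        "fraction": round(frac, 4),
    }


def _stage_compare_mpv(config, state, report):
    _require(report, "compare_mpv", "call_guts")
    dataset = state["dataset"]
    target = list(state["overlap"].members_overlap) if "overlap" in state \
        else state["guts"]
    target = target[: config.max_mpv_genes]
    if not target:
        report["compare_mpv"] = {"n_tested": 0, "n_faster_in_allo": 0}
        return
    table = mc.compare_gene_table(
        dataset.qpcr_table, target, alpha=config.mpv_alpha,
        ln2_constant=config.ln2_constant)
    report["compare_mpv"] = {
        "n_tested": int(len(table)),
        "n_faster_in_allo": int(table["faster_in_allo"].sum()),
        "alpha": config.mpv_alpha,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "fit": _stage_fit,
    "call_guts": _stage_call_guts,
    "integrate": _stage_integrate,
    "enrich": _stage_enrich,
    "scan_motifs": _stage_scan_motifs,
    "compare_mpv": _stage_compare_mpv,
}
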