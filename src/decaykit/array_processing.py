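"""Two-channel array normalization, replicate testing and filtering.

A "slide" is one (bio_rep, tech_rep, timepoint) hybridization with a
sample-dye and a reference-dye channel.  Channel labels follow the
dyes; by convention even-numbered technical replicates are dye swaps
(the biological materials trade channels), so their log2 ratios are
sign-flipped before aggregation, which cancels additive dye bias.

Normalization is global median-centering of the per-slide log2 ratios
(each slide's gene-median ratio becomes 0), a standard choice for
two-color data when the bulk of genes is unchanged.  A no-op mode is
available for pre-normalized input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

SPOT_COLUMNS = ["gene_id", "bio_rep", "tech_rep", "timepoint_min",
                "channel", "intensity"]


@dataclass(frozen=True)
class FilterConfig:
    """Reproducibility filter: t-test level and fold-change floor."""

    alpha: float = 0.001
    min_fold: float = 2.0
    require_both_datasets: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")


def normalize_arrays(
    spot_table: pd.DataFrame,
    *,
    method: str = "median",
    floor_epsilon: float = 1.0,
    max_floored_fraction: float = 0.5,
    dye_swap_flip: bool = True,
    min_spots: int = 10,
) -> pd.DataFrame:
    """Per-slide log2 ratios, median-centered and dye-swap corrected.

    Returns one row per (gene_id, bio_rep, tech_rep, timepoint_min)
    with a ``log2_ratio`` column (sample over reference, oriented so
    positive means higher in the biological sample after swap
    correction).  Non-positive intensities are floored to
    ``floor_epsilon`` (counts logged); genes floored on more than
    ``max_floored_fraction`` of their spots are dropped.

    ``method``: "median" (default) or "none" for pre-normalized input.
    """
    missing = set(SPOT_COLUMNS) - set(spot_table.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    if method not in ("median", "none"):
        raise ValueError(f"unknown normalization method: {method!r}")

    df = spot_table.copy()
    floored = df["intensity"] <= 0
    n_floored = int(floored.sum())
    if n_floored:
        log.warning("floored %d non-positive intensities to %g",
                    n_floored, floor_epsilon)
        df.loc[floored, "intensity"] = floor_epsilon
    df["_floored"] = floored

    keys = ["gene_id", "bio_rep", "tech_rep", "timepoint_min"]
    wide = df.pivot_table(index=keys, columns="channel",
                          values="intensity", aggfunc="mean")
    if not {"sample", "reference"} <= set(wide.columns):
        raise ValueError("spot table needs both 'sample' and 'reference' channels")
    flo = df.groupby(keys)["_floored"].mean()

    ratios = np.log2(wide["sample"] / wide["reference"])
    out = ratios.rename("log2_ratio").reset_index()
    out["_floored_frac"] = flo.reindex(
        pd.MultiIndex.from_frame(out[keys])).to_numpy()

    slide_keys = ["bio_rep", "tech_rep", "timepoint_min"]
    sizes = out.groupby(slide_keys)["gene_id"].size()
    if (sizes < min_spots).any():
        bad = sizes[sizes < min_spots].index.tolist()
        raise ValueError(f"slides with < {min_spots} usable spots: {bad}")

    if method == "median":
        med = out.groupby(slide_keys)["log2_ratio"].transform("median")
        out["log2_ratio"] = out["log2_ratio"] - med

    if dye_swap_flip:
        swapped = pd.to_numeric(out["tech_rep"]) % 2 == 0
        out.loc[swapped, "log2_ratio"] *= -1.0

    # drop genes dominated by floored spots
    gene_flo = out.groupby("gene_id")["_floored_frac"].transform("mean")
    dropped = out["gene_id"][gene_flo > max_floored_fraction].unique()
    if len(dropped):
        log.warning("dropping %d genes with > %.0f%% floored spots",
                    len(dropped), 100 * max_floored_fraction)
        out = out[~out["gene_id"].isin(dropped)]
    return out.drop(columns="_floored_frac").reset_index(drop=True)


def temporal_ratios(
    observations: pd.DataFrame, *, mode: str = "per-timepoint-reference"
) -> pd.DataFrame:
    """Per-replicate temporal log2 change relative to t=0.

    In "per-timepoint-reference" mode each slide compares sample(t) to
    the common reference pool, so the temporal change for a replicate is
    log2_ratio(t) − log2_ratio(0).  In "timepoint-vs-timepoint" mode
    each slide already measures t against 0 directly and the ratio is
    used as-is (the nominal t=0 rows, identically 0, are dropped).
    """
    if mode == "per-timepoint-reference":
        base = observations[observations["timepoint_min"] == 0]
        if base.empty:
            raise ValueError("no t=0 observations to reference against")
        keys = ["gene_id", "bio_rep", "tech_rep"]
        merged = observations.merge(
            base[keys + ["log2_ratio"]].rename(columns={"log2_ratio": "_t0"}),
            on=keys, how="inner",
        )
        merged = merged[merged["timepoint_min"] > 0].copy()
        merged["log2_change"] = merged["log2_ratio"] - merged["_t0"]
        return merged[keys + ["timepoint_min", "log2_change"]]
    if mode == "timepoint-vs-timepoint":
        out = observations[observations["timepoint_min"] > 0].copy()
        out = out.rename(columns={"log2_ratio": "log2_change"})
        return out[["gene_id", "bio_rep", "tech_rep", "timepoint_min",
                    "log2_change"]]
    raise ValueError(f"unknown design mode: {mode!r}")


def replicate_t_test(values, alpha: float = 0.001):
    """One-sample two-sided t-test of the replicate log2 ratios against 0.

    Returns (t_statistic, p_value, passed).  Degenerate zero-variance
    inputs: all-equal nonzero values give p = 0 (infinitely strong
    evidence at this resolution); all-zero values give t = 0, p = 1.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate values")
    if np.ptp(x) == 0:
        if x[0] == 0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, x[0]), 0.0, True
    t, p = stats.ttest_1samp(x, 0.0)
    return float(t), float(p), bool(p <= alpha)


def summarize_genes(
    changes: pd.DataFrame, filter_config: FilterConfig | None = None
) -> pd.DataFrame:
    """Per-gene replicate summary for one dataset.

    ``changes`` holds per-replicate ``log2_change`` values (output of
    :func:`temporal_ratios`).  Each (gene, timepoint) contrast is
    summarized separately; downstream fitting consumes the
    per-timepoint means.  Returns gene_id, timepoint_min,
    mean_log2_ratio, t, p, n, passed.
    """
    fc = filter_config or FilterConfig()
    rows = []
    for (gid, t), grp in changes.groupby(["gene_id", "timepoint_min"], sort=True):
        vals = grp["log2_change"].to_numpy()
        if vals.size < 2:
            tstat, p, ok = math.nan, math.nan, False
        else:
            tstat, p, ok = replicate_t_test(vals, fc.alpha)
        mean = float(vals.mean())
        rows.append({
            "gene_id": gid, "timepoint_min": t, "mean_log2_ratio": mean,
            "t": tstat, "p": p, "n": int(vals.size),
            "passed": bool(ok and abs(mean) >= math.log2(fc.min_fold)),
        })
    return pd.DataFrame(rows)


def summarize_genes_fast(
    changes: pd.DataFrame, filter_config: FilterConfig | None = None
) -> pd.DataFrame:
    """Vectorized equivalent of :func:`summarize_genes` for large tables."""
    fc = filter_config or FilterConfig()
    g = changes.groupby(["gene_id", "timepoint_min"], sort=True)["log2_change"]
    n = g.size()
    mean = g.mean()
    sd = g.std(ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(t.to_numpy()), df=(n - 1).to_numpy()),
        index=t.index,
    )
    # zero-variance degenerate cases
    zero_var = sd == 0
    t = t.mask(zero_var & (mean == 0), 0.0)
    p = p.mask(zero_var & (mean == 0), 1.0)
    t = t.mask(zero_var & (mean != 0), np.sign(mean) * np.inf)
    p = p.mask(zero_var & (mean != 0), 0.0)
    passed = (p <= fc.alpha) & (mean.abs() >= math.log2(fc.min_fold)) & (n >= 2)
    out = pd.DataFrame({
        "mean_log2_ratio": mean, "t": t, "p": p, "n": n, "passed": passed,
    }).reset_index()
    return out


def filter_reproducible(
    summaries_per_dataset: list[pd.DataFrame],
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Genes passing the t-test and fold threshold in every dataset.

    Each element of ``summaries_per_dataset`` is one biological
    dataset's per-gene summary.  The fold threshold is inclusive
    (|mean log2 ratio| ≥ log2(min_fold)).  Mismatched gene universes
    are intersected with a warning.  Output: one row per retained
    (gene, timepoint), sorted by gene_id, with the cross-dataset mean.
    """
    fc = filter_config or FilterConfig()
    if not summaries_per_dataset:
        raise ValueError("no datasets supplied")
    if not fc.require_both_datasets and len(summaries_per_dataset) > 1:
        pooled = pd.concat(summaries_per_dataset)
        keep = pooled[pooled["passed"]]
        return (keep.groupby(["gene_id", "timepoint_min"], sort=True)
                ["mean_log2_ratio"].mean().reset_index())

    universes = [set(s["gene_id"]) for s in summaries_per_dataset]
    common = set.intersection(*universes)
    if any(u != common for u in universes):
        log.warning("gene universes differ between datasets; using the "
                    "intersection of %d genes", len(common))

    merged = None
    for i, s in enumerate(summaries_per_dataset):
        s = s[s["gene_id"].isin(common)]
        cols = s[["gene_id", "timepoint_min", "mean_log2_ratio", "passed"]]
        cols = cols.rename(columns={
            "mean_log2_ratio": f"mean_{i}", "passed": f"passed_{i}"})
        merged = cols if merged is None else merged.merge(
            cols, on=["gene_id", "timepoint_min"], how="inner")
    pass_cols = [c for c in merged.columns if c.startswith("passed_")]
    mean_cols = [c for c in merged.columns if c.startswith("mean_")]
    keep = merged[merged[pass_cols].all(axis=1)].copy()
    keep["mean_log2_ratio"] = keep[mean_cols].mean(axis=1)
    out = keep[["gene_id", "timepoint_min", "mean_log2_ratio"]]
    return out.sort_values(["gene_id", "timepoint_min"]).reset_index(drop=True)
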