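"""Genotype-wise decay from qPCR-style series and allo-vs-MPV contrast.

Relative transcript abundance (target over a stable internal control
such as *eIF4A2*, renormalized so the t=0 mean is 1) is fitted with the
same first-order model as the arrays, per genotype.  The mid-parent
value (MPV) emulates a 1:1 mix of parental RNAs, so it is the
arithmetic mean of the two parental series on the linear scale; a mix
of two exponentials is not itself exponential, and the fitted k_mpv is
its least-squares first-order approximation.

Whether the allotetraploid decays faster than the MPV is tested as a
difference of log-linear slopes: an OLS model on replicate-level
ln(abundance) with genotype, time and a genotype×time interaction; the
interaction t-test is the slope-difference test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay_kinetics import LN2_ROUNDED, DecayFit, fit_first_order

GENOTYPES = ("allo", "parentA", "parentB")


@dataclass
class QpcrSeries:
    """Control-normalized relative abundance for one gene × genotype.

    ``points`` columns: timepoint_min, replicate, relative_abundance.
    """

    gene_id: str
    genotype: str
    points: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"timepoint_min", "replicate", "relative_abundance"}
        if not req <= set(self.points.columns):
            raise ValueError(f"points need columns {sorted(req)}")
        if np.any(self.points["relative_abundance"].to_numpy() <= 0):
            raise ValueError("relative abundances must be positive")
        if 0 not in set(self.points["timepoint_min"]):
            raise ValueError("series must include timepoint 0")

    def replicate_means(self) -> pd.Series:
        return self.points.groupby("timepoint_min")["relative_abundance"].mean()

    def fit(self, **kwargs) -> DecayFit:
        m = self.replicate_means()
        return fit_first_order(list(zip(m.index, m.to_numpy())),
                               gene_id=self.gene_id, **kwargs)


@dataclass(frozen=True)
class MpvComparison:
    gene_id: str
    t_half_allo: float
    t_half_parentA: float
    t_half_parentB: float
    t_half_mpv: float
    delta_k: float       # k_allo − k_mpv, per minute
    p_value: float
    faster_in_allo: bool
    indeterminate: bool = False


def relative_abundance(
    target: pd.DataFrame, control: pd.DataFrame, *, gene_id: str = "",
    genotype: str = "",
) -> QpcrSeries:
    """Target/control quantity ratios, renormalized to a t=0 mean of 1.

    Both tables need columns timepoint_min, replicate, quantity; the
    control must be measured at every (timepoint, replicate) of the
    target.
    """
    keys = ["timepoint_min", "replicate"]
    merged = target.merge(control, on=keys, suffixes=("_t", "_c"), how="left")
    if merged["quantity_c"].isna().any():
        missing = merged.loc[merged["quantity_c"].isna(), keys]
        raise ValueError(f"control missing at {missing.to_dict('records')}")
    ratio = merged["quantity_t"] / merged["quantity_c"]
    t0_mean = ratio[merged["timepoint_min"] == 0].mean()
    if not t0_mean > 0:
        raise ValueError("no positive t=0 measurements")
    pts = pd.DataFrame({
        "timepoint_min": merged["timepoint_min"],
        "replicate": merged["replicate"],
        "relative_abundance": ratio / t0_mean,
    })
    return QpcrSeries(gene_id, genotype, pts)


def series_from_table(qpcr_table: pd.DataFrame, gene_id: str,
                      genotype: str, *, renormalize: bool = True) -> QpcrSeries:
    """Extract one gene × genotype series from a long qPCR table."""
    sel = qpcr_table[(qpcr_table["gene_id"] == gene_id)
                     & (qpcr_table["genotype"] == genotype)]
    if sel.empty:
        raise ValueError(f"no rows for {gene_id}/{genotype}")
    pts = sel[["timepoint_min", "replicate", "relative_abundance"]].copy()
    if renormalize:
        t0 = pts.loc[pts["timepoint_min"] == 0, "relative_abundance"].mean()
        pts["relative_abundance"] = pts["relative_abundance"] / t0
    return QpcrSeries(gene_id, genotype, pts)


def build_mpv_series(parent_a: QpcrSeries, parent_b: QpcrSeries) -> QpcrSeries:
    """Mid-parent series: per-timepoint linear mean of the parents.

    When the parents share replicate labels, replicates are paired
    (MPV replicate r = mean of parent replicates r), preserving the
    replicate structure for the downstream slope test; otherwise the
    replicate means are averaged into a single synthetic replicate.
    """
    keys = ["timepoint_min", "replicate"]
    pa, pb = parent_a.points, parent_b.points
    if set(pa["timepoint_min"]) != set(pb["timepoint_min"]):
        raise ValueError("parental timepoints do not match")
    if set(map(tuple, pa[keys].to_numpy())) == set(map(tuple, pb[keys].to_numpy())):
        merged = pa.merge(pb, on=keys, suffixes=("_a", "_b"))
        pts = pd.DataFrame({
            "timepoint_min": merged["timepoint_min"],
            "replicate": merged["replicate"],
            "relative_abundance": (merged["relative_abundance_a"]
                                   + merged["relative_abundance_b"]) / 2.0,
        })
    else:
        ma, mb = parent_a.replicate_means(), parent_b.replicate_means()
        mean = (ma + mb.reindex(ma.index)) / 2.0
        pts = pd.DataFrame({
            "timepoint_min": mean.index,
            "replicate": 1,
            "relative_abundance": mean.to_numpy(),
        })
    return QpcrSeries(parent_a.gene_id, "mpv", pts)


def _slope_difference_test(a: QpcrSeries, b: QpcrSeries) -> tuple[float, float]:
    """ANCOVA-style slope difference on replicate-level ln values.

    Fits ln(y) ~ genotype + time + genotype:time by OLS and returns
    (slope_a − slope_b, two-sided p of the interaction term).
    Equivalent to the standard two-regression slope comparison with a
    pooled residual variance.
    """
    ta = a.points["timepoint_min"].to_numpy(dtype=float)
    ya = np.log(a.points["relative_abundance"].to_numpy(dtype=float))
    tb = b.points["timepoint_min"].to_numpy(dtype=float)
    yb = np.log(b.points["relative_abundance"].to_numpy(dtype=float))

    def _ols(t, y):
        tc = t - t.mean()
        sxx = float(np.sum(tc * tc))
        slope = float(np.sum(tc * (y - y.mean())) / sxx)
        resid = y - y.mean() - slope * tc
        return slope, sxx, float(np.sum(resid**2)), len(t)

    sa, sxxa, rssa, na = _ols(ta, ya)
    sb, sxxb, rssb, nb = _ols(tb, yb)
    diff = sa - sb
    df = na + nb - 4
    if df <= 0:
        return diff, float("nan")
    pooled = (rssa + rssb) / df
    se = math.sqrt(pooled * (1.0 / sxxa + 1.0 / sxxb))
    if se == 0:
        return diff, 1.0 if diff == 0 else 0.0
    t_stat = diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return diff, float(p)


def compare_allo_vs_mpv(
    allo: QpcrSeries,
    mpv: QpcrSeries,
    *,
    parent_a: QpcrSeries | None = None,
    parent_b: QpcrSeries | None = None,
    alpha: float = 0.05,
    ln2_constant: float = LN2_ROUNDED,
) -> MpvComparison:
    """Does the allotetraploid transcript decay faster than the MPV?

    delta_k = k_allo − k_mpv from the replicate-level slope fits;
    ``faster_in_allo`` requires both delta_k > 0 and interaction
    p ≤ alpha.  A comparison where both fits are censored (no decay
    anywhere) is flagged indeterminate.
    """
    fit_a = allo.fit(ln2_constant=ln2_constant)
    fit_m = mpv.fit(ln2_constant=ln2_constant)
    slope_diff, p = _slope_difference_test(allo, mpv)
    delta_k = -slope_diff  # k = −slope on the ln scale
    indet = fit_a.censored and fit_m.censored and abs(delta_k) < 1e-12
    fa = parent_a.fit(ln2_constant=ln2_constant) if parent_a else None
    fb = parent_b.fit(ln2_constant=ln2_constant) if parent_b else None
    return MpvComparison(
        gene_id=allo.gene_id,
        t_half_allo=fit_a.t_half,
        t_half_parentA=fa.t_half if fa else math.nan,
        t_half_parentB=fb.t_half if fb else math.nan,
        t_half_mpv=fit_m.t_half,
        delta_k=delta_k,
        p_value=p,
        faster_in_allo=bool(delta_k > 0 and p <= alpha and not indet),
        indeterminate=indet,
    )


def compare_gene_table(
    qpcr_table: pd.DataFrame, gene_ids, *, alpha: float = 0.05,
    ln2_constant: float = LN2_ROUNDED,
) -> pd.DataFrame:
    """Run the allo-vs-MPV contrast for each gene in a long qPCR table."""
    rows = []
    for gid in gene_ids:
        pa = series_from_table(qpcr_table, gid, "parentA")
        pb = series_from_table(qpcr_table, gid, "parentB")
        allo = series_from_table(qpcr_table, gid, "allo")
        mpv = build_mpv_series(pa, pb)
        cmp_ = compare_allo_vs_mpv(allo, mpv, parent_a=pa, parent_b=pb,
                                   alpha=alpha, ln2_constant=ln2_constant)
        rows.append(cmp_.__dict__)
    return pd.DataFrame(rows)
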