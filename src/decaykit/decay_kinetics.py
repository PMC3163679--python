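"""First-order mRNA decay fitting and unstable-transcript (GUT) calling.

After transcription shutoff, most transcripts decay with first-order
kinetics: N(t) = N(0)·exp(−k·t).  On the log scale, ln(ratio remaining)
is linear in time with slope −k, and the half-life is t½ = 0.693/k.

The half-life constant defaults to the rounded 0.693 used in the
original microarray analysis; pass ``ln2_constant=math.log(2)`` (or use
:data:`LN2_EXACT`) for the exact value.  Genes whose fitted k is ≤ 0
(flat or rising signal) are *censored*: their half-life is reported as
+inf and they are never called GUTs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Rounded half-life constant as used in the source analysis.
LN2_ROUNDED = 0.693
#: Exact natural log of 2, for calibration / recovery work.
LN2_EXACT = math.log(2.0)

#: Half-life threshold (minutes) below which a transcript is "unstable".
GUT_THRESHOLD_MIN = 60.0


@dataclass(frozen=True)
class DecayFit:
    """Per-gene first-order decay fit.

    ``t_half`` is +inf when ``censored`` (k ≤ 0); otherwise
    ``t_half == ln2_constant / k_decay`` exactly.
    """

    gene_id: str
    k_decay: float          # per minute
    t_half: float           # minutes, +inf if censored
    n_points: int
    r_squared: float        # nan for 2-point fits
    censored: bool


@dataclass(frozen=True)
class GutCall:
    gene_id: str
    t_half: float
    is_gut: bool
    threshold: float = GUT_THRESHOLD_MIN


def half_life_from_ratio(
    ratio: float, t: float, ln2_constant: float = LN2_ROUNDED
) -> float:
    """Half-life from a single fraction-remaining measurement.

    Inverts ln(ratio) = −k·t and returns ln2_constant / k.  A ratio ≥ 1
    (no net decay) yields +inf.

    Parameters
    ----------
    ratio : fraction of the transcript remaining at time ``t`` (> 0).
    t : minutes elapsed since transcription shutoff (> 0).
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    if ratio >= 1:
        return math.inf
    k = -math.log(ratio) / t
    return ln2_constant / k


def fit_first_order(
    series: Iterable[tuple[float, float]],
    *,
    gene_id: str = "",
    free_intercept: bool = True,
    ln2_constant: float = LN2_ROUNDED,
) -> DecayFit:
    """Fit ln(ratio) = a − k·t to a (timepoint, mean ratio) series.

    Two points use the closed form k = −ln(r1/r0)/(t1−t0).  Three or
    more points use least squares on the log scale; by default the
    intercept is free (robust to mis-scaled t=0 values), with
    ``free_intercept=False`` forcing the line through ln(ratio)=0 at
    t=0.  A non-positive fitted k censors the gene.
    """
    pts = sorted(series)
    if len(pts) < 2:
        raise ValueError("need at least 2 timepoints to fit decay")
    t = np.asarray([p[0] for p in pts], dtype=float)
    r = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    y = np.log(r)

    if len(pts) == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        r2 = math.nan
    elif free_intercept:
        slope, _ = np.polyfit(t, y, 1)
        resid = y - np.polyval(np.polyfit(t, y, 1), t)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        # through-origin regression: slope = Σty / Σt²
        slope = float(np.sum(t * y) / np.sum(t * t))
        resid = y - slope * t
        ss_tot = float(np.sum(y**2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    k = -float(slope)
    if k <= 0:
        return DecayFit(gene_id, k, math.inf, len(pts), r2, censored=True)
    return DecayFit(gene_id, k, ln2_constant / k, len(pts), r2, censored=False)


def fit_many(
    ratios: pd.DataFrame,
    *,
    free_intercept: bool = True,
    ln2_constant: float = LN2_ROUNDED,
) -> pd.DataFrame:
    """Vectorized per-gene fits from a long table.

    ``ratios`` needs columns gene_id, timepoint_min, ratio (linear
    fraction remaining, replicate-averaged).  Returns a frame with
    gene_id, k_per_min, t_half_min, n_points, r_squared, censored.
    """
    required = {"gene_id", "timepoint_min", "ratio"}
    missing = required - set(ratios.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    df = ratios.copy()
    if np.any(df["ratio"].to_numpy() <= 0):
        raise ValueError("ratios must be positive")
    df["lnr"] = np.log(df["ratio"].to_numpy())

    g = df.groupby("gene_id", sort=True)
    n = g.size()
    t_mean = g["timepoint_min"].mean()
    y_mean = g["lnr"].mean()
    df["_tc"] = df["timepoint_min"] - df["gene_id"].map(t_mean)
    df["_yc"] = df["lnr"] - df["gene_id"].map(y_mean)
    if free_intercept:
        sxy = (df["_tc"] * df["_yc"]).groupby(df["gene_id"]).sum()
        sxx = (df["_tc"] ** 2).groupby(df["gene_id"]).sum()
    else:
        sxy = (df["timepoint_min"] * df["lnr"]).groupby(df["gene_id"]).sum()
        sxx = (df["timepoint_min"] ** 2).groupby(df["gene_id"]).sum()
    slope = sxy / sxx
    k = -slope

    ss_res = ((df["_yc"] - df["_tc"] * df["gene_id"].map(slope)) ** 2
              ).groupby(df["gene_id"]).sum()
    ss_tot = (df["_yc"] ** 2).groupby(df["gene_id"]).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    r2 = r2.where(ss_tot > 0, 1.0).where(n > 2, np.nan)

    censored = k <= 0
    t_half = ln2_constant / k.where(~censored)
    t_half = t_half.fillna(np.inf)
    out = pd.DataFrame(
        {
            "gene_id": n.index,
            "k_per_min": k.to_numpy(),
            "t_half_min": t_half.to_numpy(),
            "n_points": n.to_numpy(),
            "r_squared": r2.to_numpy(),
            "censored": censored.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def call_guts(
    fits: Sequence[DecayFit] | pd.DataFrame,
    threshold: float = GUT_THRESHOLD_MIN,
) -> list[GutCall]:
    """Call genes with unstable transcripts: t½ strictly below threshold.

    Censored fits (no measurable decay) are never GUTs.  A call is
    returned for every input gene.
    """
    if isinstance(fits, pd.DataFrame):
        rows = fits.itertuples()
        return [
            GutCall(r.gene_id, r.t_half_min,
                    bool(not r.censored and r.t_half_min < threshold),
                    threshold)
            for r in rows
        ]
    return [
        GutCall(f.gene_id, f.t_half,
                bool(not f.censored and f.t_half < threshold), threshold)
        for f in fits
    ]


def fits_to_frame(fits: Sequence[DecayFit], threshold: float = GUT_THRESHOLD_MIN) -> pd.DataFrame:
    """Export fits in the standard TSV layout (with GUT flags)."""
    calls = call_guts(fits, threshold)
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "k_per_min": [f.k_decay for f in fits],
            "t_half_min": [f.t_half for f in fits],
            "censored": [f.censored for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "is_gut": [c.is_gut for c in calls],
        }
    )
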