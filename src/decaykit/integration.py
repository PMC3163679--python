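"""Integrating GUT calls with a nonadditive-expression gene set.

Covers the set-level questions: how many unstable-transcript genes are
also nonadditively expressed (Venn overlap), is membership in the two
sets associated (2×2 chi-square on the gene universe), is steady-state
expression correlated with decay rate, and what does the joint
decay/expression profile look like after hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    members_overlap: tuple[str, ...]

    @property
    def table(self) -> np.ndarray:
        """2×2 contingency table [[both, a only], [b only, neither]]."""
        both = self.n_overlap
        a_only = self.n_set_a - both
        b_only = self.n_set_b - both
        neither = self.n_universe - both - a_only - b_only
        return np.array([[both, a_only], [b_only, neither]], dtype=float)


@dataclass(frozen=True)
class AssociationTest:
    chi_square: float
    df: int
    p_value: float
    table: tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class ClusterResult:
    leaf_order: tuple[str, ...]
    merge_tree: tuple[tuple[int, int, float], ...]
    distance: str
    linkage: str
    ordered_matrix: pd.DataFrame = field(repr=False, compare=False, default=None)


def intersect_gene_sets(set_a, set_b, universe) -> OverlapResult:
    """Exact intersection of two gene sets within a universe.

    Members outside the universe are logged and clipped.  Ordering of
    the overlap members is lexicographic, so results are deterministic.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a, b = set(set_a), set(set_b)
    for name, s in (("set_a", a), ("set_b", b)):
        extra = s - universe
        if extra:
            log.warning("%d %s members outside the universe were clipped",
                        len(extra), name)
    a &= universe
    b &= universe
    overlap = tuple(sorted(a & b))
    return OverlapResult(len(universe), len(a), len(b), len(overlap), overlap)


def chi_square_association(
    overlap: OverlapResult | np.ndarray, *, continuity_correction: bool = False
) -> AssociationTest:
    """Pearson chi-square test of 2×2 association (df = 1).

    No Yates continuity correction by default; with genome-scale
    universes the correction is immaterial and the plain statistic
    matches the textbook N(ad−bc)²/(r₁r₂c₁c₂) formula.
    """
    table = overlap.table if isinstance(overlap, OverlapResult) else np.asarray(
        overlap, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(table < 0):
        raise ValueError("negative cell counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(
        table, correction=continuity_correction)
    return AssociationTest(float(chi2), int(df), float(p),
                           tuple(map(tuple, table)))


def correlate_expression_decay(
    expression: pd.Series | dict,
    decay: pd.Series | dict,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate steady-state expression with decay rate across genes.

    Pairs by gene id with listwise deletion of missing/non-finite
    values (censored genes should be excluded upstream).  Spearman is
    the default — the decay-constant distribution is heavy-tailed.
    """
    e = pd.Series(expression).astype(float)
    d = pd.Series(decay).astype(float)
    df = pd.concat({"e": e, "d": d}, axis=1, join="inner").replace(
        [np.inf, -np.inf], np.nan).dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 paired finite values")
    if df["e"].nunique() < 2 or df["d"].nunique() < 2:
        raise ValueError("constant vector; correlation undefined")
    if method == "spearman":
        rho, p = stats.spearmanr(df["e"], df["d"])
    elif method == "pearson":
        rho, p = stats.pearsonr(df["e"], df["d"])
    else:
        raise ValueError(f"unknown method: {method!r}")
    return CorrelationResult(method, float(rho), len(df), float(p))


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Condensed 1 − Pearson distance between rows."""
    return pdist(matrix.to_numpy(dtype=float), metric="correlation")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    *,
    distance: str = "correlation",
    linkage: str = "average",
    clip: float = 3.0,
) -> ClusterResult:
    """Average-linkage agglomerative clustering of gene profiles.

    Default distance is 1 − Pearson correlation between rows, the
    classic gene-expression clustering metric.  Rows with zero variance
    (undefined correlation) are dropped with a warning.  The returned
    ordered matrix is clipped to ±``clip`` for display parity with the
    usual log2 heat-map color range.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows to cluster")
    mat = matrix.astype(float)
    if not np.all(np.isfinite(mat.to_numpy())):
        raise ValueError("non-finite entries in profile matrix")
    if distance == "correlation":
        var = mat.var(axis=1, ddof=0)
        bad = var == 0
        if bad.any():
            log.warning("dropping %d zero-variance rows", int(bad.sum()))
            mat = mat[~bad]
            if len(mat) < 2:
                raise ValueError("fewer than 2 rows left after dropping "
                                 "zero-variance rows")
        dvec = correlation_distance_matrix(mat)
    elif distance == "euclidean":
        dvec = pdist(mat.to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown distance: {distance!r}")
    # scipy breaks distance ties by the smallest cluster indices
    Z = hierarchy.linkage(dvec, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    leaf_ids = tuple(mat.index[i] for i in leaves)
    ordered = mat.iloc[leaves].clip(-clip, clip)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return ClusterResult(leaf_ids, merges, distance, linkage, ordered)
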