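"""GOSlim fold enrichment of a gene set against the genome background.

Fold enrichment of category c is the set proportion divided by the
genome proportion: (n_in_set/set_size) / (n_in_genome/genome_size).
GOSlim is treated as a flat vocabulary (no DAG propagation); a gene
with several categories counts once in each.  An optional
hypergeometric upper-tail test with Benjamini–Hochberg adjustment adds
significance to the ratio-only presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryAnnotation:
    """gene_id → set of category labels, plus the background size.

    ``background_size`` is the number of genes in the genome/array
    universe; by default it includes unannotated genes ("all genes in
    the genome"), the convention matching proportion-of-genome
    denominators.  Use ``annotated_only()`` for the alternative.
    """

    mapping: dict[str, frozenset[str]]
    background_size: int

    def __post_init__(self) -> None:
        sizes = self.category_sizes()
        largest = max(sizes.values()) if sizes else 0
        if self.background_size < largest:
            raise ValueError("background smaller than its largest category")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   background_size: int | None = None) -> "CategoryAnnotation":
        """Build from a two-column (gene_id, goslim_term) table."""
        mapping: dict[str, set[str]] = {}
        for gid, term in zip(frame["gene_id"], frame["goslim_term"]):
            mapping.setdefault(str(gid).upper(), set()).add(str(term))
        frozen = {g: frozenset(c) for g, c in mapping.items()}
        return cls(frozen, background_size or len(frozen))

    def annotated_only(self) -> "CategoryAnnotation":
        return CategoryAnnotation(self.mapping, len(self.mapping))

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cats in self.mapping.values():
            for c in cats:
                sizes[c] = sizes.get(c, 0) + 1
        return sizes


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    n_in_set: int
    set_size: int
    n_in_genome: int
    genome_size: int
    fold: float
    p_hyper: float | None = None
    q_value: float | None = None


def fold_enrichment(
    gene_set,
    annotation: CategoryAnnotation,
    *,
    with_test: bool = False,
    bh_adjust: bool = False,
) -> list[EnrichmentRow]:
    """Per-category fold enrichment of ``gene_set`` vs the background.

    One row per category present in the annotation, sorted by
    descending fold (ties by category name).  Categories absent from
    the genome background are excluded with a warning.  Set and genome
    sizes count all supplied genes, annotated or not.
    """
    genes = {str(g).upper() for g in gene_set}
    if not genes:
        raise ValueError("empty gene set")
    set_size = len(genes)
    genome_size = annotation.background_size
    genome_counts = annotation.category_sizes()

    set_counts: dict[str, int] = {c: 0 for c in genome_counts}
    for g in genes:
        for c in annotation.mapping.get(g, ()):
            set_counts[c] = set_counts.get(c, 0) + 1

    rows = []
    for cat in sorted(genome_counts):
        n_genome = genome_counts[cat]
        if n_genome == 0:
            log.warning("category %s has no genome members; excluded", cat)
            continue
        n_set = set_counts.get(cat, 0)
        fold = (n_set / set_size) / (n_genome / genome_size)
        rows.append(EnrichmentRow(cat, n_set, set_size, n_genome,
                                  genome_size, fold))
    if with_test:
        rows = [EnrichmentRow(r.category, r.n_in_set, r.set_size,
                              r.n_in_genome, r.genome_size, r.fold,
                              p_hyper=hypergeometric_test(r))
                for r in rows]
        if bh_adjust and rows:
            from statsmodels.stats.multitest import multipletests

            _, q, _, _ = multipletests([r.p_hyper for r in rows], method="fdr_bh")
            rows = [EnrichmentRow(r.category, r.n_in_set, r.set_size,
                                  r.n_in_genome, r.genome_size, r.fold,
                                  r.p_hyper, q_value=float(qi))
                    for r, qi in zip(rows, q)]
    rows.sort(key=lambda r: (-r.fold, r.category))
    return rows


def hypergeometric_test(row: EnrichmentRow) -> float:
    """Upper-tail hypergeometric p: P(X ≥ n_in_set).

    Drawing ``set_size`` genes without replacement from a genome of
    ``genome_size`` containing ``n_in_genome`` category members.
    """
    if not (0 <= row.n_in_set <= min(row.set_size, row.n_in_genome)):
        raise ValueError("impossible counts in enrichment row")
    if row.set_size > row.genome_size or row.n_in_genome > row.genome_size:
        raise ValueError("set or category larger than genome")
    return float(stats.hypergeom.sf(row.n_in_set - 1, row.genome_size,
                                    row.n_in_genome, row.set_size))


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
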