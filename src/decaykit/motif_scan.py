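"""Scanning upstream sequences for circadian cis-elements.

Two literal motifs are built in: the CCA1-binding site
(CBS, AAAAATCT) and the evening element (EE, core AATATCT, often
written with an AA prefix as AAAATATCT).  An EE hit is reported
whenever the 7-mer core matches; the ``extended`` flag records whether
the AA prefix is present, and a strict mode requires it.  Coordinates
are 0-based half-open on the sequence as supplied (upstream region
written 5'→3' ending at the transcription start).  Scanning is
forward-strand by default; reverse-complement scanning is optional.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

CBS_CORE = "AAAAATCT"
EE_CORE = "AATATCT"
EE_PREFIX = "AA"


@dataclass(frozen=True)
class MotifDef:
    name: str
    core: str
    optional_prefix: str = ""


CBS = MotifDef("CBS", CBS_CORE)
EE = MotifDef("EE", EE_CORE, EE_PREFIX)
DEFAULT_MOTIFS = (CBS, EE)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_name: str
    start: int          # 0-based; hit spans [start, start + len(core))
    strand: str         # '+' or '-'
    extended: bool      # EE only: AA prefix immediately upstream

    @property
    def end(self) -> int:
        core = CBS_CORE if self.motif_name == "CBS" else EE_CORE
        return self.start + len(core)


def _find_all(seq: str, sub: str) -> list[int]:
    """All (possibly overlapping) match offsets of sub in seq."""
    hits, i = [], seq.find(sub)
    while i != -1:
        hits.append(i)
        i = seq.find(sub, i + 1)
    return hits


def scan_sequence(
    seq: str,
    motifs=DEFAULT_MOTIFS,
    *,
    gene_id: str = "",
    scan_reverse: bool = False,
    strict_extended: bool = False,
) -> list[MotifHit]:
    """All motif occurrences in a promoter sequence.

    ``N`` (or any non-ACGT symbol) never matches.  With
    ``strict_extended`` an EE hit additionally requires the AA prefix.
    With ``scan_reverse`` the reverse complement is scanned too; hit
    coordinates on the '-' strand refer to the forward sequence
    (start of the motif's reverse-complement image).
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    strands = [("+", seq)]
    if scan_reverse:
        strands.append(("-", str(Seq(seq).reverse_complement())))
    for strand, s in strands:
        for m in motifs:
            for pos in _find_all(s, m.core):
                extended = False
                if m.optional_prefix:
                    p = len(m.optional_prefix)
                    extended = pos >= p and s[pos - p:pos] == m.optional_prefix
                    if strict_extended and not extended:
                        continue
                start = pos if strand == "+" else len(seq) - pos - len(m.core)
                hits.append(MotifHit(gene_id, m.name, start, strand, extended))
    hits.sort(key=lambda h: (h.start, h.motif_name, h.strand))
    return hits


def scan_promoters(
    promoters: dict[str, str], **kwargs
) -> dict[str, list[MotifHit]]:
    """Scan a gene_id → sequence mapping; returns hits per gene."""
    return {g: scan_sequence(s, gene_id=g, **kwargs)
            for g, s in promoters.items()}


def summarize_presence(
    hits_per_gene: dict[str, list[MotifHit]], gene_set
) -> tuple[int, float]:
    """Count genes in ``gene_set`` with at least one motif hit.

    Returns (n_with_hit, fraction of the set).  Genes absent from
    ``hits_per_gene`` count as hitless.
    """
    genes = {str(g).upper() for g in gene_set}
    if not genes:
        raise ValueError("empty gene set")
    lookup = {str(g).upper(): h for g, h in hits_per_gene.items()}
    n_hit = sum(1 for g in genes if lookup.get(g))
    return n_hit, n_hit / len(genes)
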