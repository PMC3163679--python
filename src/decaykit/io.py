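"""Readers and writers for the package's plain-text formats.

Everything is TSV with a header row ('#' lines are comments), FASTA, or
one-gene-per-line lists.  Gene identifiers are case-normalized to
uppercase AGI style on read so joins are reliable.  The transcribed
reference table of 61 nonadditively expressed unstable-transcript genes
ships with the package and is integrity-checked on load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

SPOT_SCHEMA = ["gene_id", "bio_rep", "tech_rep", "timepoint_min",
               "channel", "intensity"]
QPCR_SCHEMA = ["gene_id", "genotype", "timepoint_min", "replicate",
               "relative_abundance"]
GOSLIM_SCHEMA = ["gene_id", "goslim_term"]

_TABLE1_RESOURCE = "table1_alloguts.tsv"
_TABLE1_SHA256 = (
    "e7f22d62528957a394089db6bcb2c903bcdac3dc86c0079712748f01149f4edd"
)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "gene_id" in df.columns:
        df["gene_id"] = df["gene_id"].astype(str).str.upper()
    return df


def read_spot_table(path) -> pd.DataFrame:
    return _read_tsv(path, SPOT_SCHEMA)


def read_qpcr_table(path) -> pd.DataFrame:
    return _read_tsv(path, QPCR_SCHEMA)


def read_goslim_map(path) -> pd.DataFrame:
    return _read_tsv(path, GOSLIM_SCHEMA)


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored.

    Duplicates are removed (first occurrence kept) with a logged count.
    """
    seen: dict[str, None] = {}
    dups = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip().upper()
        if not s or s.startswith("#"):
            continue
        if s in seen:
            dups += 1
        else:
            seen[s] = None
    if dups:
        log.warning("%s: removed %d duplicate gene ids", path, dups)
    return list(seen)


def read_fasta(path) -> dict[str, str]:
    """gene_id → sequence; tolerates line wrapping and CRLF endings."""
    return {rec.id.upper(): str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=g, description="")
               for g, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


@dataclass(frozen=True)
class Table1Fixture:
    """The 61 nonadditively expressed unstable-transcript genes.

    Transcribed verbatim; one locus (AT3G15210) is printed twice in the
    source table with two different half-lives, so there are 61 records
    but 60 unique locus ids.
    """

    records: pd.DataFrame  # columns locus, description, t_half_min

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.records["locus"]))

    def half_life(self, locus: str) -> float:
        sel = self.records[self.records["locus"] == locus.upper()]
        if sel.empty:
            raise KeyError(locus)
        return float(sel["t_half_min"].iloc[0])


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged reference table, verifying its checksum."""
    ref = resources.files("decaykit").joinpath("data", _TABLE1_RESOURCE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            f"packaged fixture checksum mismatch: {digest}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    df["locus"] = df["locus"].str.upper()
    return Table1Fixture(df)
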