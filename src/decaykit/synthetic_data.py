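"""Synthetic transcription-shutoff datasets with known ground truth.

Emulates the experimental design of a genome-wide mRNA-stability study
in an *Arabidopsis* allotetraploid: ~26,090 genes on a two-color
spotted-oligo array, transcription blocked chemically at t=0, slides
hybridized at each timepoint with the allotetraploid sample against a
1:1 parental RNA mix (mid-parent value, MPV) as reference, with two
biological × two technical (dye-swap) replicates.  Roughly 1% of genes
carry unstable transcripts (half-life < 60 min); those genes are
preferentially nonadditively expressed, their steady-state log2
expression ratio is negatively coupled to the decay constant, chosen GO
categories are enriched among them, and circadian promoter elements
(CBS / evening element) are planted upstream at configurable rates.

Everything is driven by a single integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CBS_MOTIF = "AAAAATCT"
EE_MOTIF_EXTENDED = "AAAATATCT"  # evening element with its AA prefix

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults mirror the array experiment being emulated: 26,090 genes,
    ~0.8% unstable (expected ≈ 208 genes), sampling at 0 and 120 min
    with two biological and two technical (dye-swap) replicates.
    """

    n_genes: int = 26090
    fraction_unstable: float = 0.008
    unstable_halflife_range: tuple[float, float] = (15.0, 59.0)
    stable_halflife_range: tuple[float, float] = (90.0, 600.0)
    timepoints: tuple[float, ...] = (0.0, 60.0, 120.0)
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    noise_sd_log2: float = 0.15       # SD of the per-spot log2 ratio noise
    dye_bias_log2: float = 0.10       # additive bias of the sample-dye channel
    nonadditive_rate_stable: float = 0.05
    nonadditive_coupling: float = 0.5
    n_categories: int = 20
    category_base_prob: float = 0.05  # per-category membership prob, stable genes
    enrichment_factor: float = 3.0    # target fold enrichment of category 0 in GUTs
    promoter_length: int = 1000
    motif_plant_prob_unstable: float = 0.5
    motif_plant_prob_stable: float = 0.1
    qpcr_n_reps: int = 3
    qpcr_noise_sd_ln: float = 0.1
    parental_divergence: float = 0.0  # parent k = true_k * (1 ± divergence)
    base_intensity: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("fraction_unstable", "nonadditive_coupling",
                     "motif_plant_prob_unstable", "motif_plant_prob_stable",
                     "nonadditive_rate_stable"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("unstable_halflife_range", "stable_halflife_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered")
        tps = self.timepoints
        if tps[0] != 0 or any(a >= b for a, b in zip(tps, tps[1:])) or tps[0] < 0:
            raise ValueError("timepoints must start at 0 and strictly increase")
        if self.noise_sd_log2 < 0 or self.qpcr_noise_sd_ln < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class TrueGene:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_halflife: float          # minutes; +inf for non-decaying
    true_k: float                 # ln2 / true_halflife, 0 when infinite
    is_unstable: bool             # true_halflife < 60
    categories: frozenset[str]
    nonadditive: bool
    expression_log2_ratio: float  # steady-state log2(allo / MPV)
    promoter: str


@dataclass
class SimulatedDataset:
    genes: list[TrueGene]
    spot_table: pd.DataFrame
    qpcr_table: pd.DataFrame
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    # AGI-style ids: ATxGnnnnn, chromosome cycling 1..5
    return [f"AT{i % 5 + 1}G{i // 5:05d}" for i in range(n)]


def generate_gene_catalog(config: SimulationConfig) -> list[TrueGene]:
    """Draw a gene catalog with the configured mixture structure.

    Unstable genes (Bernoulli ``fraction_unstable``) get half-lives
    uniform on ``unstable_halflife_range``, stable genes on
    ``stable_halflife_range``.  P(nonadditive | unstable) exceeds
    P(nonadditive | stable) by ``nonadditive_coupling`` (clipped at 1),
    and the steady-state expression log2 ratio is drawn with a negative
    dependence on the decay constant when coupling > 0.  Category 0's
    membership probability among unstable genes is boosted so that its
    expected fold enrichment in the unstable set equals
    ``enrichment_factor``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    ids = _gene_ids(n)

    unstable = rng.random(n) < config.fraction_unstable
    lo_u, hi_u = config.unstable_halflife_range
    lo_s, hi_s = config.stable_halflife_range
    halflife = np.where(
        unstable,
        rng.uniform(lo_u, hi_u, size=n),
        rng.uniform(lo_s, hi_s, size=n),
    )
    k = math.log(2.0) / halflife

    # nonadditive expression flag, coupled to instability
    p_s = config.nonadditive_rate_stable
    p_u = min(1.0, p_s + config.nonadditive_coupling)
    nonadd = rng.random(n) < np.where(unstable, p_u, p_s)

    # expression ratio: negative slope on k, plus residual scatter
    c = config.nonadditive_coupling
    noise_sd = 0.5 * (1.0 - 0.5 * c) + 1e-12
    expr = -c * 60.0 * k + rng.normal(0.0, noise_sd, size=n)

    # category memberships; category 0 enriched among unstable genes
    q = config.category_base_prob
    f = config.enrichment_factor
    fu = config.fraction_unstable
    if f * fu < 1.0:
        q_u0 = min(1.0, f * q * (1.0 - fu) / (1.0 - f * fu))
    else:
        q_u0 = min(1.0, f * q)
    cat_names = [f"GO:{i:04d}" for i in range(config.n_categories)]
    member = rng.random((n, config.n_categories)) < q
    if config.n_categories > 0:
        member[unstable, 0] = rng.random(int(unstable.sum())) < q_u0

    promoters = _generate_promoters(rng, config, unstable)

    genes: list[TrueGene] = []
    for i in range(n):
        cats = frozenset(cat_names[j] for j in np.nonzero(member[i])[0])
        genes.append(
            TrueGene(
                gene_id=ids[i],
                true_halflife=float(halflife[i]),
                true_k=float(k[i]),
                is_unstable=bool(unstable[i]),
                categories=cats,
                nonadditive=bool(nonadd[i]),
                expression_log2_ratio=float(expr[i]),
                promoter=promoters[i],
            )
        )
    return genes


def _generate_promoters(
    rng: np.random.Generator, config: SimulationConfig, unstable: np.ndarray
) -> list[str]:
    """i.i.d. uniform ACGT sequences with CBS/EE planted on the forward strand."""
    n, L = config.n_genes, config.promoter_length
    arr = _BASES[rng.integers(0, 4, size=(n, L))]
    plant_p = np.where(unstable, config.motif_plant_prob_unstable,
                       config.motif_plant_prob_stable)
    plant = rng.random(n) < plant_p
    which = rng.integers(0, 2, size=n)  # 0 = CBS, 1 = EE (with AA prefix)
    motifs = (CBS_MOTIF, EE_MOTIF_EXTENDED)
    max_len = max(len(m) for m in motifs)
    pos = rng.integers(0, max(1, L - max_len + 1), size=n)
    for i in np.nonzero(plant)[0]:
        m = motifs[which[i]]
        p = int(pos[i])
        arr[i, p:p + len(m)] = np.frombuffer(m.encode(), dtype="S1")
    return [a.tobytes().decode() for a in arr]


def simulate_measurements(
    genes: Sequence[TrueGene], config: SimulationConfig
) -> SimulatedDataset:
    """Simulate the two-channel spot table and the qPCR series.

    Spot table: one slide per (bio_rep, tech_rep, timepoint) comparing
    the allotetraploid sample at time t against the MPV reference pool.
    The expected sample-channel intensity decays as exp(−k·t); each
    channel carries i.i.d. log2 noise of SD ``noise_sd_log2 / √2`` so
    the per-spot log2-ratio noise has SD ``noise_sd_log2``.  Channel
    labels follow the dyes: even-numbered technical replicates are
    dye swaps, in which the biological materials trade channels, and the
    additive ``dye_bias_log2`` always sits on the sample-dye channel.

    qPCR table: control-normalized relative abundance per genotype with
    expectation exp(−k_g·t); parental decay constants are true_k scaled
    by (1 ∓ ``parental_divergence``).
    """
    if len(genes) == 0:
        raise ValueError("empty gene catalog")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n = len(genes)
    ids = np.array([g.gene_id for g in genes])
    k = np.array([g.true_k for g in genes])
    expr = np.array([g.expression_log2_ratio for g in genes])
    tps = np.asarray(config.timepoints, dtype=float)
    chan_sd = config.noise_sd_log2 / math.sqrt(2.0)

    frames = []
    for b in range(1, config.n_bio_reps + 1):
        for tr in range(1, config.n_tech_reps + 1):
            swapped = tr % 2 == 0
            for t in tps:
                # biological expectation on this slide
                allo = config.base_intensity * 2.0 ** expr * np.exp(-k * t)
                mpv = np.full(n, config.base_intensity)
                allo = allo * 2.0 ** rng.normal(0.0, chan_sd, n)
                mpv = mpv * 2.0 ** rng.normal(0.0, chan_sd, n)
                if swapped:
                    sample_chan, ref_chan = mpv, allo
                else:
                    sample_chan, ref_chan = allo, mpv
                sample_chan = sample_chan * 2.0 ** config.dye_bias_log2
                frames.append(pd.DataFrame({
                    "gene_id": np.tile(ids, 2),
                    "bio_rep": b,
                    "tech_rep": tr,
                    "timepoint_min": t,
                    "channel": np.repeat(["sample", "reference"], n),
                    "intensity": np.concatenate([sample_chan, ref_chan]),
                }))
    spot_table = pd.concat(frames, ignore_index=True)

    qpcr_table = _simulate_qpcr(rng, ids, k, config)
    return SimulatedDataset(list(genes), spot_table, qpcr_table, config)


def _simulate_qpcr(
    rng: np.random.Generator,
    ids: np.ndarray,
    k: np.ndarray,
    config: SimulationConfig,
) -> pd.DataFrame:
    cols = ["gene_id", "genotype", "timepoint_min", "replicate",
            "relative_abundance"]
    if config.qpcr_n_reps == 0:
        return pd.DataFrame(columns=cols)
    d = config.parental_divergence
    geno_k = {"allo": k, "parentA": k * (1.0 - d), "parentB": k * (1.0 + d)}
    tps = np.asarray(config.timepoints, dtype=float)
    sd = config.qpcr_noise_sd_ln
    frames = []
    n = len(ids)
    for geno, kg in geno_k.items():
        for rep in range(1, config.qpcr_n_reps + 1):
            for t in tps:
                # mean-one lognormal noise keeps E[abundance at t0] = 1
                noise = np.exp(rng.normal(0.0, sd, n) - sd**2 / 2.0)
                frames.append(pd.DataFrame({
                    "gene_id": ids,
                    "genotype": geno,
                    "timepoint_min": t,
                    "replicate": rep,
                    "relative_abundance": np.exp(-kg * t) * noise,
                }))
    return pd.concat(frames, ignore_index=True)


def truth_frame(genes: Sequence[TrueGene]) -> pd.DataFrame:
    """Ground-truth table in the standard TSV layout."""
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "true_halflife_min": [g.true_halflife for g in genes],
        "true_k_per_min": [g.true_k for g in genes],
        "is_unstable": [g.is_unstable for g in genes],
        "nonadditive": [g.nonadditive for g in genes],
        "categories": [";".join(sorted(g.categories)) for g in genes],
    })


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset to a directory of plain-text files.

    Emits spots.tsv, qpcr.tsv, promoters.fasta, goslim.tsv,
    nonadditive_genes.txt and truth.tsv; all round-trip through the
    package readers.  Returns the file manifest.
    """
    from . import io as dio  # local import: io depends on nothing here

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": directory / "spots.tsv",
        "qpcr": directory / "qpcr.tsv",
        "promoters": directory / "promoters.fasta",
        "goslim": directory / "goslim.tsv",
        "nonadditive": directory / "nonadditive_genes.txt",
        "truth": directory / "truth.tsv",
    }
    dio.write_tsv(dataset.spot_table, paths["spots"])
    dio.write_tsv(dataset.qpcr_table, paths["qpcr"])
    dio.write_fasta(
        {g.gene_id: g.promoter for g in dataset.genes}, paths["promoters"]
    )
    rows = [
        {"gene_id": g.gene_id, "goslim_term": c}
        for g in dataset.genes
        for c in sorted(g.categories)
    ]
    dio.write_tsv(pd.DataFrame(rows, columns=["gene_id", "goslim_term"]),
                  paths["goslim"])
    dio.write_gene_list(
        [g.gene_id for g in dataset.genes if g.nonadditive], paths["nonadditive"]
    )
    dio.write_tsv(truth_frame(dataset.genes), paths["truth"])
    return paths


def simulate(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Convenience: catalog + measurements in one call."""
    config = replace(config or SimulationConfig(), **overrides)
    return simulate_measurements(generate_gene_catalog(config), config)
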