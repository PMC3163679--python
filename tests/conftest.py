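import numpy as np
import pandas as pd
import pytest

from decaykit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(n_genes=300, seed=11, nonadditive_coupling=1.0)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sd.SimulatedDataset:
    return sd.simulate(small_config)


@pytest.fixture(scope="session")
def genome_scale_run():
    """One genome-scale noisy shutoff experiment, fitted end to end.

    26,090 genes, ~0.8% unstable, two biological × two technical
    dye-swap replicates at 0 and 120 min, log2 ratio noise SD 0.15.
    Shared across the recovery-style tests because it is the expensive
    fixture.
    """
    from decaykit import array_processing as ap
    from decaykit import decay_kinetics as dk

    config = sd.SimulationConfig(
        n_genes=26090,
        fraction_unstable=0.008,
        timepoints=(0.0, 120.0),
        noise_sd_log2=0.15,
        n_bio_reps=2,
        n_tech_reps=2,
        nonadditive_coupling=1.0,
        enrichment_factor=3.0,
        qpcr_n_reps=0,
        seed=2024,
    )
    genes = sd.generate_gene_catalog(config)
    dataset = sd.simulate_measurements(genes, config)
    obs = ap.normalize_arrays(dataset.spot_table, method="none")
    changes = ap.temporal_ratios(obs, mode="per-timepoint-reference")
    mean_changes = (changes.groupby(["gene_id", "timepoint_min"], sort=True)
                    ["log2_change"].mean().reset_index())
    mean_changes["ratio"] = 2.0 ** mean_changes["log2_change"]
    t0 = mean_changes[["gene_id"]].drop_duplicates()
    t0["timepoint_min"] = 0.0
    t0["ratio"] = 1.0
    ratios = pd.concat(
        [t0, mean_changes[["gene_id", "timepoint_min", "ratio"]]],
        ignore_index=True)
    fits = dk.fit_many(ratios, ln2_constant=dk.LN2_EXACT)
    calls = dk.call_guts(fits)
    truth = sd.truth_frame(genes).set_index("gene_id")
    return {"config": config, "genes": genes, "dataset": dataset,
            "fits": fits, "calls": calls, "truth": truth}
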