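"""Normalization, dye-swap handling, replicate t-test and filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from decaykit import array_processing as ap


def _spot_table(rows):
    return pd.DataFrame(rows, columns=ap.SPOT_COLUMNS)


def _one_slide(sample_intensities, ref=1.0, tech_rep=1):
    rows = []
    for i, s in enumerate(sample_intensities):
        gid = f"AT1G{i:05d}"
        rows.append((gid, 1, tech_rep, 0.0, "sample", s))
        rows.append((gid, 1, tech_rep, 0.0, "reference", ref))
    return _spot_table(rows)


def test_median_centering_of_single_slide():
    obs = ap.normalize_arrays(_one_slide([2.0, 4.0, 8.0]), min_spots=3)
    assert sorted(obs["log2_ratio"]) == pytest.approx([-1.0, 0.0, 1.0])


def test_equal_intensities_center_to_zero():
    obs = ap.normalize_arrays(_one_slide([5.0] * 12))
    assert obs["log2_ratio"].to_numpy() == pytest.approx(np.zeros(12))


def test_normalization_is_idempotent():
    obs = ap.normalize_arrays(_one_slide([1.0, 2.0, 3.0, 4.0, 5.0]),
                              min_spots=5)
    rebuilt = _spot_table(
        [(g, 1, 1, 0.0, "sample", 2.0 ** r) for g, r in
         zip(obs["gene_id"], obs["log2_ratio"])]
        + [(g, 1, 1, 0.0, "reference", 1.0) for g in obs["gene_id"]])
    again = ap.normalize_arrays(rebuilt, min_spots=5)
    merged = obs.merge(again, on="gene_id", suffixes=("_1", "_2"))
    assert merged["log2_ratio_1"].to_numpy() == pytest.approx(
        merged["log2_ratio_2"].to_numpy())


def test_dye_swap_sign_flip_recovers_orientation():
    # forward slide measures +1.2; its dye swap measures −0.8 in dye
    # coordinates; after the flip, both estimate the biological ratio
    rows = []
    for tech, ratio in ((1, 1.2), (2, -0.8)):
        for i in range(10):
            gid = f"AT1G{i:05d}"
            r = ratio if i == 0 else 0.0
            rows.append((gid, 1, tech, 0.0, "sample", 2.0 ** r))
            rows.append((gid, 1, tech, 0.0, "reference", 1.0))
    obs = ap.normalize_arrays(_spot_table(rows), method="none")
    vals = obs[obs.gene_id == "AT1G00000"].sort_values("tech_rep")
    assert vals["log2_ratio"].tolist() == pytest.approx([1.2, 0.8])
    assert vals["log2_ratio"].mean() == pytest.approx(1.0)


def test_nonpositive_intensities_are_floored():
    table = _one_slide([3.0] * 11 + [0.0])
    obs = ap.normalize_arrays(table, method="none", floor_epsilon=1.0,
                              max_floored_fraction=0.6)
    g = obs[obs.gene_id == "AT1G00011"]
    assert g["log2_ratio"].iloc[0] == pytest.approx(0.0)  # log2(1/1)


def test_too_few_spots_is_an_error():
    with pytest.raises(ValueError, match="usable spots"):
        ap.normalize_arrays(_one_slide([1.0, 2.0]))


def test_replicate_t_test_examples():
    t, p, passed = ap.replicate_t_test([0.0, 0.0, 0.0, 0.0])
    assert (t, p, passed) == (0.0, 1.0, False)

    t, p, passed = ap.replicate_t_test([-2.1, -1.9, -2.0, -2.2])
    assert t == pytest.approx(-31.76, abs=0.01)
    assert p < 0.001 and passed

    t, p, passed = ap.replicate_t_test([5.0, -5.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    assert not passed


def test_replicate_t_test_degenerate_and_errors():
    t, p, passed = ap.replicate_t_test([1.5, 1.5, 1.5])
    assert math.isinf(t) and p == 0.0 and passed
    with pytest.raises(ValueError):
        ap.replicate_t_test([1.0])


def _summary(gene, mean, p, t=120.0):
    return {"gene_id": gene, "timepoint_min": t, "mean_log2_ratio": mean,
            "t": -10.0, "p": p, "n": 4, "passed": None}


def _summaries(records, fc):
    df = pd.DataFrame(records)
    df["passed"] = (df["p"] <= fc.alpha) & (
        df["mean_log2_ratio"].abs() >= math.log2(fc.min_fold))
    return df


def test_filter_requires_reproducibility_in_both_datasets():
    fc = ap.FilterConfig()
    d1 = _summaries([_summary("AT1G00010", -2.0, 1e-5),
                     _summary("AT1G00020", -2.0, 1e-5)], fc)
    d2 = _summaries([_summary("AT1G00010", -1.0, 1e-5),   # exactly 2-fold
                     _summary("AT1G00020", -0.26, 1e-5)], fc)  # 1.2-fold
    out = ap.filter_reproducible([d1, d2], fc)
    assert out["gene_id"].tolist() == ["AT1G00010"]  # inclusive threshold


def test_filter_empty_input_gives_empty_output():
    fc = ap.FilterConfig()
    empty = pd.DataFrame(
        columns=["gene_id", "timepoint_min", "mean_log2_ratio", "t", "p",
                 "n", "passed"])
    out = ap.filter_reproducible([empty, empty], fc)
    assert out.empty


def test_filter_monotone_in_alpha_and_fold():
    genes = [f"AT1G{i:05d}" for i in range(50)]
    def dataset(seed):
        r = np.random.default_rng(seed)
        return [
            _summary(g, float(r.normal(-1.2, 0.8)),
                     float(10 ** r.uniform(-6, 0)))
            for g in genes
        ]
    base = ap.FilterConfig(alpha=0.01, min_fold=2.0)
    stricter_alpha = ap.FilterConfig(alpha=0.001, min_fold=2.0)
    stricter_fold = ap.FilterConfig(alpha=0.01, min_fold=3.0)
    ds = [dataset(1), dataset(2)]
    kept = {fc: set(ap.filter_reproducible(
        [_summaries(d, fc) for d in ds], fc)["gene_id"])
        for fc in (base, stricter_alpha, stricter_fold)}
    assert kept[stricter_alpha] <= kept[base]
    assert kept[stricter_fold] <= kept[base]


def test_fast_summary_matches_reference_implementation():
    rng = np.random.default_rng(7)
    rows = []
    for g in range(12):
        for b in (1, 2):
            for tr in (1, 2):
                rows.append({
                    "gene_id": f"AT1G{g:05d}", "bio_rep": b, "tech_rep": tr,
                    "timepoint_min": 120.0,
                    "log2_change": float(rng.normal(-1, 0.5)),
                })
    changes = pd.DataFrame(rows)
    slow = ap.summarize_genes(changes)
    fast = ap.summarize_genes_fast(changes)
    merged = slow.merge(fast, on=["gene_id", "timepoint_min"],
                        suffixes=("_s", "_f"))
    for col in ("mean_log2_ratio", "t", "p"):
        assert merged[f"{col}_s"].to_numpy() == pytest.approx(
            merged[f"{col}_f"].to_numpy())
    assert (merged["passed_s"] == merged["passed_f"]).all()


def test_temporal_ratio_modes():
    rows = []
    for t, r in ((0.0, 0.4), (120.0, -1.6)):
        rows.append({"gene_id": "AT1G00001", "bio_rep": 1, "tech_rep": 1,
                     "timepoint_min": t, "log2_ratio": r})
    obs = pd.DataFrame(rows)
    per_ref = ap.temporal_ratios(obs, mode="per-timepoint-reference")
    assert per_ref["log2_change"].tolist() == pytest.approx([-2.0])
    direct = ap.temporal_ratios(obs, mode="timepoint-vs-timepoint")
    assert direct["log2_change"].tolist() == pytest.approx([-1.6])
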