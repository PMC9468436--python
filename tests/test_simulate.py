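"""Synthetic cohort generator: determinism, class structure, censoring."""

from dataclasses import replace

import numpy as np
import pytest
import scipy.stats

from fusionbalance.expression import expression_profile
from fusionbalance.qpcr_io import read_ct_table
from fusionbalance.simulate import (
    ALK_COMMON_MIX,
    CohortConfig,
    default_config,
    generate_cohort,
    write_cohort,
)

ALK_PAIR = ("ALK_ex9_10", "ALK_ex22_23")


def test_same_seed_same_bytes(tmp_path):
    config = default_config(seed=123).with_counts(
        ALK_fusion=15, ROS1_fusion=5, MET_ex14=2, EGFR_mut=8,
        RAS_mut_imbalanced=3, RAS_mut_plain=5, negative=40,
    )
    out_a, out_b = tmp_path / "a", tmp_path / "b"
    write_cohort(*generate_cohort(config), out_a)
    write_cohort(*generate_cohort(config), out_b)
    assert (out_a / "ct_table.csv").read_bytes() == (out_b / "ct_table.csv").read_bytes()
    assert (out_a / "truth.csv").read_bytes() == (out_b / "truth.csv").read_bytes()
    # and a different seed changes the data
    write_cohort(*generate_cohort(replace(config, seed=124)), tmp_path / "c")
    assert (out_a / "ct_table.csv").read_bytes() != (tmp_path / "c" / "ct_table.csv").read_bytes()


def test_class_counts_are_exact():
    config = default_config(seed=0).with_counts(
        ALK_fusion=7, ROS1_fusion=3, MET_ex14=0, EGFR_mut=2,
        RAS_mut_imbalanced=1, RAS_mut_plain=0, negative=11,
    )
    samples, truth = generate_cohort(config)
    assert len(samples) == 24
    counts = truth["true_class"].value_counts().to_dict()
    assert counts == {"negative": 11, "ALK_fusion": 7, "ROS1_fusion": 3,
                      "EGFR_mut": 2, "RAS_mut_imbalanced": 1}
    assert truth["sample_id"].is_unique


def test_all_negative_cohort():
    config = CohortConfig(n_per_class={"negative": 10}, seed=1)
    samples, truth = generate_cohort(config)
    assert len(samples) == 10
    assert (truth["true_class"] == "negative").all()
    assert (truth["implanted_variant"] == "").all()
    assert all(not s.variant_calls for s in samples)


def test_generated_csv_is_readable(tmp_path, small_cohort):
    samples, truth = small_cohort
    ct_path, _ = write_cohort(samples, truth, tmp_path)
    back = read_ct_table(ct_path)
    assert len(back) == len(samples)


def test_implanted_offset_separates_imbalance():
    """A class whose 3'-end offset is 6 cycles below the negatives' shows a
    higher mean ALK imbalance (one-sided Welch t at alpha = 0.001)."""
    config = default_config(seed=42).with_counts(
        ALK_fusion=200, ROS1_fusion=0, MET_ex14=0, EGFR_mut=0,
        RAS_mut_imbalanced=0, RAS_mut_plain=0, negative=200,
    )
    offsets = dict(config.assay_offsets)
    offsets[("ALK_fusion", "ALK_ex22_23")] = offsets[("negative", "ALK_ex22_23")] - 6
    config = replace(config, assay_offsets=offsets)
    samples, truth = generate_cohort(config)
    cls = truth.set_index("sample_id")["true_class"]
    imb = {
        "ALK_fusion": [], "negative": [],
    }
    for s in samples:
        imb[cls[s.sample_id]].append(expression_profile(s).imbalance[ALK_PAIR])
    t = scipy.stats.ttest_ind(imb["ALK_fusion"], imb["negative"],
                              equal_var=False, alternative="greater")
    assert t.pvalue < 1e-3
    assert np.mean(imb["ALK_fusion"]) > np.mean(imb["negative"])


def test_fusion_leaves_five_prime_assay_untouched():
    """Implanting an ALK fusion must not shift the 5'-end (exons 9-10)
    distribution — the fusion affects only transcripts downstream of the
    breakpoint."""
    config = default_config(seed=7).with_counts(
        ALK_fusion=300, ROS1_fusion=0, MET_ex14=0, EGFR_mut=0,
        RAS_mut_imbalanced=0, RAS_mut_plain=0, negative=300,
    )
    samples, truth = generate_cohort(config)
    cls = truth.set_index("sample_id")["true_class"]
    rel5 = {"ALK_fusion": [], "negative": []}
    for s in samples:
        if not s.ct["ALK_ex9_10"].censored and not s.ct["SDHA"].censored:
            rel5[cls[s.sample_id]].append(s.ct["ALK_ex9_10"].cycles - s.ct["SDHA"].cycles)
    res = scipy.stats.ks_2samp(rel5["ALK_fusion"], rel5["negative"])
    assert res.pvalue > 0.01  # same generating distribution


def test_censoring_monotone_in_rna_quality():
    """Later reference Cts (poorer RNA) push more assay reactions past the
    38-cycle detection limit."""
    fractions = []
    for mu in (24.0, 27.0, 30.0):
        config = replace(
            default_config(seed=5).with_counts(
                ALK_fusion=0, ROS1_fusion=0, MET_ex14=0, EGFR_mut=0,
                RAS_mut_imbalanced=0, RAS_mut_plain=0, negative=400,
            ),
            sdha_mu=mu,
        )
        samples, _ = generate_cohort(config)
        censored = sum(ct.censored for s in samples for ct in s.ct.values())
        fractions.append(censored / (len(samples) * 6))
    assert fractions[0] < fractions[1] < fractions[2]


def test_default_config_geometry():
    config = default_config()
    off = config.assay_offsets
    # fused ALK kinase domain at least 16-fold (4 cycles) above baseline
    assert off[("ALK_fusion", "ALK_ex22_23")] - off[("negative", "ALK_ex22_23")] <= -4
    # negatives are balanced by construction
    assert off[("negative", "ALK_ex9_10")] == off[("negative", "ALK_ex22_23")]
    assert off[("negative", "ROS1_ex17_18")] == off[("negative", "ROS1_ex38_39")]
    assert config.censor_at == 38.0


def test_variant_mix_and_rare_fraction():
    config = default_config(seed=9).with_counts(
        ALK_fusion=400, ROS1_fusion=0, MET_ex14=0, EGFR_mut=0,
        RAS_mut_imbalanced=0, RAS_mut_plain=0, negative=0,
    )
    samples, truth = generate_cohort(config)
    variants = truth["implanted_variant"]
    # the dominant junction dominates, as configured
    top = variants[variants.isin(ALK_COMMON_MIX)].value_counts()
    assert top.index[0] == "EML4-ALK (E13;A20)"
    # rare variants are implanted without a variant-specific PCR call
    rare_ids = set(truth.loc[~variants.isin(ALK_COMMON_MIX), "sample_id"])
    frac = len(rare_ids) / 400
    assert 0.02 < frac < 0.15
    for s in samples:
        assert bool(s.variant_calls) == (s.sample_id not in rare_ids)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(n_per_class={"weird": 3})
    with pytest.raises(ValueError):
        CohortConfig(n_per_class={"negative": -1})
    with pytest.raises(ValueError):
        CohortConfig(n_per_class={"negative": 1}, noise_sd=0.0)
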