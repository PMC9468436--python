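"""Seeded synthetic Ct cohorts with the structure the screen exploits.

The generator emulates an FFPE lung-cancer qPCR cohort at the level the
analysis needs, not at the level of PCR chemistry:

* per-sample RNA quantity/quality enters only through the reference-gene
  (SDHA) Ct, drawn once per sample; every other assay Ct is SDHA plus a
  class/assay mean offset, plus a per-sample *per-gene* biological term
  (shared by both ends of a gene, so it cancels in the imbalance), plus
  small independent per-reaction technical noise.  Imbalance is therefore
  quality-invariant by construction — the property the 5'/3' ratio test
  relies on — and much tighter than single-assay expression, which is why
  the dCt statistic screens well;
* an implanted fusion's overexpression has a per-sample magnitude (tumour
  cell content and expression heterogeneity vary), so fusion-positive
  samples show a spread of imbalances including a weak tail — the reason
  a calibrated cutoff, not perfect separation, is the realistic regime;
* ALK is essentially silent in fusion-negative lung tissue (large
  offsets, Cts near the detection limit, frequent censoring at 38),
  while ROS1 has an appreciable baseline;
* an implanted ALK fusion lowers the Ct of every amplicon *downstream*
  of its breakpoint (usually only the kinase-domain exons 22-23 assay),
  and never touches assays upstream of it;
* ROS1 fusions raise both transcript ends, with a clear extra 3' excess
  only for EZR/SLC34A2 partners; tumours driven by other tyrosine
  kinases (EGFR, ALK, MET) also show globally elevated ROS1;
* a RAS-mutant subgroup carries moderate ALK imbalance without any
  fusion — the confounder that makes reflex confirmation necessary.

All offset magnitudes are tuning constants chosen to reproduce the
qualitative group geometry of real cohorts (strong, cleanly separable
ALK signal; ambiguous ROS1 signal); they are not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .qpcr_io import (
    CENSOR_CT,
    DEFAULT_PANEL,
    FusionVariant,
    Panel,
    SampleRecord,
    cap_ct,
    parse_fusion_name,
    write_ct_table,
)

__all__ = ["CohortConfig", "default_config", "generate_cohort", "write_cohort"]

CLASSES = (
    "ALK_fusion",
    "ROS1_fusion",
    "MET_ex14",
    "EGFR_mut",
    "RAS_mut_imbalanced",
    "RAS_mut_plain",
    "negative",
)

# Common-variant mixes follow the relative frequencies seen in large
# EGFR-negative NSCLC collections (the dominant EML4-ALK E13;A20 near 46%).
ALK_COMMON_MIX = {
    "EML4-ALK (E13;A20)": 0.458,
    "EML4-ALK (E6;A20)": 0.383,
    "EML4-ALK (E20;A20)": 0.131,
    "EML4-ALK (E18;A20)": 0.028,
}
ALK_RARE_VARIANTS = (
    "EML4-ALK (E2;A20)",
    "KIF5B-ALK (K17;A20)",
    "DCTN1-ALK (D26;A20)",
    "EML4-ALK (E6ins33;A18)",
    "HIP1-ALK (H30;A20)",
)
ROS1_MIX = {
    "CD74-ROS1 (C6;R34)": 0.523,
    "SLC34A2-ROS1 (S13;R32)": 0.159,
    "EZR-ROS1 (E10;R34)": 0.114,
    "SDC4-ROS1 (S2;R32)": 0.068,
    "EZR-ROS1 (E10;R32)": 0.045,
    "TPM3-ROS1 (T8;R35)": 0.045,
    "SLC34A2-ROS1 (S4;R32)": 0.023,
    "TPM3-ROS1 (T10;R35)": 0.023,
}
#: ROS1 partners whose fusions show a clear 3'-end excess.
ROS1_IMBALANCED_PARTNERS = ("EZR", "SLC34A2")

# Demographics per class: (median age, fraction women, fraction never-smokers)
_DEMOGRAPHICS = {
    "ALK_fusion": (58, 0.64, 0.76),
    "ROS1_fusion": (59, 0.75, 0.80),
    "MET_ex14": (71, 0.65, 0.62),
    "EGFR_mut": (65, 0.78, 0.57),
    "RAS_mut_imbalanced": (63, 0.28, 0.45),
    "RAS_mut_plain": (63, 0.28, 0.45),
    "negative": (63, 0.28, 0.45),
}
_DRIVER_STATUS = {
    "ALK_fusion": "ALK",
    "ROS1_fusion": "ROS1",
    "MET_ex14": "MET_ex14",
    "EGFR_mut": "EGFR",
    "RAS_mut_imbalanced": "KRAS",
    "RAS_mut_plain": "KRAS",
    "negative": "none",
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort, deterministically.

    ``assay_offsets`` maps (class, assay) to the mean Ct offset of that
    assay relative to SDHA, in cycles (larger offset = later Ct = less
    transcript).  ``noise_sd`` is per-reaction technical noise; ``bio_sd``
    is per-sample-per-gene biological expression variability (shared by a
    gene's 5' and 3' assays); ``fusion_boost_sd`` spreads the per-sample
    magnitude of a fusion's 3'-end overexpression; ``sdha_mu`` /
    ``sdha_sd`` set the RNA quantity/quality distribution.
    """

    n_per_class: Mapping[str, int]
    sdha_mu: float = 26.0
    sdha_sd: float = 1.8
    noise_sd: float = 0.45
    bio_sd: float = 1.0
    fusion_boost_sd: float = 1.2
    censor_at: float = CENSOR_CT
    seed: int = 0
    assay_offsets: Mapping[tuple[str, str], float] = field(default_factory=dict)
    alk_rare_fraction: float = 0.07
    smoking_unknown_fraction: float = 0.55

    def __post_init__(self) -> None:
        for cls, n in self.n_per_class.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown cohort class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for class {cls!r}")
        if self.noise_sd <= 0 or self.sdha_sd <= 0:
            raise ValueError("noise_sd and sdha_sd must be positive")

    def with_counts(self, **counts: int) -> "CohortConfig":
        n = dict(self.n_per_class)
        n.update(counts)
        return replace(self, n_per_class=n)


# Baseline offsets (cycles above SDHA) for fusion-negative tissue.
_BASELINE = {
    "ALK_ex9_10": 9.0,
    "ALK_ex19_20": 9.0,
    "ALK_ex22_23": 9.0,
    "ROS1_ex17_18": 5.0,
    "ROS1_ex38_39": 5.0,
}
#: Ct offset of a fusion-driven ALK kinase-domain amplicon (4.5 cycles
#: below baseline ~ 23-fold overexpression).
_ALK_FUSED_3P = 4.5
#: Moderate fusion-independent ALK imbalance of the RAS-mutant subgroup.
_RAS_IMBALANCED_3P = 6.5
#: Globally elevated ROS1 in tumours driven by any tyrosine kinase.
_TK_ROS1 = 3.5
#: ROS1 in ROS1-rearranged tumours: both ends up ...
_ROS1_FUSED = 3.0
#: ... and for EZR/SLC34A2 partners the 3' end further up.
_ROS1_FUSED_3P_IMBALANCED = 1.5


def _default_offsets() -> dict[tuple[str, str], float]:
    offsets: dict[tuple[str, str], float] = {}
    for cls in CLASSES:
        for assay, base in _BASELINE.items():
            offsets[(cls, assay)] = base
    offsets[("ALK_fusion", "ALK_ex22_23")] = _ALK_FUSED_3P
    offsets[("RAS_mut_imbalanced", "ALK_ex22_23")] = _RAS_IMBALANCED_3P
    for cls in ("ALK_fusion", "EGFR_mut", "MET_ex14"):
        offsets[(cls, "ROS1_ex17_18")] = _TK_ROS1
        offsets[(cls, "ROS1_ex38_39")] = _TK_ROS1
    offsets[("ROS1_fusion", "ROS1_ex17_18")] = _ROS1_FUSED
    offsets[("ROS1_fusion", "ROS1_ex38_39")] = _ROS1_FUSED
    return offsets


def default_config(seed: int = 0) -> CohortConfig:
    """A study-sized default cohort: ~2150 samples dominated by negatives.

    Counts mirror the composition of a large EGFR-screened NSCLC referral
    series (about 5% ALK fusions, 2% ROS1 fusions, 1.5% MET exon-14,
    a sizeable RAS-mutant fraction, and EGFR-mutant samples retained as
    fusion-negative controls).
    """
    return CohortConfig(
        n_per_class={
            "ALK_fusion": 107,
            "ROS1_fusion": 44,
            "MET_ex14": 31,
            "EGFR_mut": 140,
            "RAS_mut_imbalanced": 21,
            "RAS_mut_plain": 380,
            "negative": 1426,
        },
        seed=seed,
        assay_offsets=_default_offsets(),
    )


def _sample_offsets(
    cls: str,
    variant: Optional[FusionVariant],
    offsets: Mapping[tuple[str, str], float],
    panel: Panel,
    rng: np.random.Generator,
    config: "CohortConfig",
) -> dict[str, float]:
    """Per-sample assay offsets: class means plus breakpoint-aware fusion boost.

    The fusion boost (how far the fused 3' end sits below its baseline)
    is drawn per sample around the class mean, floored at 0.3 cycles, and
    applied to every amplicon lying fully downstream of the breakpoint —
    never to amplicons upstream of it.
    """
    out = {assay: offsets.get((cls, assay), _BASELINE.get(assay, 0.0))
           for assay in panel.assay_names if assay != panel.reference.name}
    if variant is None:
        return out
    if variant.three_prime_gene == "ALK":
        base_boost = _BASELINE["ALK_ex22_23"] - offsets.get((cls, "ALK_ex22_23"), _ALK_FUSED_3P)
        boost = max(rng.normal(base_boost, config.fusion_boost_sd), 0.3)
        for assay in ("ALK_ex19_20", "ALK_ex22_23"):
            a = panel[assay]
            if a.exon_start is not None and a.exon_start >= variant.three_prime_exon:
                out[assay] = _BASELINE[assay] - boost
    elif variant.three_prime_gene == "ROS1":
        if variant.five_prime_gene in ROS1_IMBALANCED_PARTNERS:
            base_boost = out["ROS1_ex38_39"] - _ROS1_FUSED_3P_IMBALANCED
            boost = max(rng.normal(base_boost, config.fusion_boost_sd), 0.0)
            out["ROS1_ex38_39"] = out["ROS1_ex38_39"] - boost
    return out


def generate_cohort(
    config: CohortConfig, panel: Panel = DEFAULT_PANEL
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Generate samples and a truth table, deterministically from the seed.

    Class counts are allocated exactly as configured (not sampled), in a
    fixed class order, so truth-table frequencies are reproducible and
    power calculations in tests are deterministic.  The truth table has
    columns ``sample_id``, ``true_class``, ``implanted_variant``.
    """
    rng = np.random.default_rng(config.seed)
    offsets = dict(config.assay_offsets) if config.assay_offsets else _default_offsets()
    ref_name = panel.reference.name

    samples: list[SampleRecord] = []
    truth_rows: list[dict[str, str]] = []
    idx = 0
    for cls in CLASSES:
        n = int(config.n_per_class.get(cls, 0))
        for _ in range(n):
            idx += 1
            sid = f"S{idx:05d}"
            variant: Optional[FusionVariant] = None
            has_call = False
            if cls == "ALK_fusion":
                if rng.random() < config.alk_rare_fraction:
                    name = ALK_RARE_VARIANTS[rng.integers(len(ALK_RARE_VARIANTS))]
                else:
                    names = list(ALK_COMMON_MIX)
                    probs = np.array(list(ALK_COMMON_MIX.values()))
                    name = names[rng.choice(len(names), p=probs / probs.sum())]
                    has_call = True
                variant = parse_fusion_name(name)
            elif cls == "ROS1_fusion":
                names = list(ROS1_MIX)
                probs = np.array(list(ROS1_MIX.values()))
                name = names[rng.choice(len(names), p=probs / probs.sum())]
                variant = parse_fusion_name(name)
                has_call = True

            sdha_raw = rng.normal(config.sdha_mu, config.sdha_sd)
            ct = {ref_name: cap_ct(max(sdha_raw, 0.1) if sdha_raw < config.censor_at else None)}
            sample_offsets = _sample_offsets(cls, variant, offsets, panel, rng, config)
            genes = sorted({panel[a].gene for a in sample_offsets})
            bio = {g: rng.normal(0.0, config.bio_sd) for g in genes}
            for assay, off in sample_offsets.items():
                raw = (sdha_raw + off + bio[panel[assay].gene]
                       + rng.normal(0.0, config.noise_sd))
                ct[assay] = cap_ct(max(raw, 0.1) if raw < config.censor_at else None)

            med_age, f_women, f_never = _DEMOGRAPHICS[cls]
            age = float(np.clip(np.round(rng.normal(med_age, 9.0)), 16, 90))
            sex = "F" if rng.random() < f_women else "M"
            if rng.random() < config.smoking_unknown_fraction:
                smoking = ""
            else:
                smoking = "never" if rng.random() < f_never else "ever"
            cov: dict[str, object] = {"age": age, "sex": sex}
            if smoking:
                cov["smoking"] = smoking

            samples.append(
                SampleRecord(
                    sid,
                    ct,
                    variant_calls=(variant,) if (variant is not None and has_call) else (),
                    driver_status=_DRIVER_STATUS[cls],
                    covariates=cov,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "true_class": cls,
                    "implanted_variant": variant.canonical_name() if variant else "",
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "true_class", "implanted_variant"])
    return samples, truth


def write_cohort(
    samples: list[SampleRecord],
    truth: pd.DataFrame,
    directory: str | Path,
    panel: Panel = DEFAULT_PANEL,
) -> tuple[Path, Path]:
    """Write ``ct_table.csv`` (the format qpcr_io reads) and ``truth.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ct_path = directory / "ct_table.csv"
    truth_path = directory / "truth.csv"
    write_ct_table(samples, ct_path, panel=panel)
    truth.to_csv(truth_path, index=False)
    return ct_path, truth_path
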