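"""End-to-end screening workflow and cohort-level reporting.

Stage order (fixed):

1. **QC** — samples whose reference-gene signal appears at cycle 36 or
   later are set aside as ``qc_fail`` and excluded from the screening
   denominator (a config switch restores them to the denominator).
2. **Variant-specific PCR** — samples with an identified fusion call are
   ``fusion_detected`` and are *not* passed to the expression classifier.
3. **Expression classifier** — the calibrated union of ALK logistic
   models runs on the remainder; flagged samples are
   ``expression_flagged_reflex_recommended`` (confirmation by another
   method, e.g. NGS/FISH, is required before reporting a fusion).
4. **ROS1 rule** — the fixed dCt > 2 triage rule is evaluated
   independently for every evaluable sample; it determines the primary
   status only for samples not already claimed by an earlier stage.

Cohort summaries use half-away-from-zero rounding at one decimal, the
convention of clinical frequency tables.  No multiple-testing adjustment
is applied to the association tests; the screen is exploratory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import stats
from .classifier import (
    ALK_NARROW_SPEC,
    ALK_WIDE_SPEC,
    ROS1_DELTA_CT_THRESHOLD,
    ROS1_PAIR,
    ScreeningDecision,
    UnbalanceModel,
    calibrate_cutoff,
    classify,
    fit_logistic,
    ros1_flag,
)
from .expression import ExpressionProfile, expression_profile
from .qpcr_io import DEFAULT_PANEL, Panel, SampleRecord, qc_evaluable

__all__ = [
    "ScreenConfig",
    "ScreeningReport",
    "ConfigurationError",
    "STATUSES",
    "train_alk_models",
    "run_screen",
    "cohort_summary",
    "association_tests",
    "cooccurrence_proportion",
]

STATUSES = (
    "qc_fail",
    "fusion_detected",
    "expression_flagged_reflex_recommended",
    "ros1_flagged",
    "negative",
)


class ConfigurationError(ValueError):
    """The pipeline cannot run as configured (e.g. no models, no labels)."""


@dataclass(frozen=True)
class ScreenConfig:
    """Pipeline configuration; defaults reproduce the standard screen."""

    panel: Panel = DEFAULT_PANEL
    target_sensitivity: float = 0.95
    ros1_threshold: float = ROS1_DELTA_CT_THRESHOLD
    #: driver statuses treated as fusion-negative controls when training
    negative_driver_statuses: tuple[str, ...] = ("EGFR", "ROS1", "MET_ex14")
    include_qc_failed_in_denominator: bool = False
    fisher_resamples: int = 100_000
    seed: int = 0


@dataclass(frozen=True)
class ScreeningReport:
    """Per-sample triage table plus the models and configuration used.

    ``samples`` has one row per input sample with its primary status
    (mutually exclusive; see module docstring for precedence), per-model
    probabilities and the independent ROS1 flag.
    """

    samples: pd.DataFrame
    models: tuple[UnbalanceModel, ...]
    config: ScreenConfig
    trained_here: bool = False

    @property
    def evaluable(self) -> pd.DataFrame:
        return self.samples[self.samples["status"] != "qc_fail"]


def train_alk_models(
    profiles: Sequence[ExpressionProfile],
    labels: Sequence[int | bool],
    target_sensitivity: float = 0.95,
) -> tuple[UnbalanceModel, UnbalanceModel]:
    """Fit and calibrate both ALK models on labelled expression profiles.

    The wide model pairs exons 9-10 with 22-23; the narrow model pairs
    19-20 with 22-23.  Each cutoff is calibrated on the positives to the
    target training sensitivity (default 95%).
    """
    y = np.asarray([bool(v) for v in labels])
    models = []
    for name, spec in (("alk_wide", ALK_WIDE_SPEC), ("alk_narrow", ALK_NARROW_SPEC)):
        feats = np.asarray([spec.features(p) for p in profiles], dtype=float)
        model = fit_logistic(features=feats, labels=y.astype(float), spec=spec, name=name)
        model = calibrate_cutoff(model, feats[y], target_sensitivity)
        models.append(model)
    return tuple(models)


def _training_sets(
    samples: Sequence[SampleRecord],
    profiles: Mapping[str, ExpressionProfile],
    qc: Mapping[str, bool],
    config: ScreenConfig,
) -> tuple[list[ExpressionProfile], list[bool]]:
    """Training data mirroring the study design: variant-call-positive ALK
    samples are positives; samples driven by other kinases are negatives."""
    profs: list[ExpressionProfile] = []
    labels: list[bool] = []
    for s in samples:
        if not qc[s.sample_id]:
            continue
        has_alk_call = any(v.three_prime_gene == "ALK" for v in s.variant_calls)
        has_ros1_call = any(v.three_prime_gene == "ROS1" for v in s.variant_calls)
        if has_alk_call:
            profs.append(profiles[s.sample_id])
            labels.append(True)
        elif has_ros1_call or (s.driver_status in config.negative_driver_statuses):
            profs.append(profiles[s.sample_id])
            labels.append(False)
    return profs, labels


def run_screen(
    samples: Sequence[SampleRecord],
    models: Optional[Sequence[UnbalanceModel]] = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreeningReport:
    """Run the full screen; train the ALK models in place if none are given.

    Without pre-fitted models, training requires variant-call positives and
    kinase-driven negative controls within the cohort itself; otherwise a
    :class:`ConfigurationError` is raised.
    """
    panel = config.panel
    qc = {s.sample_id: qc_evaluable(s, panel) for s in samples}
    profiles = {s.sample_id: expression_profile(s, panel) for s in samples if qc[s.sample_id]}

    trained_here = False
    if models is None:
        profs, labels = _training_sets(samples, profiles, qc, config)
        n_pos = sum(labels)
        if n_pos < 3 or n_pos == len(labels) or not labels:
            raise ConfigurationError(
                "no calibrated models supplied and the cohort lacks enough "
                f"labelled training samples ({n_pos} positives / {len(labels)} labelled)"
            )
        models = train_alk_models(profs, labels, config.target_sensitivity)
        trained_here = True
    models = tuple(models)

    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "qc_pass": qc[s.sample_id],
            "variant_call": "|".join(v.canonical_name() for v in s.variant_calls),
            "driver_status": s.driver_status or "",
            "age": s.covariates.get("age", np.nan),
            "sex": s.covariates.get("sex", ""),
            "smoking": s.covariates.get("smoking", ""),
        }
        if not qc[s.sample_id]:
            row["status"] = "qc_fail"
            for m in models:
                row[f"p_{m.name}"] = np.nan
                row[f"flag_{m.name}"] = None
            row.update(alk_union_flag=None, ros1_delta_ct=np.nan, ros1_flag=None)
            rows.append(row)
            continue

        profile = profiles[s.sample_id]
        r_flag = ros1_flag(profile, config.ros1_threshold)
        row["ros1_delta_ct"] = profile.imbalance[ROS1_PAIR]
        row["ros1_flag"] = r_flag

        if s.variant_calls:
            # stage precedence: a variant-specific call short-circuits the classifier
            row["status"] = "fusion_detected"
            for m in models:
                row[f"p_{m.name}"] = np.nan
                row[f"flag_{m.name}"] = None
            row["alk_union_flag"] = None
        else:
            decision = classify(models, profile, qc_pass=True)
            for m in models:
                row[f"p_{m.name}"] = decision.probabilities[m.name]
                row[f"flag_{m.name}"] = decision.flags[m.name]
            row["alk_union_flag"] = decision.overall
            if decision.overall:
                row["status"] = "expression_flagged_reflex_recommended"
            elif r_flag:
                row["status"] = "ros1_flagged"
            else:
                row["status"] = "negative"
        rows.append(row)

    df = pd.DataFrame(rows)
    return ScreeningReport(df, models, config, trained_here)


def cohort_summary(report: ScreeningReport) -> dict[str, pd.DataFrame]:
    """Frequency tables: triage statuses, per-gene fusion yield, variant mix.

    Percentages are over evaluable samples (or all samples if QC failures
    are configured into the denominator) and are rounded half-away-from-zero
    to one decimal; within-gene variant percentages use the gene's fusion
    count as denominator.
    """
    df = report.samples
    if df.empty:
        raise ValueError("empty cohort")
    denom_df = df if report.config.include_qc_failed_in_denominator else report.evaluable
    denom = len(denom_df)
    if denom == 0:
        raise ValueError("no evaluable samples")

    status_rows = [
        {"status": st, "count": int((df["status"] == st).sum()),
         "percent": stats.percent(int((df["status"] == st).sum()), len(df))}
        for st in STATUSES
    ]
    status_df = pd.DataFrame(status_rows)

    calls = denom_df.loc[denom_df["variant_call"] != "", "variant_call"]
    per_variant: dict[str, int] = {}
    per_gene: dict[str, int] = {}
    for cell in calls:
        for name in cell.split("|"):
            per_variant[name] = per_variant.get(name, 0) + 1
            gene = name.split("-")[1].split(" ")[0]
            per_gene[gene] = per_gene.get(gene, 0) + 1
    gene_df = pd.DataFrame(
        [
            {"gene": g, "count": c, "percent": stats.percent(c, denom)}
            for g, c in sorted(per_gene.items())
        ],
        columns=["gene", "count", "percent"],
    )
    variant_df = pd.DataFrame(
        [
            {
                "variant": v,
                "gene": v.split("-")[1].split(" ")[0],
                "count": c,
                "percent_within_gene": stats.percent(c, per_gene[v.split("-")[1].split(" ")[0]]),
            }
            for v, c in sorted(per_variant.items())
        ],
        columns=["variant", "gene", "count", "percent_within_gene"],
    )
    flagged = int((denom_df["status"] == "expression_flagged_reflex_recommended").sum())
    screen_df = pd.DataFrame(
        [
            {"quantity": "evaluable_samples", "count": denom, "percent": 100.0},
            {"quantity": "expression_flagged", "count": flagged,
             "percent": stats.percent(flagged, denom)},
            {"quantity": "ros1_flagged_rule", "count": int(denom_df["ros1_flag"].fillna(False).sum()),
             "percent": stats.percent(int(denom_df["ros1_flag"].fillna(False).sum()), denom)},
        ]
    )
    return {"statuses": status_df, "genes": gene_df, "variants": variant_df, "screen": screen_df}


def association_tests(
    samples_df: pd.DataFrame,
    group_col: str = "driver_status",
    config: ScreenConfig = ScreenConfig(),
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Clinical-covariate association tests across driver groups.

    * sex x group: chi-squared test on the contingency table;
    * smoking x group: Fisher's exact test (exact for 2x2; seeded
      Monte-Carlo with ``config.fisher_resamples`` tables otherwise);
    * age: Kruskal-Wallis rank test across groups.

    ``groups`` restricts and orders the compared groups (default: every
    non-empty label present in the data).  A requested group with zero
    samples is dropped with a warning.  Rows with missing values for a
    covariate are excluded from that test only.
    """
    df = samples_df.copy()
    if groups is None:
        groups = [g for g in df[group_col].unique() if g not in ("", None)]
    else:
        groups = list(groups)
    dropped = [g for g in groups if df[df[group_col] == g].empty]
    for g in dropped:
        warnings.warn(f"group {g!r} has no samples and was dropped", UserWarning, stacklevel=2)
    groups = [g for g in groups if g not in dropped]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")

    results = []

    if "sex" in df.columns:
        sub = df[df["sex"].isin(["M", "F"]) & df[group_col].isin(groups)]
        tab = pd.crosstab(sub["sex"], sub[group_col])
        tab = tab.loc[:, (tab.sum(axis=0) > 0)]
        if tab.shape[0] == 2 and tab.shape[1] >= 2:
            chi2 = scipy.stats.chi2_contingency(tab.to_numpy())
            results.append(
                {"covariate": "sex", "test": "chi-squared",
                 "statistic": float(chi2.statistic), "p_value": float(chi2.pvalue)}
            )

    if "smoking" in df.columns:
        sub = df[df["smoking"].isin(["ever", "never"]) & df[group_col].isin(groups)]
        tab = pd.crosstab(sub["smoking"], sub[group_col])
        tab = tab.loc[:, (tab.sum(axis=0) > 0)]
        if tab.shape[0] == 2 and tab.shape[1] >= 2:
            arr = tab.to_numpy()
            if arr.shape == (2, 2):
                p = float(scipy.stats.fisher_exact(arr).pvalue)
                test = "fisher_exact"
            else:
                p = stats.fisher_exact_mc(
                    arr, n_resamples=config.fisher_resamples, seed=config.seed
                )
                test = f"fisher_exact_mc({config.fisher_resamples})"
            results.append(
                {"covariate": "smoking", "test": test, "statistic": np.nan, "p_value": p}
            )

    if "age" in df.columns:
        arrays = []
        for g in groups:
            vals = pd.to_numeric(df.loc[df[group_col] == g, "age"], errors="coerce").dropna()
            if len(vals):
                arrays.append(vals.to_numpy())
        if len(arrays) >= 2:
            kw = scipy.stats.kruskal(*arrays)
            results.append(
                {"covariate": "age", "test": "kruskal-wallis",
                 "statistic": float(kw.statistic), "p_value": float(kw.pvalue)}
            )
    return pd.DataFrame(results, columns=["covariate", "test", "statistic", "p_value"])


@dataclass(frozen=True)
class CooccurrenceResult:
    count: int
    total: int
    percent: float  # whole-percent, half-away-from-zero
    ci_low: float  # Clopper-Pearson 95% bounds, in percent
    ci_high: float


def cooccurrence_proportion(flags: Sequence[bool]) -> CooccurrenceResult:
    """Proportion of expression-flagged, fusion-negative samples carrying a
    given co-mutation (e.g. KRAS/NRAS), with an exact binomial 95% CI.

    ``flags`` holds one boolean per sample in the denominator group.
    """
    flags = [bool(f) for f in flags]
    total = len(flags)
    if total == 0:
        raise ValueError("empty denominator")
    count = sum(flags)
    lo, hi = stats.clopper_pearson(count, total)
    return CooccurrenceResult(
        count=count,
        total=total,
        percent=stats.percent(count, total, ndigits=0),
        ci_low=100 * lo,
        ci_high=100 * hi,
    )
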