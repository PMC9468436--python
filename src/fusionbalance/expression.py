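"""Reference-normalised expression and 5'/3'-end imbalance statistics.

All quantities are plain Ct differences, i.e. log2 expression ratios:

* relative expression of an assay = ``Ct(SDHA) - Ct(assay)``, so larger
  means more transcript (a value of +3 is 8-fold above the reference);
* the imbalance statistic of a gene = ``Ct(5' assay) - Ct(3' assay)``
  (``dCt``), positive when the 3' (kinase-domain) end is overexpressed —
  the expected signature of an oncogenic fusion.

Because both statistics are differences of Cts measured on the same cDNA,
adding a constant to every Ct of a sample (RNA quantity/quality) leaves
the imbalance unchanged; that invariance is what makes the 5'/3' ratio a
usable screen on degraded FFPE material.

Censored Cts (capped at cycle 38) propagate as *flagged bounds* rather
than missing values: the numeric result is kept, and a censor flag marks
it as a bound, so downstream classification never silently drops samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .qpcr_io import CtValue, Panel, DEFAULT_PANEL, SampleRecord
from .stats import mean_half_away

__all__ = [
    "relative_expression",
    "imbalance_delta_ct",
    "ExpressionProfile",
    "expression_profile",
    "ShiftSummary",
    "paired_shift_summary",
]


def relative_expression(ct_target: CtValue, ct_ref: CtValue) -> tuple[float, bool]:
    """log2 expression of a target relative to the reference gene.

    Returns ``(ct_ref.cycles - ct_target.cycles, flag)``; the flag is set
    when either input is censored, in which case the value is a bound on
    expression rather than an estimate.
    """
    value = ct_ref.cycles - ct_target.cycles
    return value, ct_target.censored or ct_ref.censored


def imbalance_delta_ct(ct_5prime: CtValue, ct_3prime: CtValue) -> tuple[float, bool]:
    """5'/3'-end imbalance ``dCt = Ct(5') - Ct(3')``.

    Positive values mean the 3' end is overexpressed (a dCt of +4 is a
    16-fold excess).  The flag is set when either Ct is censored; a
    censored 5' end makes the value a lower bound on the true imbalance.
    """
    value = ct_5prime.cycles - ct_3prime.cycles
    return value, ct_5prime.censored or ct_3prime.censored


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-sample expression summary derived from one :class:`SampleRecord`.

    ``rel_expr`` maps each assay to its log2 expression relative to the
    reference (the reference maps to 0 by construction); ``imbalance``
    maps each (5'-assay, 3'-assay) panel pair to its dCt.  ``censor_flags``
    marks every entry that involved a censored Ct.
    """

    sample_id: str
    rel_expr: Mapping[str, float]
    imbalance: Mapping[tuple[str, str], float]
    censor_flags: Mapping[object, bool]


def expression_profile(sample: SampleRecord, panel: Panel = DEFAULT_PANEL) -> ExpressionProfile:
    """Compute relative expression and all panel 5'/3' imbalances for a sample."""
    ref_name = panel.reference.name
    ref = sample.ct[ref_name]
    rel: dict[str, float] = {}
    flags: dict[object, bool] = {}
    for assay in panel.assay_names:
        value, flag = relative_expression(sample.ct[assay], ref)
        rel[assay] = value
        flags[assay] = flag
    imb: dict[tuple[str, str], float] = {}
    for five, three in panel.pairs():
        value, flag = imbalance_delta_ct(sample.ct[five], sample.ct[three])
        imb[(five, three)] = value
        flags[(five, three)] = flag
    return ExpressionProfile(sample.sample_id, rel, imb, flags)


@dataclass(frozen=True)
class ShiftSummary:
    """Median (range) of paired Ct shifts per assay, plus their grand mean.

    Used to compare protocol variants (e.g. reverse-transcription priming
    strategies) across a panel: each assay contributes the median of its
    per-sample paired Ct differences, and ``grand_mean`` averages those
    medians.  ``grand_mean_1dp`` is the reporting value, rounded
    half-away-from-zero to one decimal.
    """

    per_assay: Mapping[str, tuple[float, float, float]]  # median, min, max
    grand_mean: float
    grand_mean_1dp: float


def paired_shift_summary(paired_diffs: Mapping[str, Sequence[float]]) -> ShiftSummary:
    """Summarise paired Ct differences per assay.

    ``paired_diffs`` maps an assay name to the per-sample Ct differences
    between two protocols.  An empty list raises a ValueError naming the
    assay.
    """
    per_assay: dict[str, tuple[float, float, float]] = {}
    medians: list[float] = []
    for assay, diffs in paired_diffs.items():
        arr = np.asarray(list(diffs), dtype=float)
        if arr.size == 0:
            raise ValueError(f"no paired differences for assay {assay!r}")
        med = float(np.median(arr))
        per_assay[assay] = (med, float(arr.min()), float(arr.max()))
        medians.append(med)
    grand = float(np.mean(medians))
    return ShiftSummary(per_assay, grand, mean_half_away(medians, 1))
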