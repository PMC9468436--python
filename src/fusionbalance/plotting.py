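"""Diagnostic plots for the expression screen.

These are exploratory views, not publication figures: the decision
scatter shows each model's predictor plane with its calibrated
iso-probability cutoff line, and the gene-expression strip plot shows
per-group 5'/3' relative expression on the log2 (negative dCt) scale.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt

from .classifier import UnbalanceModel
from .expression import ExpressionProfile

__all__ = ["plot_decision_scatter", "plot_group_expression"]


def plot_decision_scatter(
    model: UnbalanceModel,
    profiles: Sequence[ExpressionProfile],
    labels: Sequence[bool],
    ax: Optional[plt.Axes] = None,
):
    """Scatter of (3'-end expression, 5'/3' imbalance) with the cutoff line.

    The line is the iso-probability contour ``p = cutoff`` of the fitted
    logistic model; points above/right of it are flagged.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    feats = np.asarray([model.spec.features(p) for p in profiles], dtype=float)
    y = np.asarray([bool(v) for v in labels])
    ax.scatter(feats[~y, 0], feats[~y, 1], s=10, c="tab:green", alpha=0.5, label="fusion-negative")
    ax.scatter(feats[y, 0], feats[y, 1], s=12, c="m", alpha=0.8, label="fusion-positive")
    if model.cutoff is not None and model.coef_imbalance != 0:
        logit_tau = np.log(model.cutoff / (1 - model.cutoff)) if 0 < model.cutoff < 1 else None
        if logit_tau is not None:
            xs = np.linspace(feats[:, 0].min(), feats[:, 0].max(), 50)
            ys = (logit_tau - model.intercept - model.coef_expr * xs) / model.coef_imbalance
            ax.plot(xs, ys, "k--", lw=1, label=f"cutoff p = {model.cutoff:.3g}")
    ax.set_xlabel(f"log2 expression of {model.spec.three_prime_assay} vs reference")
    ax.set_ylabel(
        f"dCt {model.spec.five_prime_assay} - {model.spec.three_prime_assay} (cycles)"
    )
    ax.set_title(model.name)
    ax.legend(fontsize=7)
    return ax


def plot_group_expression(
    profiles: Sequence[ExpressionProfile],
    groups: Sequence[str],
    assay: str,
    ax: Optional[plt.Axes] = None,
):
    """Strip plot of one assay's relative expression (log2) by sample group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    groups = list(groups)
    order = sorted(set(groups))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, g in enumerate(order):
        vals = np.asarray([p.rel_expr[assay] for p, gg in zip(profiles, groups) if gg == g])
        ax.scatter(i + rng.uniform(-0.2, 0.2, size=vals.size), vals, s=8, alpha=0.6)
    ax.set_xticks(range(len(order)), order, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(f"log2 expression of {assay} vs reference")
    return ax
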