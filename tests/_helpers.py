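"""Independent oracles and cohort-building helpers shared by the tests.

Everything here is deliberately implemented apart from the package's own
code paths: the grid-search likelihood maximiser checks the IRLS fit, and
the hypergeometric enumeration checks the Fisher test route.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def grid_search_logistic(
    X: np.ndarray,
    y: np.ndarray,
    half_width: float = 10.0,
    points: int = 21,
    levels: int = 6,
) -> np.ndarray:
    """Coarse-to-fine grid maximiser of the binomial log-likelihood.

    Searches (b0, b1, b2) over a shrinking box centred on the running
    best; the likelihood is concave, so the refinement converges to the
    global optimum whenever it lies inside the initial box.  Final grid
    step is ~3e-4, well inside the 1e-3 comparison tolerance.
    """
    Xd = np.column_stack([np.ones(len(y)), X])
    y = np.asarray(y, dtype=float)

    def ll(betas: np.ndarray) -> np.ndarray:
        eta = betas @ Xd.T  # (G, n)
        return -(
            np.logaddexp(0.0, -eta[:, y == 1]).sum(axis=1)
            + np.logaddexp(0.0, eta[:, y == 0]).sum(axis=1)
        )

    center = np.zeros(3)
    hw = half_width
    for _ in range(levels):
        axes = [np.linspace(c - hw, c + hw, points) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        center = grid[np.argmax(ll(grid))]
        step = 2 * hw / (points - 1)
        hw = 2 * step
    return center


def fisher_2x2_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full enumeration of the 2x2 support."""
    table = np.asarray(table, dtype=int)
    r1, c1 = table[0].sum(), table[:, 0].sum()
    n = table.sum()
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table[0, 0])
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def training_cohort(seed: int, n_pos: int = 250, n_neg: int = 2000):
    """ALK-fusion positives vs clean negatives, as expression profiles.

    Returns (profiles, labels) for QC-passing samples.
    """
    from fusionbalance.expression import expression_profile
    from fusionbalance.qpcr_io import qc_evaluable
    from fusionbalance.simulate import default_config, generate_cohort

    config = default_config(seed=seed).with_counts(
        ALK_fusion=n_pos,
        ROS1_fusion=0,
        MET_ex14=0,
        EGFR_mut=0,
        RAS_mut_imbalanced=0,
        RAS_mut_plain=0,
        negative=n_neg,
    )
    samples, truth = generate_cohort(config)
    is_pos = (truth.set_index("sample_id")["true_class"] == "ALK_fusion").to_dict()
    profiles, labels = [], []
    for s in samples:
        if qc_evaluable(s):
            profiles.append(expression_profile(s))
            labels.append(is_pos[s.sample_id])
    return profiles, np.asarray(labels, dtype=bool)
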