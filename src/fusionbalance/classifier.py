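"""Fusion screening by logistic classification of 5'/3' expression imbalance.

Two binomial logistic models are fitted for ALK, one per 5' amplicon,
each with the same two predictors:

* ``x1`` — kinase-domain (3'-end) expression relative to the reference
  gene, ``Ct(SDHA) - Ct(3' assay)``;
* ``x2`` — the 5'/3' imbalance ``dCt = Ct(5' assay) - Ct(3' assay)``.

High 3'-end expression alone can indicate a fusion even with balanced
ends, while moderate imbalance at very low kinase-domain expression
rarely does; using both predictors encodes exactly that.

Each model's probability cutoff is calibrated on the training positives
to the *lowest* threshold count that still classifies a target fraction
(default 95%) of them correctly — i.e. the cutoff maximises specificity
subject to a floor on training sensitivity.  A sample is screen-positive
when flagged by at least one model (union rule).

For ROS1, where fusions raise both transcript ends and a discriminative
model is not attainable, only a fixed imbalance rule (``dCt > 2``) is
provided for triage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .expression import ExpressionProfile

__all__ = [
    "PredictorSpec",
    "UnbalanceModel",
    "ScreeningDecision",
    "SeparationWarning",
    "fit_logistic",
    "calibrate_cutoff",
    "calibrate_threshold",
    "classify",
    "ros1_flag",
    "evaluate",
    "save_models",
    "load_models",
    "ALK_WIDE_SPEC",
    "ALK_NARROW_SPEC",
    "ROS1_PAIR",
    "ROS1_DELTA_CT_THRESHOLD",
]

#: Fixed triage rule for ROS1: flag when dCt(5',3') exceeds this, strictly.
ROS1_DELTA_CT_THRESHOLD = 2.0
ROS1_PAIR = ("ROS1_ex17_18", "ROS1_ex38_39")

RIDGE_LAMBDA = 1e-6
GRADIENT_TOL = 1e-8


class SeparationWarning(UserWarning):
    """The classes were perfectly separable; a small ridge penalty was used."""


@dataclass(frozen=True)
class PredictorSpec:
    """The assay pair defining a model's predictors."""

    three_prime_assay: str
    five_prime_assay: str

    def features(self, profile: ExpressionProfile) -> tuple[float, float]:
        x1 = profile.rel_expr[self.three_prime_assay]
        x2 = profile.imbalance[(self.five_prime_assay, self.three_prime_assay)]
        return x1, x2


#: Wide-span ALK model: exons 9-10 vs 22-23 — covers any breakpoint but is
#: more exposed to rearrangement-independent imbalance (e.g. splicing).
ALK_WIDE_SPEC = PredictorSpec("ALK_ex22_23", "ALK_ex9_10")
#: Narrow-span ALK model: exons 19-20 vs 22-23 — less artifact-prone but
#: blind to breakpoints upstream of exon 19.
ALK_NARROW_SPEC = PredictorSpec("ALK_ex22_23", "ALK_ex19_20")


@dataclass(frozen=True)
class UnbalanceModel:
    """A fitted two-predictor logistic screen with an optional calibrated cutoff.

    ``p = expit(intercept + coef_expr * x1 + coef_imbalance * x2)``; the
    sample is flagged when ``p >= cutoff``.
    """

    name: str
    spec: PredictorSpec
    intercept: float
    coef_expr: float
    coef_imbalance: float
    cutoff: Optional[float] = None
    target_sensitivity: Optional[float] = None
    n_obs: int = 0
    log_likelihood: float = math.nan
    null_log_likelihood: float = math.nan
    converged: bool = True
    separation: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.intercept, self.coef_expr, self.coef_imbalance])

    def predict_proba(self, x1, x2) -> np.ndarray:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        return expit(self.intercept + self.coef_expr * x1 + self.coef_imbalance * x2)

    def probability(self, profile: ExpressionProfile) -> float:
        x1, x2 = self.spec.features(profile)
        return float(self.predict_proba(x1, x2))

    def flag(self, profile: ExpressionProfile) -> bool:
        if self.cutoff is None:
            raise ValueError(f"model {self.name!r} has no calibrated cutoff")
        return self.probability(profile) >= self.cutoff


def _log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = np.clip(X @ beta, -700, 700)
    # log p and log(1-p) in a numerically safe form
    return float(-(np.logaddexp(0.0, -eta)[y == 1].sum() + np.logaddexp(0.0, eta)[y == 0].sum()))


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, lam: float = RIDGE_LAMBDA, tol: float = GRADIENT_TOL,
    maxiter: int = 500,
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for the ridge-penalised binomial likelihood.

    The penalty ``lam/2 * (b1^2 + b2^2)`` acts on the slopes only, keeping
    the intercept free; it exists to make the optimum finite under perfect
    separation and is small enough (1e-6) to be irrelevant otherwise.
    """
    pen = np.diag([0.0, lam, lam])
    beta = np.zeros(X.shape[1])

    def pll(b: np.ndarray) -> float:
        return _log_likelihood(b, X, y) - 0.5 * lam * float(b[1] ** 2 + b[2] ** 2)

    current = pll(beta)
    converged = False
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        p = expit(eta)
        grad = X.T @ (y - p) - pen @ beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = np.maximum(p * (1 - p), 1e-12)
        hess = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(hess, grad)
        # damped update: halve until the penalised likelihood improves
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            val = pll(cand)
            if val >= current - 1e-12:
                beta, current = cand, val
                break
            scale /= 2
        else:  # pragma: no cover - pathological
            break
    return beta, converged


def fit_logistic(
    observations: Sequence[tuple[float, float, int]] | None = None,
    *,
    features: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    spec: PredictorSpec = ALK_WIDE_SPEC,
    name: str = "model",
) -> UnbalanceModel:
    """Fit the two-predictor binomial logistic model by maximum likelihood.

    ``observations`` is a sequence of ``(x1, x2, label)`` triples (labels
    0/1 or bool); alternatively pass ``features`` (n x 2) and ``labels``.
    Requires n >= 3 and both classes present.  Under perfect separation
    the unpenalised optimum does not exist; the fit then falls back to a
    tiny ridge penalty on the slopes and emits :class:`SeparationWarning`.
    """
    if observations is not None:
        arr = np.asarray([(a, b, int(c)) for a, b, c in observations], dtype=float)
        features = arr[:, :2]
        labels = arr[:, 2]
    if features is None or labels is None:
        raise ValueError("provide observations or features+labels")
    features = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("both classes must be present in the training data")
    X = np.column_stack([np.ones(n), features])

    beta = None
    separation = False
    converged = True
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # degenerate design (e.g. constant predictors): the likelihood is
        # flat along a subspace; the slope penalty picks the minimum-norm
        # solution, which zeroes the uninformative coefficients
        beta, converged = _ridge_logistic(X, y)
        ll = _log_likelihood(beta, X, y)
        p_bar = y.mean()
        null_beta = np.array([math.log(p_bar / (1 - p_bar)), 0.0, 0.0])
        return UnbalanceModel(
            name=name, spec=spec,
            intercept=float(beta[0]), coef_expr=float(beta[1]),
            coef_imbalance=float(beta[2]),
            n_obs=n, log_likelihood=ll,
            null_log_likelihood=_log_likelihood(null_beta, X, y),
            converged=converged, separation=False,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
        beta = np.asarray(res.params, dtype=float)
        converged = bool(getattr(res, "converged", True))
        # a log-likelihood at (numerically) zero means perfect separation
        if not converged or _log_likelihood(beta, X, y) > -1e-6:
            beta = None
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        beta = None

    if beta is None:
        separation = True
        warnings.warn(
            f"perfect separation while fitting {name!r}; "
            f"refitted with ridge penalty {RIDGE_LAMBDA:g} on the slopes",
            SeparationWarning,
            stacklevel=2,
        )
        beta, converged = _ridge_logistic(X, y)

    ll = _log_likelihood(beta, X, y)
    p_bar = y.mean()
    null_beta = np.array([math.log(p_bar / (1 - p_bar)), 0.0, 0.0])
    null_ll = _log_likelihood(null_beta, X, y)
    return UnbalanceModel(
        name=name,
        spec=spec,
        intercept=float(beta[0]),
        coef_expr=float(beta[1]),
        coef_imbalance=float(beta[2]),
        n_obs=n,
        log_likelihood=ll,
        null_log_likelihood=null_ll,
        converged=converged,
        separation=separation,
    )


def _required_hits(n: int, target_sensitivity: float) -> int:
    """ceil(target * n), robust to the float representation of targets like 0.95."""
    m = target_sensitivity * n
    r = round(m)
    if abs(m - r) < 1e-9:
        return int(r)
    return int(math.ceil(m))


def calibrate_threshold(probabilities: Sequence[float], target_sensitivity: float) -> float:
    """Cutoff on predicted probabilities attaining a training sensitivity floor.

    Returns the largest observed probability tau such that at least
    ``target_sensitivity`` of the inputs satisfy ``p >= tau`` — the k-th
    smallest probability with ``k = n - ceil(s*n) + 1``.  Flagging uses
    ``p >= tau``, so the calibrated sensitivity is attained exactly and
    any strictly larger observed cutoff would fall below the target.
    """
    probs = np.sort(np.asarray(probabilities, dtype=float))
    n = probs.size
    if n == 0:
        raise ValueError("no training positives to calibrate on")
    if not (0.0 < target_sensitivity <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    k_req = _required_hits(n, target_sensitivity)
    return float(probs[n - k_req])


def calibrate_cutoff(
    model: UnbalanceModel,
    training_positives: np.ndarray | Sequence[tuple[float, float]],
    target_sensitivity: float = 0.95,
) -> UnbalanceModel:
    """Return a copy of ``model`` with its probability cutoff calibrated.

    ``training_positives`` are (x1, x2) feature pairs of known fusion-positive
    samples; the cutoff is chosen by :func:`calibrate_threshold`.
    """
    feats = np.asarray(training_positives, dtype=float).reshape(-1, 2)
    probs = model.predict_proba(feats[:, 0], feats[:, 1])
    tau = calibrate_threshold(probs, target_sensitivity)
    return replace(model, cutoff=tau, target_sensitivity=target_sensitivity)


@dataclass(frozen=True)
class ScreeningDecision:
    """Per-sample classifier output: per-model probabilities/flags and the union.

    ``overall`` is None (and ``indeterminate`` True) for QC-failed samples —
    a quality failure is never reported as a negative screen.
    """

    sample_id: str
    probabilities: Mapping[str, float] = field(default_factory=dict)
    flags: Mapping[str, bool] = field(default_factory=dict)
    overall: Optional[bool] = None
    indeterminate: bool = False


def classify(
    models: Sequence[UnbalanceModel],
    profile: ExpressionProfile,
    qc_pass: bool = True,
) -> ScreeningDecision:
    """Apply calibrated models to one sample; union rule across models.

    A sample is screen-positive when at least one model's probability
    reaches its cutoff (ties flag, matching how the cutoff is attained in
    calibration).  QC-failed samples yield an indeterminate decision.
    """
    if not qc_pass:
        return ScreeningDecision(profile.sample_id, overall=None, indeterminate=True)
    probs: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for model in models:
        if model.cutoff is None:
            raise ValueError(f"model {model.name!r} is not calibrated")
        p = model.probability(profile)
        probs[model.name] = p
        flags[model.name] = p >= model.cutoff
    return ScreeningDecision(profile.sample_id, probs, flags, overall=any(flags.values()))


def ros1_flag(
    profile: ExpressionProfile,
    threshold: float = ROS1_DELTA_CT_THRESHOLD,
    pair: tuple[str, str] = ROS1_PAIR,
) -> bool:
    """Fixed triage rule for ROS1: true iff dCt(5', 3') strictly exceeds the threshold."""
    return profile.imbalance[pair] > threshold


def _metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, object]:
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return {"tp": tp, "fn": fn, "tn": tn, "fp": fp, "sensitivity": sens, "specificity": spec}


def evaluate(
    decisions: Sequence[ScreeningDecision], truth: Sequence[int | bool]
) -> dict[str, dict[str, object]]:
    """Confusion-matrix metrics per model and for the union rule.

    ``truth`` holds the fusion labels aligned with ``decisions``.  A metric
    whose denominator class is absent is reported as None, not 0.
    Indeterminate decisions are rejected — evaluate QC-passing samples only.
    """
    if len(decisions) != len(truth):
        raise ValueError("decisions and truth must have equal length")
    if any(d.indeterminate for d in decisions):
        raise ValueError("cannot evaluate indeterminate (QC-failed) decisions")
    y = np.asarray([bool(t) for t in truth])
    out: dict[str, dict[str, object]] = {}
    names = list(decisions[0].flags) if decisions else []
    for name in names:
        pred = np.asarray([d.flags[name] for d in decisions])
        out[name] = _metrics(pred, y)
    union = np.asarray([bool(d.overall) for d in decisions])
    out["union"] = _metrics(union, y)
    return out


# ---------------------------------------------------------------------------
# Persistence


def _model_to_dict(model: UnbalanceModel) -> dict:
    d = asdict(model)
    d["spec"] = asdict(model.spec)
    return d


def _model_from_dict(d: dict) -> UnbalanceModel:
    d = dict(d)
    d["spec"] = PredictorSpec(**d["spec"])
    return UnbalanceModel(**d)


def save_models(models: Iterable[UnbalanceModel], path: str | Path) -> None:
    """Persist models as JSON; float fields round-trip bit-exactly."""
    payload = {"format": "fusionbalance-models", "version": 1,
               "models": [_model_to_dict(m) for m in models]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> list[UnbalanceModel]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "fusionbalance-models":
        raise ValueError(f"{path} is not a fusionbalance model file")
    return [_model_from_dict(d) for d in payload["models"]]
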