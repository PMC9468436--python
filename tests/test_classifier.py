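"""Logistic fitting, cutoff calibration, the union rule and evaluation."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _helpers import grid_search_logistic, training_cohort
from fusionbalance.classifier import (
    ALK_NARROW_SPEC,
    ALK_WIDE_SPEC,
    PredictorSpec,
    ScreeningDecision,
    SeparationWarning,
    UnbalanceModel,
    calibrate_cutoff,
    calibrate_threshold,
    classify,
    evaluate,
    fit_logistic,
    load_models,
    ros1_flag,
    save_models,
)
from fusionbalance.expression import ExpressionProfile
from fusionbalance.pipeline import train_alk_models

# A 12-point, non-separable toy problem (one positive sits inside the
# negative cluster) with a finite, moderate maximum-likelihood optimum.
TOY = [
    (-2.0, 0.0, 0), (-1.5, 0.5, 0), (-1.0, -0.5, 0), (-0.5, 0.2, 0),
    (0.0, -0.2, 0), (0.5, 0.5, 0),
    (-0.5, 1.0, 1), (0.0, 0.8, 1), (0.5, 1.5, 1), (1.0, 0.5, 1),
    (1.5, 1.2, 1), (0.2, -0.1, 1),
]


def _profile(sample_id="s", x1=0.0, x2=0.0):
    """Minimal profile carrying the ALK predictors (and a ROS1 imbalance)."""
    return ExpressionProfile(
        sample_id,
        rel_expr={"ALK_ex22_23": x1},
        imbalance={
            ("ALK_ex9_10", "ALK_ex22_23"): x2,
            ("ALK_ex19_20", "ALK_ex22_23"): x2,
            ("ROS1_ex17_18", "ROS1_ex38_39"): 0.0,
        },
        censor_flags={},
    )


def test_intercept_only_optimum():
    """With predictors identical across samples, the fit reduces to the
    base rate: slopes ~0 and fitted probability = the positive fraction."""
    obs = [(1.0, -2.0, 1 if i < 3 else 0) for i in range(10)]
    model = fit_logistic(obs)
    assert model.coef_expr == pytest.approx(0.0, abs=1e-6)
    assert model.coef_imbalance == pytest.approx(0.0, abs=1e-6)
    assert model.predict_proba(1.0, -2.0) == pytest.approx(0.3, abs=1e-6)


def test_fit_matches_grid_search_oracle():
    model = fit_logistic(TOY)
    X = np.array([(a, b) for a, b, _ in TOY])
    y = np.array([c for _, _, c in TOY])
    oracle = grid_search_logistic(X, y)
    assert np.max(np.abs(model.coefficients - oracle)) < 1e-3
    assert model.log_likelihood >= model.null_log_likelihood


def test_separable_data_gets_ridge_and_warning():
    obs = [(-1.0, -1.0, 0), (-2.0, 0.0, 0), (-1.5, -0.5, 0),
           (1.0, 1.0, 1), (2.0, 0.5, 1), (1.5, 1.5, 1)]
    with pytest.warns(SeparationWarning):
        model = fit_logistic(obs)
    assert model.separation
    assert np.all(np.isfinite(model.coefficients))
    # the ridge optimum still separates the training points
    p = model.predict_proba(*np.array([(a, b) for a, b, _ in obs]).T)
    assert (p > 0.5).tolist() == [False, False, False, True, True, True]


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        fit_logistic([(0.0, 0.0, 1), (1.0, 1.0, 1), (2.0, 0.0, 1)])  # one class
    with pytest.raises(ValueError):
        fit_logistic([(0.0, 0.0, 1), (1.0, 1.0, 0)])  # n < 3


@pytest.mark.parametrize(
    "probs, target, expected",
    [
        ([0.01] + [0.99] * 19, 0.95, 0.99),  # drops exactly the worst 5%
        ([1.0] * 8, 0.5, 1.0),
        ([0.2, 0.4, 0.6, 0.8], 1.0, 0.2),  # s*=1 forces the minimum
    ],
)
def test_calibrate_threshold(probs, target, expected):
    assert calibrate_threshold(probs, target) == pytest.approx(expected)


def test_calibrated_sensitivity_attained():
    probs = [0.01] + [0.99] * 19
    tau = calibrate_threshold(probs, 0.95)
    assert np.mean(np.asarray(probs) >= tau) == pytest.approx(19 / 20)


@given(
    probs=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60),
    target=st.floats(min_value=0.05, max_value=1.0),
)
def test_calibration_maximality(probs, target):
    """tau achieves the sensitivity floor, and any strictly larger observed
    probability as cutoff would fall below it (maximal specificity)."""
    tau = calibrate_threshold(probs, target)
    arr = np.asarray(probs)
    n = len(arr)
    assert np.mean(arr >= tau) >= target - 1e-12
    larger = arr[arr > tau]
    if larger.size:
        tau2 = larger.min()
        assert np.mean(arr >= tau2) < target


def _toy_model(name, intercept=0.0, b1=1.0, b2=1.0, cutoff=0.5):
    return UnbalanceModel(
        name=name, spec=ALK_WIDE_SPEC, intercept=intercept,
        coef_expr=b1, coef_imbalance=b2, cutoff=cutoff, target_sensitivity=0.95,
    )


def test_union_rule():
    flags_a = _toy_model("a", intercept=5.0)  # flags everything
    flags_none = _toy_model("b", intercept=-5.0)  # flags nothing
    d = classify([flags_a, flags_none], _profile(x1=0.0, x2=0.0))
    assert d.flags == {"a": True, "b": False}
    assert d.overall is True
    d = classify([flags_none], _profile())
    assert d.overall is False


def test_probability_at_cutoff_flags():
    model = _toy_model("m", intercept=0.0, b1=0.0, b2=0.0, cutoff=0.5)
    d = classify([model], _profile())  # p = expit(0) = 0.5 exactly
    assert d.probabilities["m"] == pytest.approx(0.5)
    assert d.flags["m"] is True


def test_union_monotone_in_models():
    base = _toy_model("a", intercept=5.0)
    extra = _toy_model("b", intercept=-5.0)
    prof = _profile()
    assert classify([base], prof).overall is True
    assert classify([base, extra], prof).overall is True  # adding never demotes


def test_qc_failed_is_indeterminate():
    d = classify([_toy_model("a")], _profile(), qc_pass=False)
    assert d.overall is None
    assert d.indeterminate
    with pytest.raises(ValueError):
        evaluate([d], [1])


def test_uncalibrated_model_refuses_to_classify():
    model = _toy_model("m")
    model = UnbalanceModel(**{**model.__dict__, "cutoff": None})
    with pytest.raises(ValueError, match="not calibrated"):
        classify([model], _profile())


def test_decision_invariant_to_rna_quality_when_expression_unused():
    """A global Ct shift moves x1 but not x2; with zero weight on x1 the
    decision depends on the imbalance alone and is quality-invariant."""
    model = _toy_model("m", intercept=-2.0, b1=0.0, b2=1.0, cutoff=0.5)
    for shift in (-3.0, 0.0, 4.0):
        prof = _profile(x1=-6.0 + shift, x2=2.5)
        assert classify([model], prof).flags["m"] is True
        prof = _profile(x1=-6.0 + shift, x2=1.5)
        assert classify([model], prof).flags["m"] is False


@pytest.mark.parametrize("delta, expected", [(2.5, True), (2.0, False), (-1.0, False)])
def test_ros1_fixed_threshold_is_strict(delta, expected):
    prof = ExpressionProfile(
        "s", {}, {("ROS1_ex17_18", "ROS1_ex38_39"): delta}, {}
    )
    assert ros1_flag(prof) is expected


def test_evaluate_arithmetic():
    decisions, truth = [], []
    model_flags = [(True, 1)] * 19 + [(False, 1)] + [(False, 0)] * 199 + [(True, 0)]
    for i, (flag, label) in enumerate(model_flags):
        decisions.append(
            ScreeningDecision(f"s{i}", {"m": 1.0 if flag else 0.0}, {"m": flag}, overall=flag)
        )
        truth.append(label)
    m = evaluate(decisions, truth)
    assert m["m"]["sensitivity"] == pytest.approx(0.95)
    assert m["m"]["specificity"] == pytest.approx(0.995)
    assert (m["m"]["tp"], m["m"]["fn"], m["m"]["tn"], m["m"]["fp"]) == (19, 1, 199, 1)
    assert m["union"] == m["m"]


def test_evaluate_undefined_metrics():
    d = [ScreeningDecision("s", {"m": 0.0}, {"m": False}, overall=False)]
    m = evaluate(d, [0])
    assert m["m"]["sensitivity"] is None
    assert m["m"]["specificity"] == 1.0


def test_evaluate_random_flags_specificity():
    """Flags thrown at rate q on all-negative data give specificity ~ 1-q."""
    rng = np.random.default_rng(42)
    q = 0.1
    flags = rng.random(2000) < q
    decisions = [
        ScreeningDecision(f"s{i}", {"m": float(f)}, {"m": bool(f)}, overall=bool(f))
        for i, f in enumerate(flags)
    ]
    m = evaluate(decisions, [0] * 2000)
    se = math.sqrt(q * (1 - q) / 2000)
    assert abs(m["union"]["specificity"] - (1 - q)) < 4 * se


def test_model_json_round_trip_bit_exact(tmp_path):
    profiles, labels = training_cohort(seed=5, n_pos=60, n_neg=300)
    models = train_alk_models(profiles, labels)
    path = tmp_path / "models.json"
    save_models(models, path)
    back = load_models(path)
    assert tuple(back) == tuple(models)  # bit-exact floats and all metadata
    json.loads(path.read_text())  # and it is valid JSON


def test_parameter_recovery_on_synthetic_cohorts():
    """Calibration generalises: training sensitivity meets the 95% floor by
    construction, and held-out sensitivity stays near it on fresh cohorts
    drawn from the same class geometry (mean over 20 seeded replicates)."""
    devs, train_ok = [], []
    for seed in range(20):
        profiles, labels = training_cohort(seed=100 + seed, n_pos=150, n_neg=800)
        models = train_alk_models(profiles, labels, 0.95)
        decisions = [classify(models, p) for p in profiles]
        m = evaluate(decisions, labels)
        train_ok.append(m["union"]["sensitivity"] >= 0.95)
        held_p, held_y = training_cohort(seed=900 + seed, n_pos=150, n_neg=50)
        held = evaluate([classify(models, p) for p in held_p], held_y)
        devs.append(held["union"]["sensitivity"] - 0.95)
    assert all(train_ok)
    assert abs(float(np.mean(devs))) <= 0.03
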