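import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed synthetic cohort shared across I/O and pipeline tests."""
    from fusionbalance.simulate import default_config, generate_cohort

    config = default_config(seed=11).with_counts(
        ALK_fusion=40,
        ROS1_fusion=12,
        MET_ex14=6,
        EGFR_mut=30,
        RAS_mut_imbalanced=8,
        RAS_mut_plain=20,
        negative=250,
    )
    samples, truth = generate_cohort(config)
    return samples, truth
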