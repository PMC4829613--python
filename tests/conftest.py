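import pytest

from lepnorm import (
    CohortConfig,
    baseline_correct,
    build_feature_table,
    normalize_table,
    simulate_cohort,
)

# Small, fast cohort for unit tests; statistics are sampling-rate-insensitive
# (everything downstream operates on RMS), so 200 Hz is fine here.
SMALL_CONFIG = CohortConfig(
    n_individuals=6, pulses_per_level=3, sampling_rate=200.0, seed=7
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    trials, _ = small_cohort
    return build_feature_table([baseline_correct(t) for t in trials])


@pytest.fixture(scope="session")
def small_normalized(small_features):
    return normalize_table(small_features)
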