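import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fcclassify as fc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def strong_cohort():
    """50+50 subjects, 60 regions, 10 planted edges at a strong effect:
    the setting where selection and classification should succeed."""
    spec = fc.demo_spec(seed=3, n_controls=50, n_patients=50, effect_size=0.5)
    records, truth = fc.generate_cohort(spec)
    x, y, ids = fc.features_table(records)
    return x, y, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Exchangeable cohort: no planted structure at all."""
    spec = fc.demo_spec(seed=11, n_controls=50, n_patients=50,
                        effect_size=0.0, n_planted=0)
    records, _ = fc.generate_cohort(spec)
    x, y, ids = fc.features_table(records)
    return x, y


@pytest.fixture(scope="session")
def hetero_cohort():
    """Heterogeneous patient group: shared 10-edge signature plus
    subtype-signed loadings on 40 heterogeneity edges."""
    spec = fc.demo_spec(seed=2, subtype_fraction=0.5)
    records, truth = fc.generate_cohort(spec)
    x, y, ids = fc.features_table(records)
    labels = np.array(["patient" if t else "control" for t in y])
    return x, y, labels, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny strong-signal cohort for fast CV mechanics tests."""
    spec = fc.demo_spec(seed=7, n_regions=30, n_controls=16, n_patients=16,
                        n_timepoints=100, effect_size=0.5, n_planted=6)
    records, truth = fc.generate_cohort(spec)
    x, y, ids = fc.features_table(records)
    return x, y, truth
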