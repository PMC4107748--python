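import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20140715)


@pytest.fixture
def published_counts():
    """Genotype counts of the deletion locus: (group, cn) -> count."""
    return {("high", 1): 12, ("high", 2): 83, ("low", 1): 2, ("low", 2): 90}


@pytest.fixture
def two_group_cohort(published_counts):
    """Minimal cohort frame matching the published genotype counts."""
    rng = np.random.default_rng(7)
    rows = []
    i = 0
    for (group, cn), count in published_counts.items():
        for _ in range(count):
            i += 1
            rows.append(dict(
                subject_id=f"P{i:03d}", group=group,
                sbp=165.0 if group == "high" else 98.0,
                dbp=94.0 if group == "high" else 64.0,
                age=float(abs(rng.normal(*(55.1, 8.3) if group == "high"
                                         else (32.6, 14.5)))),
                sex="male" if rng.random() < 0.5 else "female",
                bmi=float(rng.normal(*(28.3, 4.5) if group == "high"
                                     else (22.7, 3.2))),
                treated=int(group == "high" and rng.random() < 0.5),
                true_cn=cn))
    return pd.DataFrame(rows)
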