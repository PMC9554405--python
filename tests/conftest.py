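import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seropanel as sp

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized 67 x 103 synthetic cohort (seed 1)."""
    return sp.generate_cohort(sp.default_config(seed=1))


@pytest.fixture(scope="session")
def log10_cohort(default_cohort):
    meta, matrix, truth = default_cohort
    logm = sp.log10_transform(sp.substitute_below_lod(matrix))
    return meta, logm, truth


def small_cohort_config(seed=0, n_per_group=10, n_analytes=6, effects=None, lod_quantile=None):
    """A tiny two/three-group cohort for fast unit tests."""
    cat = sp.load_catalogue()
    analytes = tuple(cat.index[:n_analytes])
    base = {a: 2.0 for a in analytes}
    lod = {a: 1e-6 for a in analytes}
    return sp.CohortConfig(
        group_sizes={"A": n_per_group, "B": n_per_group},
        analytes=analytes,
        base_log10_mean=base,
        lod=lod,
        base_log10_sd=0.3,
        noise_sd=0.1,
        effect_table=effects or {},
        seed=seed,
    )


@pytest.fixture
def small_config():
    return small_cohort_config()
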