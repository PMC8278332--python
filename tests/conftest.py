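import numpy as np
import pytest

from sdnv import CohortSpec, generate_cohort, variability_map


def nv_matrix(cohort, **kwargs):
    return np.vstack([variability_map(ts, **kwargs).nv for ts in cohort.timeseries])


@pytest.fixture(scope="session")
def small_spec():
    # cheap cohort for IO/CLI and structural unit tests
    return CohortSpec(n_participants=24, n_nodes=40, n_volumes=100, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (58 participants, 264 nodes, 145 volumes)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def default_nv(default_cohort):
    return nv_matrix(default_cohort)
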