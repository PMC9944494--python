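import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrsclust as hc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_profiles():
    return hc.load_table1_profiles()


@pytest.fixture(scope="session")
def table1_cohort():
    """Full-size cohort drawn from the published per-cluster parameters."""
    return hc.simulate_cohort(hc.table1_config(n_admissions=5564, seed=7))


@pytest.fixture(scope="session")
def highsep_cohort():
    """Well-separated planted four-cluster cohort for recovery tests."""
    return hc.simulate_cohort(hc.high_separation_config(n_admissions=240, seed=2))


@pytest.fixture(scope="session")
def highsep_consensus(highsep_cohort):
    """Consensus matrices for k = 2..6 on the separable fixture."""
    features = hc.zscore_continuous(hc.encode_features(highsep_cohort))
    config = hc.ConsensusConfig(k_min=2, k_max=6, iterations=50, seed=0)
    return hc.run_consensus(features, config)


@pytest.fixture(scope="session")
def highsep_diagnostics(highsep_consensus):
    return hc.compute_diagnostics(highsep_consensus)


def make_consensus_matrix(values_upper, n):
    """Build a ConsensusMatrix from explicit upper-triangle entries."""
    m = np.ones((n, n), dtype=float)
    iu = np.triu_indices(n, k=1)
    vals = np.asarray(values_upper, dtype=float)
    assert vals.shape[0] == iu[0].shape[0]
    m[iu] = vals
    m[(iu[1], iu[0])] = vals
    return hc.ConsensusMatrix(
        k=2, matrix=m, cosample_counts=np.full((n, n), 1, dtype=np.uint16)
    )


@pytest.fixture
def consensus_from_values():
    return make_consensus_matrix
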