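import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mpp_eqtl.datatypes import FounderProbabilities
from mpp_eqtl.synthetic_data import simulate_marker_map, simulate_ril_genomes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    """One 10 cM chromosome, 101 markers at 50 kb / 0.1 cM spacing."""
    return simulate_marker_map(1, 5_000_000, 50_000, 2.0)


@pytest.fixture(scope="session")
def small_probs(small_map):
    """30 strains of smoothed founder probabilities on the small map."""
    _, probs = simulate_ril_genomes(small_map, 30, 8, 2.0, 0.05, seed=11)
    return probs


@pytest.fixture()
def onehot_two_founder_probs(small_map):
    """4 strains x 2 founders, one-hot (A, A, B, B) at every marker."""
    P = np.zeros((4, small_map.n_markers, 2))
    P[:2, :, 0] = 1.0
    P[2:, :, 1] = 1.0
    return FounderProbabilities(["s1", "s2", "s3", "s4"], small_map.marker_ids, P)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def brute_force_lod(y: np.ndarray, X: np.ndarray) -> float:
    """Independent two-model OLS oracle for the Haley-Knott LOD."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r1 = y - X @ beta
    rss1 = float(r1 @ r1)
    rss0 = float(((y - y.mean()) ** 2).sum())
    return n / 2.0 * np.log10(rss0 / rss1)
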