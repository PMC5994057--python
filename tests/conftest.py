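import numpy as np
import pytest
from scipy.stats import ortho_group

from tensorica import OmicsTensor, SimulationConfig, simulate_multiomic


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_tensor(rng):
    """Random centered 3x4x5 tensor for operator-algebra checks."""
    v = rng.normal(size=(3, 4, 5))
    v -= v.mean(axis=2, keepdims=True)
    return OmicsTensor(v)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset (2 x 100 x 1000, sigma=1)."""
    return simulate_multiomic(SimulationConfig(seed=11))


def make_mixed_tensor(seed, d1=2, d2=3, p=10000, distributions=None):
    """X = S (x)_1 O1 (x)_2 O2 with independent unit-variance sources.

    By default source slices cycle through six unit-variance distributions
    with excess kurtoses -1.2, 0, 3, -0.6, 1.2, 6, chosen so that per-mode
    kurtosis row/column sums are distinct — the regime in which both FOBI
    and JADE are identifiable.  Returns (tensor, sources, O1, O2).
    """
    rng = np.random.default_rng(seed)
    if distributions is None:
        distributions = [
            lambda s: rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), s),  # -1.2
            lambda s: rng.normal(0.0, 1.0, s),  # 0
            lambda s: rng.laplace(0.0, 1.0 / np.sqrt(2.0), s),  # 3
            lambda s: rng.triangular(-np.sqrt(6.0), 0.0, np.sqrt(6.0), s),  # -0.6
            lambda s: rng.logistic(0.0, np.sqrt(3.0) / np.pi, s),  # 1.2
            lambda s: rng.standard_t(5, s) / np.sqrt(5.0 / 3.0),  # 6
        ]
    S = np.empty((d1, d2, p))
    for a in range(d1):
        for b in range(d2):
            S[a, b] = distributions[(a * d2 + b) % len(distributions)](p)
    O1 = np.eye(d1) if d1 == 1 else ortho_group.rvs(d1, random_state=rng)
    O2 = np.eye(d2) if d2 == 1 else ortho_group.rvs(d2, random_state=rng)
    X = np.einsum("ab,bcd,ec->aed", O1, S, O2)
    return OmicsTensor(X), S, O1, O2


def matched_abs_correlations(S_true, S_est):
    """Greedy |correlation| matching of estimated to true source slices.

    Returns, per true component, the best |r| over estimated components
    (each estimated component used at most once).
    """
    n, p = S_true.reshape(-1, S_true.shape[-1]).shape
    A = S_true.reshape(n, p)
    B = S_est.reshape(-1, p)
    C = np.abs(np.corrcoef(A, B)[:n, n:])
    out = np.zeros(n)
    used = set()
    for _ in range(n):
        i, j = np.unravel_index(
            np.argmax(np.where([[c not in used for c in range(C.shape[1])]] , C, -1.0)),
            C.shape,
        )
        out[i] = C[i, j]
        used.add(j)
        C[i, :] = -1.0
    return out
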