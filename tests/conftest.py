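import itertools

import numpy as np
import pytest

from asehmm import make_state_space


@pytest.fixture
def ase_space():
    return make_state_space("ASE")


@pytest.fixture
def nase_space():
    return make_state_space("NASE")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_parameters(space, rng, e=None):
    """Random valid parameters for a state space (helper, not a fixture)."""
    from asehmm import ModelParameters, validate_parameters

    M = space.M
    A = rng.dirichlet(np.ones(M), size=M)
    pi = rng.dirichlet(np.ones(M))
    theta = ModelParameters(
        A=A, pi=pi, e=float(rng.uniform(0.001, 0.1)) if e is None else e,
        alpha1=float(rng.uniform(2, 50)), beta1=float(rng.uniform(2, 50)),
        alpha2=float(rng.uniform(2, 50)), beta2=float(rng.uniform(2, 50)),
    )
    return validate_parameters(theta, space)


def count_vectors_with_total(n):
    """All 4-part compositions of n (every possible base-count vector)."""
    out = []
    for a in range(n + 1):
        for c in range(n + 1 - a):
            for g in range(n + 1 - a - c):
                out.append((a, c, g, n - a - c - g))
    return np.array(out, dtype=np.int64)


def brute_force_posteriors(logb, A, pi):
    """Exhaustive-path HMM posteriors: the independent oracle for
    forward-backward, feasible for M**L up to a few thousand paths."""
    L, M = logb.shape
    gamma = np.zeros((L, M))
    xi = np.zeros((M, M))
    total = 0.0
    for path in itertools.product(range(M), repeat=L):
        lp = np.log(pi[path[0]]) + logb[0, path[0]]
        for l in range(1, L):
            lp += np.log(A[path[l - 1], path[l]]) + logb[l, path[l]]
        p = np.exp(lp)
        total += p
        for l, k in enumerate(path):
            gamma[l, k] += p
        for l in range(1, L):
            xi[path[l - 1], path[l]] += p
    return gamma / total, xi / total, np.log(total)
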