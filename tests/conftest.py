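"""Shared fixtures and independent oracles.

The enumeration oracle computes state posteriors and likelihoods by summing
over every hidden path in log space.  It shares no code with the package's
scaled forward-backward recursion and is only feasible for tiny instances,
which is the point.
"""

import numpy as np
import pytest

from stackstate import ChromSizes, HMMParams


def enumerate_posteriors(params: HMMParams, obs: np.ndarray):
    """Exhaustive path-sum posteriors and log-likelihood for a tiny chunk.

    Sums P(path, obs) over all S^T paths; emission probabilities are computed
    directly in log space (missing code 2 contributes nothing).
    """
    T, D = obs.shape
    S = params.n_states
    log_e = np.log(params.emissions)
    log_ne = np.log1p(-params.emissions)
    log_a = np.log(params.transitions)
    log_pi = np.log(params.initial)

    def log_emit(s, o):
        total = 0.0
        for d in range(D):
            if o[d] == 1:
                total += log_e[s, d]
            elif o[d] == 0:
                total += log_ne[s, d]
        return total

    emit = np.array([[log_emit(s, obs[t]) for s in range(S)] for t in range(T)])
    paths = np.stack(np.unravel_index(np.arange(S**T), (S,) * T), axis=1)  # (S^T, T)
    lp = log_pi[paths[:, 0]] + emit[0, paths[:, 0]]
    for t in range(1, T):
        lp += log_a[paths[:, t - 1], paths[:, t]] + emit[t, paths[:, t]]
    shift = lp.max()
    w = np.exp(lp - shift)
    gamma = np.zeros((T, S))
    for t in range(T):
        for s in range(S):
            gamma[t, s] = w[paths[:, t] == s].sum()
    gamma /= gamma.sum(axis=1, keepdims=True)
    total = shift + np.log(w.sum())
    return gamma, total


def random_params(S: int, D: int, rng: np.random.Generator) -> HMMParams:
    return HMMParams(
        emissions=rng.uniform(0.05, 0.95, size=(S, D)),
        transitions=rng.dirichlet(np.ones(S), size=S),
        initial=rng.dirichlet(np.ones(S)),
    )


@pytest.fixture
def small_chromsizes():
    return ChromSizes({"chrA": 10_000, "chrB": 4_500})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
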