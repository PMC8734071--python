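"""Stacked multivariate Bernoulli hidden Markov model.

The model has S hidden states over genomic 200-bp bins and D binary features
(one per epigenomic dataset).  State s emits feature d as present with
probability ``e[s, d]``, independently across features given the state.  With
hundreds to a thousand features the per-position joint emission probability
underflows double precision, so the forward-backward pass works with
*relative* emission products: features are folded in one at a time and the
running product across states is renormalized by its maximum after each
feature.  The discarded maxima are accumulated in log space so exact
log-likelihoods are still available.

Training follows Baum-Welch with two large-scale devices: every M-step adds a
pseudo-count to all sufficient statistics (keeping parameters strictly
interior even when an iteration never visits some configuration), and every
E-step runs on a fresh random sample of <=1-Mb observation chunks rather than
the whole genome.  Because each iteration scores a different subsample, the
recorded likelihood trace is not monotone and convergence checks on it are
disabled by default (``convergence_delta = -1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HMMParams",
    "ObservationChunk",
    "PosteriorChunk",
    "SufficientStats",
    "TrainConfig",
    "ModelFit",
    "DegenerateEmissionError",
    "NumericalError",
    "stabilized_emission_products",
    "forward_backward",
    "baum_welch_update",
    "train",
    "train_best",
    "log_likelihood",
    "aic_bic",
    "init_random",
    "compare_models",
    "mark_tissue_correlation",
]

MISSING = 2  # observation code for "no call available"


class DegenerateEmissionError(ValueError):
    """Every state assigns probability zero to an observed pattern."""


class NumericalError(FloatingPointError):
    """A non-finite intermediate occurred; the message reports the position."""


@dataclass
class HMMParams:
    """Emission, transition and initial probabilities of the stacked HMM."""

    emissions: np.ndarray  # (S, D), P(present call)
    transitions: np.ndarray  # (S, S), rows sum to 1
    initial: np.ndarray  # (S,), sums to 1
    feature_names: list | None = None

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.emissions.shape[0]

    @property
    def n_features(self) -> int:
        return self.emissions.shape[1]

    @property
    def n_free_parameters(self) -> int:
        """k = S*D + S*(S-1) + (S-1): one free parameter per Bernoulli emission,
        one lost degree of freedom per transition row and for pi."""
        S, D = self.emissions.shape
        return S * D + S * (S - 1) + (S - 1)

    def validate(self, atol: float = 1e-9) -> None:
        S = self.emissions.shape[0]
        if self.transitions.shape != (S, S):
            raise ValueError("transition matrix shape mismatch")
        if self.initial.shape != (S,):
            raise ValueError("initial distribution shape mismatch")
        if ((self.emissions < 0) | (self.emissions > 1)).any():
            raise ValueError("emission probabilities outside [0, 1]")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")


@dataclass
class ObservationChunk:
    """A block of at most ~1 Mb of binarized calls (bins x datasets)."""

    chrom: str
    start_bin: int
    data: np.ndarray  # (T, D) in {0, 1, 2}
    tag: str = ""

    def __post_init__(self):
        self.data = np.ascontiguousarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("chunk data must be 2-D")
        if not self.tag:
            self.tag = self.chrom

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class PosteriorChunk:
    gamma: np.ndarray  # (T, S), rows sum to 1
    log_likelihood: float


@dataclass
class SufficientStats:
    """Expected counts accumulated over E-steps."""

    present: np.ndarray  # (S, D)
    absent: np.ndarray  # (S, D)
    trans: np.ndarray  # (S, S)
    init: np.ndarray  # (S,)

    @classmethod
    def zeros(cls, S: int, D: int) -> "SufficientStats":
        return cls(np.zeros((S, D)), np.zeros((S, D)), np.zeros((S, S)), np.zeros(S))

    def __iadd__(self, other: "SufficientStats") -> "SufficientStats":
        self.present += other.present
        self.absent += other.absent
        self.trans += other.trans
        self.init += other.init
        return self


@dataclass
class TrainConfig:
    n_states: int
    n_sampled_chunks: int = 300
    max_iterations: int = 200
    pseudo_count: float = 1.0
    convergence_delta: float = -1.0  # -1: never stop on likelihood
    seed: int = 0

    def __post_init__(self):
        if self.n_sampled_chunks < 1:
            raise ValueError("n_sampled_chunks must be >= 1")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")


@dataclass
class ModelFit:
    params: HMMParams
    log_likelihood_trace: list
    n_eval_bins: int
    n_free_parameters: int
    aic: float
    bic: float


# ---------------------------------------------------------------------------
# Stabilized emission products
# ---------------------------------------------------------------------------

@njit(cache=False)
def _emission_products_kernel(emissions, obs):  # pragma: no cover
    T, D = obs.shape
    S = emissions.shape[0]
    R = np.ones((T, S))
    logcorr = np.zeros(T)
    bad = -1
    for t in range(T):
        for d in range(D):
            o = obs[t, d]
            if o == 2:  # missing call: feature skipped
                continue
            m = 0.0
            for s in range(S):
                f = emissions[s, d] if o == 1 else 1.0 - emissions[s, d]
                R[t, s] *= f
                if R[t, s] > m:
                    m = R[t, s]
            if m <= 0.0:
                if bad < 0:
                    bad = t
                break
            for s in range(S):
                R[t, s] /= m
            logcorr[t] += np.log(m)
    return R, logcorr, bad


def _emission_products(emissions: np.ndarray, obs: np.ndarray):
    """Relative joint emission probabilities for every row of ``obs``.

    Returns ``(R, logcorr)`` where ``R[t, s]`` is proportional to
    P(obs[t] | state s) with ``max_s R[t, s] = 1``, and
    ``log P(obs[t] | s) = log R[t, s] + logcorr[t]``.

    Features are folded in one at a time; after each feature the running
    products across states are divided by their maximum (the missing code 2
    skips the feature for that row), so the products never underflow even
    with ~1000 features.
    """
    emissions = np.ascontiguousarray(emissions, dtype=np.float64)
    obs = np.ascontiguousarray(obs, dtype=np.uint8)
    R, logcorr, bad = _emission_products_kernel(emissions, obs)
    if bad >= 0:
        raise DegenerateEmissionError(
            f"all states assign zero probability to the pattern at row {bad}"
        )
    return R, logcorr


def stabilized_emission_products(params: HMMParams, observation: np.ndarray) -> np.ndarray:
    """Relative emission products for a single observation row (max = 1)."""
    obs = np.asarray(observation, dtype=np.uint8).reshape(1, -1)
    if obs.shape[1] != params.n_features:
        raise ValueError("observation length must equal the number of features")
    R, _ = _emission_products(params.emissions, obs)
    return R[0]


# ---------------------------------------------------------------------------
# Scaled forward-backward (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _fb_kernel(R, a, pi):  # pragma: no cover - exercised via forward_backward
    T, S = R.shape
    alpha = np.empty((T, S))
    beta = np.empty((T, S))
    c = np.empty(T)
    acc = 0.0
    for s in range(S):
        alpha[0, s] = pi[s] * R[0, s]
        acc += alpha[0, s]
    c[0] = acc
    for s in range(S):
        alpha[0, s] /= acc
    for t in range(1, T):
        tot = 0.0
        for j in range(S):
            v = 0.0
            for i in range(S):
                v += alpha[t - 1, i] * a[i, j]
            v *= R[t, j]
            alpha[t, j] = v
            tot += v
        c[t] = tot
        for j in range(S):
            alpha[t, j] /= tot
    for s in range(S):
        beta[T - 1, s] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(S):
            v = 0.0
            for j in range(S):
                v += a[i, j] * R[t + 1, j] * beta[t + 1, j]
            beta[t, i] = v / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        tot = 0.0
        for s in range(S):
            tot += gamma[t, s]
        for s in range(S):
            gamma[t, s] /= tot
    trans = np.zeros((S, S))
    tmp = np.empty((S, S))
    for t in range(T - 1):
        denom = 0.0
        for i in range(S):
            for j in range(S):
                v = alpha[t, i] * a[i, j] * R[t + 1, j] * beta[t + 1, j] / c[t + 1]
                tmp[i, j] = v
                denom += v
        for i in range(S):
            for j in range(S):
                trans[i, j] += tmp[i, j] / denom
    return gamma, trans, c


@njit(cache=False)
def _forward_loglik_kernel(R, a, pi):  # pragma: no cover
    T, S = R.shape
    prev = np.empty(S)
    cur = np.empty(S)
    total = 0.0
    acc = 0.0
    for s in range(S):
        prev[s] = pi[s] * R[0, s]
        acc += prev[s]
    total += np.log(acc)
    for s in range(S):
        prev[s] /= acc
    for t in range(1, T):
        tot = 0.0
        for j in range(S):
            v = 0.0
            for i in range(S):
                v += prev[i] * a[i, j]
            cur[j] = v * R[t, j]
            tot += cur[j]
        total += np.log(tot)
        for j in range(S):
            prev[j] = cur[j] / tot
    return total


def forward_backward(params: HMMParams, chunk: ObservationChunk):
    """Posterior state probabilities and expected sufficient statistics.

    Each chunk is treated as an independent sequence started from the initial
    distribution.  Returns ``(PosteriorChunk, SufficientStats)``; the chunk
    log-likelihood combines the forward scaling constants with the emission-
    product normalization corrections, so it is exact.
    """
    if chunk.n_bins == 0:
        raise ValueError("empty chunk")
    if chunk.n_features != params.n_features:
        raise ValueError("chunk feature count does not match the model")
    R, logcorr = _emission_products(params.emissions, chunk.data)
    gamma, trans, c = _fb_kernel(R, params.transitions, params.initial)
    if not np.isfinite(c).all() or (c <= 0).any():
        bad = int(np.argmax(~(np.isfinite(c) & (c > 0))))
        raise NumericalError(f"non-finite forward scaling constant at position {bad}")
    loglik = float(np.log(c).sum() + logcorr.sum())
    obs = chunk.data
    present = gamma.T @ (obs == 1)
    absent = gamma.T @ (obs == 0)
    stats = SufficientStats(present=present, absent=absent, trans=trans, init=gamma[0].copy())
    return PosteriorChunk(gamma=gamma, log_likelihood=loglik), stats


def log_likelihood(params: HMMParams, chunks) -> float:
    """Total log-likelihood: sum of independent per-chunk forward passes."""
    total = 0.0
    for chunk in chunks:
        R, logcorr = _emission_products(params.emissions, chunk.data)
        total += _forward_loglik_kernel(R, params.transitions, params.initial) + logcorr.sum()
    return float(total)


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def baum_welch_update(stats: SufficientStats, pseudo_count: float = 1.0) -> HMMParams:
    """M-step with a pseudo-count added to every sufficient statistic."""
    c = float(pseudo_count)
    if c < 0:
        raise ValueError("pseudo_count must be >= 0")
    present, absent = stats.present, stats.absent
    emissions = (present + c) / (present + absent + 2 * c)
    trans = stats.trans + c
    transitions = trans / trans.sum(axis=1, keepdims=True)
    init = stats.init + c
    initial = init / init.sum()
    return HMMParams(emissions=emissions, transitions=transitions, initial=initial)


def init_random(S: int, D: int, seed: int, eps: float = 1e-3) -> HMMParams:
    """Seeded random start: emissions uniform on (eps, 1-eps), transition rows
    and the initial distribution drawn from a flat Dirichlet."""
    rng = np.random.default_rng(seed)
    emissions = rng.uniform(eps, 1.0 - eps, size=(S, D))
    transitions = rng.dirichlet(np.ones(S), size=S)
    initial = rng.dirichlet(np.ones(S))
    return HMMParams(emissions=emissions, transitions=transitions, initial=initial)


def train(chunks, config: TrainConfig, init: HMMParams | None = None) -> ModelFit:
    """Baum-Welch with per-iteration random chunk subsampling.

    Each iteration draws ``n_sampled_chunks`` chunks uniformly without
    replacement (with replacement when fewer chunks exist), runs the E-step on
    the sample, records the sampled log-likelihood under the pre-update
    parameters, then applies the pseudo-count M-step.  With
    ``convergence_delta = -1`` training always runs ``max_iterations``
    iterations; otherwise it stops once the sampled-likelihood improvement
    falls below the delta.  Fully reproducible given the seed.
    """
    chunks = list(chunks)
    if not chunks:
        raise ValueError("no chunks to train on")
    D = chunks[0].n_features
    for ch in chunks:
        if ch.n_features != D:
            raise ValueError("chunks have inconsistent feature counts")
    S = config.n_states
    rng = np.random.default_rng(config.seed)
    params = init if init is not None else init_random(S, D, seed=int(rng.integers(2**31 - 1)))
    if params.n_features != D or params.n_states != S:
        raise ValueError("initial parameters do not match config/chunks")
    n = len(chunks)
    take = min(config.n_sampled_chunks, n)
    replace = config.n_sampled_chunks > n
    size = config.n_sampled_chunks if replace else take
    trace: list[float] = []
    n_eval_bins = 0
    for _ in range(config.max_iterations):
        idx = rng.choice(n, size=size, replace=replace)
        stats = SufficientStats.zeros(S, D)
        loglik = 0.0
        n_eval_bins = 0
        for i in idx:
            post, st = forward_backward(params, chunks[i])
            loglik += post.log_likelihood
            stats += st
            n_eval_bins += chunks[i].n_bins
        trace.append(loglik)
        params = baum_welch_update(stats, config.pseudo_count)
        if (
            config.convergence_delta >= 0
            and len(trace) >= 2
            and trace[-1] - trace[-2] < config.convergence_delta
        ):
            break
    k = params.n_free_parameters
    aic, bic = aic_bic(trace[-1], k, n_eval_bins)
    return ModelFit(
        params=params,
        log_likelihood_trace=trace,
        n_eval_bins=n_eval_bins,
        n_free_parameters=k,
        aic=aic,
        bic=bic,
    )


def train_best(
    chunks,
    config: TrainConfig,
    n_restarts: int = 12,
    short_iterations: int = 15,
) -> ModelFit:
    """Short-run / long-run EM: several short seeded runs, then a full run
    continued from the short run with the best total log-likelihood.

    Baum-Welch from a single random start can settle into a local optimum
    where distinct states merge; the basins separate within a handful of
    iterations, so many cheap short runs followed by one long refinement is
    far more robust than a single long run at the same total cost.
    Deterministic given ``config.seed``.
    """
    chunks = list(chunks)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best_params, best_ll = None, -np.inf
    for s in seeds:
        cfg = TrainConfig(
            n_states=config.n_states,
            n_sampled_chunks=config.n_sampled_chunks,
            max_iterations=short_iterations,
            pseudo_count=config.pseudo_count,
            convergence_delta=-1.0,
            seed=int(s),
        )
        fit = train(chunks, cfg)
        ll = log_likelihood(fit.params, chunks)
        if ll > best_ll:
            best_params, best_ll = fit.params, ll
    final_cfg = TrainConfig(
        n_states=config.n_states,
        n_sampled_chunks=config.n_sampled_chunks,
        max_iterations=max(1, config.max_iterations - short_iterations),
        pseudo_count=config.pseudo_count,
        convergence_delta=config.convergence_delta,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return train(chunks, final_cfg, init=best_params)


def aic_bic(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2L; BIC = k ln(n) - 2L with n evaluation bins."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 2.0 * k - 2.0 * loglik, k * float(np.log(n)) - 2.0 * loglik


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def compare_models(reference: HMMParams, other: HMMParams, feature_subset=None):
    """Per-reference-state maximum Pearson correlation of emission vectors.

    Returns ``(max_corr, argmax_state)`` arrays of length ``reference.n_states``;
    a state whose (possibly subset-restricted) emission vector is constant gets
    NaN / -1.  ``feature_subset`` restricts the comparison to a shared feature
    subset (e.g. one mark's datasets).
    """
    e_ref = reference.emissions
    e_oth = other.emissions
    if feature_subset is not None:
        idx = np.asarray(feature_subset)
        e_ref = e_ref[:, idx]
        e_oth = e_oth[:, idx]
    if e_ref.shape[1] != e_oth.shape[1]:
        raise ValueError("models must share a feature set for comparison")
    max_corr = np.full(e_ref.shape[0], np.nan)
    argmax = np.full(e_ref.shape[0], -1, dtype=np.int64)
    for s in range(e_ref.shape[0]):
        corrs = np.array([_safe_corr(e_ref[s], e_oth[t]) for t in range(e_oth.shape[0])])
        if np.isnan(corrs).all():
            continue
        j = int(np.nanargmax(corrs))
        max_corr[s] = corrs[j]
        argmax[s] = j
    return max_corr, argmax


def mark_tissue_correlation(params: HMMParams, metadata, mark: str, groups=None):
    """For one mark, correlate each state's per-dataset emissions with a binary
    tissue-group indicator and report the maximum over states per group.

    ``metadata`` is a DataFrame aligned to the emission columns with columns
    ``mark`` and ``group``.  Returns a DataFrame indexed by group with the
    maximum correlation and the maximizing state.
    """
    import pandas as pd

    cols = np.flatnonzero((metadata["mark"] == mark).to_numpy())
    if len(cols) == 0:
        raise ValueError(f"no datasets for mark {mark!r}")
    sub = params.emissions[:, cols]
    col_groups = metadata["group"].to_numpy()[cols]
    if groups is None:
        groups = sorted(set(col_groups))
    rows = []
    for g in groups:
        indicator = (col_groups == g).astype(float)
        corrs = np.array([_safe_corr(sub[s], indicator) for s in range(params.n_states)])
        if np.isnan(corrs).all():
            rows.append((g, np.nan, -1))
        else:
            s = int(np.nanargmax(corrs))
            rows.append((g, corrs[s], s))
    return pd.DataFrame(rows, columns=["group", "max_corr", "state"]).set_index("group")
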