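"""Synthetic inputs generated from a known ground truth.

Every input class the pipeline consumes can be produced here without any
download: multi-dataset binary tracks sampled from a known HMM, matched
signal/control read sets that binarize back to a chosen truth track, toy
annotations with closed-form expected fold enrichments, and toy
gene/expression tables with chosen per-state effect sizes.  All generators
are deterministic per seed.

The default desk-scale scenario is 2 chromosomes x 1 Mb, 10 features and 5
well-separated states, which runs the full pipeline in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .hmm_core import HMMParams, ObservationChunk
from .io_formats import ChromSizes, ReadSet
from .segmentation import Segmentation

__all__ = [
    "SimulationConfig",
    "well_separated_params",
    "default_config",
    "simulate_genome",
    "simulate_reads",
    "make_toy_annotations",
    "make_toy_genes",
    "make_toy_expression",
]


def well_separated_params(
    n_states: int = 5,
    n_features: int = 10,
    p_on: float = 0.9,
    p_off: float = 0.1,
    stay: float = 0.95,
    seed: int = 0,
) -> HMMParams:
    """A truth model whose states are easy to tell apart: each state switches
    on a distinct block of features (emission ``p_on`` there, ``p_off``
    elsewhere) and transitions are sticky with probability ``stay``."""
    rng = np.random.default_rng(seed)
    emissions = np.full((n_states, n_features), p_off)
    # distinct feature blocks per state, cycling when D < 2S
    per = max(1, n_features // n_states)
    for s in range(n_states):
        lo = (s * per) % n_features
        emissions[s, lo : lo + per] = p_on
        # one extra distinguishing feature keeps states unique when D % S != 0
        emissions[s, (s + n_features - 1) % n_features] = p_on
    transitions = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(transitions, stay)
    initial = rng.dirichlet(np.ones(n_states) * 50)
    return HMMParams(emissions=emissions, transitions=transitions, initial=initial)


@dataclass
class SimulationConfig:
    chromsizes: ChromSizes
    params: HMMParams
    metadata: pd.DataFrame | None = None
    binsize: int = 200
    chunk_limit: int = 1_000_000
    signal_rate: float = 20.0  # mean reads per present bin
    background_rate: float = 0.5  # mean reads per absent/control bin
    seed: int = 0

    def __post_init__(self):
        if self.signal_rate <= 0 or self.background_rate < 0:
            raise ValueError("rates must be positive")

    def manifest(self) -> dict:
        """Self-describing record of the generating conditions."""
        return {
            "chromsizes": dict(self.chromsizes.items()),
            "n_states": self.params.n_states,
            "n_features": self.params.n_features,
            "binsize": self.binsize,
            "chunk_limit": self.chunk_limit,
            "signal_rate": self.signal_rate,
            "background_rate": self.background_rate,
            "seed": self.seed,
        }


def default_config(seed: int = 0) -> SimulationConfig:
    chromsizes = ChromSizes({"chr1": 1_000_000, "chr2": 1_000_000})
    return SimulationConfig(chromsizes=chromsizes, params=well_separated_params(seed=seed), seed=seed)


def _sample_path(params: HMMParams, n: int, rng: np.random.Generator) -> np.ndarray:
    cum_init = np.cumsum(params.initial)
    cum_trans = np.cumsum(params.transitions, axis=1)
    u = rng.random(n)
    path = np.empty(n, dtype=np.int64)
    path[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, n):
        path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
    return path


def simulate_genome(config: SimulationConfig):
    """Sample a state path per chromosome and Bernoulli observations from it.

    Returns ``(truth Segmentation, list of ObservationChunk)`` with chunks of
    at most ``chunk_limit`` bases, tagged "chrN.k" when a chromosome splits.
    """
    rng = np.random.default_rng(config.seed)
    params = config.params
    states: dict[str, np.ndarray] = {}
    chunks: list[ObservationChunk] = []
    bins_per_chunk = max(1, config.chunk_limit // config.binsize)
    for chrom in config.chromsizes:
        n = config.chromsizes.n_bins(chrom, config.binsize)
        path = _sample_path(params, n, rng)
        obs = (rng.random((n, params.n_features)) < params.emissions[path]).astype(np.uint8)
        states[chrom] = path
        n_parts = -(-n // bins_per_chunk)
        for k in range(n_parts):
            lo, hi = k * bins_per_chunk, min((k + 1) * bins_per_chunk, n)
            tag = chrom if n_parts == 1 else f"{chrom}.{k}"
            chunks.append(ObservationChunk(chrom=chrom, start_bin=lo, data=obs[lo:hi], tag=tag))
    seg = Segmentation.from_states(
        states, config.chromsizes, binsize=config.binsize, n_states=params.n_states
    )
    return seg, chunks


def simulate_reads(
    truth: dict,
    chromsizes: ChromSizes,
    signal_rate: float = 20.0,
    background_rate: float = 0.5,
    binsize: int = 200,
    shift: int = 100,
    read_length: int = 36,
    seed: int = 0,
):
    """Signal and control read sets whose binarization recovers ``truth``.

    ``truth`` maps chrom -> {0,1} per-bin array.  Per-bin read counts are
    Poisson: mean ``signal_rate`` in present bins and ``background_rate``
    elsewhere (control bins always at the background rate).  Reads are placed
    so that the shifted 5' position used by counting lands uniformly inside
    the intended bin, with uniform strand where chromosome bounds allow.
    """
    rng = np.random.default_rng(seed)
    sig_records, ctl_records = [], []
    for chrom in chromsizes:
        calls = np.asarray(truth[chrom])
        length = chromsizes[chrom]
        lam = np.where(calls == 1, signal_rate, background_rate)
        for records, rates in ((sig_records, lam), (ctl_records, np.full(len(calls), background_rate))):
            counts = rng.poisson(rates)
            for b in np.flatnonzero(counts):
                bin_lo = b * binsize
                bin_hi = min((b + 1) * binsize, length)
                pos = rng.integers(bin_lo, bin_hi, size=counts[b])
                strands = rng.random(counts[b]) < 0.5
                for p, minus in zip(pos, strands):
                    if minus and p + shift + 1 <= length:
                        # minus-strand: end - 1 - shift == p
                        end = p + shift + 1
                        start = max(0, end - read_length)
                        records.append((chrom, start, end, "-"))
                    else:
                        # plus-strand: start + shift == p (clip at chromosome start)
                        start = p - shift
                        if start < 0:
                            start = 0  # counting clips the shifted position anyway
                            end = min(length, shift + 1)
                            records.append((chrom, start, end, "+"))
                            continue
                        end = min(length, start + read_length)
                        if end <= start + shift:
                            end = min(length, start + shift + 1)
                        records.append((chrom, start, end, "+"))
    return ReadSet.from_records(sig_records), ReadSet.from_records(ctl_records)


def make_toy_annotations(
    truth_seg: Segmentation,
    target_states,
    hit_rate: float = 1.0,
    n_intervals: int = 200,
    interval_length: int = 200,
    seed: int = 0,
    label: str = "toy",
) -> AnnotationSet:
    """Annotation intervals enriched in ``target_states`` by construction.

    Each interval is placed, with probability ``hit_rate``, entirely inside a
    run of a target state, and otherwise entirely inside a non-target run
    (runs chosen length-weighted in both cases).  The expected overlap
    fraction with the target states is therefore ``hit_rate`` and the analytic
    fold enrichment of a single target state is ``hit_rate / coverage``; with
    ``hit_rate = 1`` it is exactly ``1 / coverage``.
    """
    if not (0.0 <= hit_rate <= 1.0):
        raise ValueError("hit_rate must be in [0, 1]")
    target_states = set(np.atleast_1d(target_states).tolist())
    rng = np.random.default_rng(seed)
    b = truth_seg.binsize
    # state runs as base intervals, truncated at chromosome ends
    target_runs, other_runs = [], []
    for chrom in truth_seg.chromsizes:
        pos = 0
        length = truth_seg.chromsizes[chrom]
        for state, nbins in truth_seg.runs[chrom]:
            end = min(pos + nbins * b, length)
            if end - pos >= interval_length:
                (target_runs if state in target_states else other_runs).append((chrom, pos, end))
            pos = end
    if not target_runs or not other_runs:
        raise ValueError("no run of the required length on one side of the target set")

    def weights(runs):
        w = np.array([e - s for _, s, e in runs], dtype=float)
        return w / w.sum()

    w_target, w_other = weights(target_runs), weights(other_runs)
    by_chrom: dict[str, list] = {}
    for _ in range(n_intervals):
        if rng.random() < hit_rate:
            chrom, lo, hi = target_runs[rng.choice(len(target_runs), p=w_target)]
        else:
            chrom, lo, hi = other_runs[rng.choice(len(other_runs), p=w_other)]
        start = int(rng.integers(lo, hi - interval_length + 1))
        by_chrom.setdefault(chrom, []).append((start, start + interval_length))
    return AnnotationSet(label=label, intervals={c: np.array(v) for c, v in by_chrom.items()})


def make_toy_genes(
    chromsizes: ChromSizes,
    n_genes: int = 100,
    gene_length: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random non-validated toy gene coordinates with alternating strands."""
    rng = np.random.default_rng(seed)
    chroms = list(chromsizes)
    sizes = np.array([chromsizes[c] for c in chroms], dtype=float)
    rows = []
    for i in range(n_genes):
        ci = rng.choice(len(chroms), p=sizes / sizes.sum())
        chrom = chroms[ci]
        start = int(rng.integers(0, chromsizes[chrom] - gene_length))
        rows.append(
            (f"G{i:04d}", chrom, start, start + gene_length, "+" if i % 2 == 0 else "-", "protein_coding")
        )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"])
    return df.set_index("gene_id")


def make_toy_expression(
    genes: pd.DataFrame,
    truth_seg: Segmentation,
    state_effects,
    noise_sd: float = 0.1,
    n_samples: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene expression (log(RPKM+1) scale) centered on the effect size of
    the gene's majority state, with Gaussian noise, clipped at zero."""
    state_effects = np.asarray(state_effects, dtype=float)
    rng = np.random.default_rng(seed)
    means = []
    for _, row in genes.iterrows():
        states = truth_seg.states(row["chrom"])
        b0 = row["start"] // truth_seg.binsize
        b1 = (row["end"] - 1) // truth_seg.binsize + 1
        majority = np.bincount(states[b0:b1], minlength=truth_seg.n_states).argmax()
        means.append(state_effects[majority])
    means = np.asarray(means)
    data = np.clip(
        means[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples)), 0.0, None
    )
    return pd.DataFrame(data, index=genes.index, columns=[f"E{j:03d}" for j in range(n_samples)])
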