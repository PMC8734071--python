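"""Genome-wide state annotation from a fitted model.

Each 200-bp bin gets the state with the highest forward-backward posterior
(ties go to the lowest state index), matching the semantics under which the
published annotation was produced; Viterbi paths are not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm_core import HMMParams, ObservationChunk, forward_backward
from .io_formats import ChromSizes

__all__ = ["Segmentation", "CoverageError", "decode", "state_coverage"]


class CoverageError(ValueError):
    """Chunks do not tile the genome exactly once."""


@dataclass
class Segmentation:
    """Run-length encoded per-bin state assignments per chromosome."""

    chromsizes: ChromSizes
    binsize: int
    runs: dict  # chrom -> (n_runs, 2) int array of (state, n_bins)
    n_states: int
    labels: dict | None = None  # state index -> mnemonic label

    def __post_init__(self):
        for chrom in self.chromsizes:
            if chrom not in self.runs:
                raise CoverageError(f"chromosome {chrom} missing from segmentation")
            arr = np.asarray(self.runs[chrom], dtype=np.int64).reshape(-1, 2)
            self.runs[chrom] = arr
            if len(arr) and (arr[:, 1] < 1).any():
                raise ValueError("run lengths must be >= 1")
            if len(arr) and (arr[:, 0] >= self.n_states).any():
                raise ValueError("state index out of range")
            expect = self.chromsizes.n_bins(chrom, self.binsize)
            if arr[:, 1].sum() != expect:
                raise CoverageError(
                    f"{chrom}: runs cover {arr[:, 1].sum()} bins, expected {expect}"
                )

    @classmethod
    def from_states(
        cls,
        states: dict,
        chromsizes: ChromSizes,
        binsize: int = 200,
        n_states: int | None = None,
        labels: dict | None = None,
    ) -> "Segmentation":
        if n_states is None:
            n_states = int(max(int(np.max(v)) for v in states.values())) + 1
        runs = {}
        for chrom, arr in states.items():
            arr = np.asarray(arr, dtype=np.int64)
            if len(arr) == 0:
                runs[chrom] = np.empty((0, 2), dtype=np.int64)
                continue
            change = np.flatnonzero(np.diff(arr) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(arr)]))
            runs[chrom] = np.column_stack((arr[starts], ends - starts))
        return cls(chromsizes=chromsizes, binsize=binsize, runs=runs, n_states=n_states, labels=labels)

    def states(self, chrom: str) -> np.ndarray:
        """Dense per-bin state array for one chromosome."""
        arr = self.runs[chrom]
        return np.repeat(arr[:, 0], arr[:, 1])

    def all_states(self) -> np.ndarray:
        """Per-bin states concatenated over chromosomes in ChromSizes order."""
        return np.concatenate([self.states(c) for c in self.chromsizes])

    def state_label(self, state: int) -> str:
        if self.labels and state in self.labels:
            return f"{state + 1}_{self.labels[state]}"
        return f"S{state + 1}"


def decode(
    params: HMMParams,
    chunks,
    chromsizes: ChromSizes | None = None,
    binsize: int = 200,
) -> Segmentation:
    """Max-posterior decoding of chunked observations into a segmentation.

    Chunks must tile each chromosome exactly once; gaps or overlaps raise
    :class:`CoverageError`.  When ``chromsizes`` is omitted, chromosome
    lengths are inferred from the bin counts (final bin full-width).
    """
    by_chrom: dict[str, list[ObservationChunk]] = {}
    for ch in chunks:
        by_chrom.setdefault(ch.chrom, []).append(ch)
    states: dict[str, np.ndarray] = {}
    for chrom, chs in by_chrom.items():
        chs.sort(key=lambda c: c.start_bin)
        pos = 0
        parts = []
        for ch in chs:
            if ch.start_bin != pos:
                raise CoverageError(
                    f"{chrom}: chunk starts at bin {ch.start_bin}, expected {pos}"
                )
            post, _ = forward_backward(params, ch)
            # np.argmax takes the lowest index on ties
            parts.append(np.argmax(post.gamma, axis=1))
            pos += ch.n_bins
        states[chrom] = np.concatenate(parts)
    if chromsizes is None:
        chromsizes = ChromSizes({c: len(v) * binsize for c, v in states.items()})
    else:
        for chrom, arr in states.items():
            if len(arr) != chromsizes.n_bins(chrom, binsize):
                raise CoverageError(f"{chrom}: chunks do not cover the chromosome")
    return Segmentation.from_states(
        states, chromsizes, binsize=binsize, n_states=params.n_states
    )


def state_coverage(seg: Segmentation) -> np.ndarray:
    """Fraction of the genome (in bases) covered by each state.

    The final bin of each chromosome is weighted by its true (possibly
    truncated) base length; fractions sum to 1.
    """
    counts = np.zeros(seg.n_states, dtype=np.float64)
    for chrom in seg.chromsizes:
        states = seg.states(chrom)
        lengths = seg.chromsizes.bin_lengths(chrom, seg.binsize)
        np.add.at(counts, states, lengths)
    return counts / counts.sum()
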