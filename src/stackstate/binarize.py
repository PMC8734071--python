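"""Signal/control read sets -> binary presence calls at 200-bp resolution.

Each bin is called present (1) when its read count is improbably high under a
Poisson background whose rate comes from a depth-scaled control (or, without a
control, from the genome-wide mean signal).  This mirrors the standard
binarization used for chromatin-mark ChIP-seq: shift reads 100 bases toward
their 3' end, count shifted 5' positions per 200-bp bin, and test the upper
Poisson tail at p <= 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ChromSizes, DatasetDescriptor, ReadSet

__all__ = [
    "CountTrack",
    "BinaryTrack",
    "count_reads",
    "binarize_track",
    "merge_binaries",
    "split_descriptor_table",
    "MergeError",
]


class MergeError(ValueError):
    """Datasets cannot be merged into one observation matrix."""


@dataclass
class CountTrack:
    """Per-chromosome non-negative read counts per bin."""

    counts: dict  # chrom -> int64 array
    binsize: int

    @property
    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))


@dataclass
class BinaryTrack:
    """Per-chromosome {0,1} calls per bin for one dataset."""

    calls: dict  # chrom -> uint8 array
    binsize: int


def count_reads(
    reads: ReadSet,
    chromsizes: ChromSizes,
    binsize: int = 200,
    shift: int = 100,
) -> CountTrack:
    """Count shifted 5' read positions per bin.

    Plus-strand reads contribute at ``start + shift``, minus-strand reads at
    ``end - 1 - shift``; shifted positions are clipped into ``[0, L)``.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    if shift < 0:
        raise ValueError("shift must be non-negative")
    counts = {
        chrom: np.zeros(chromsizes.n_bins(chrom, binsize), dtype=np.int64)
        for chrom in chromsizes
    }
    if len(reads) == 0:
        return CountTrack(counts, binsize)
    plus = reads.strand == "+"
    pos = np.where(plus, reads.start + shift, reads.end - 1 - shift)
    for chrom in chromsizes:
        mask = reads.chrom == chrom
        if not mask.any():
            continue
        p = np.clip(pos[mask], 0, chromsizes[chrom] - 1)
        np.add.at(counts[chrom], p // binsize, 1)
    return CountTrack(counts, binsize)


def binarize_track(
    signal: CountTrack,
    control: CountTrack | None = None,
    p_threshold: float = 1e-4,
) -> BinaryTrack:
    """Poisson upper-tail presence call per bin.

    The background rate in each bin is ``max(control * depth_ratio,
    mean_signal)`` where ``depth_ratio`` is total signal reads over total
    control reads; without a control the genome-wide mean signal per bin is
    used everywhere.  A bin is 1 iff ``P(X >= observed | Poisson(rate)) <=
    p_threshold``.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    for arr in signal.counts.values():
        if (arr < 0).any():
            raise ValueError("negative signal counts")
    n_bins = signal.n_bins
    mean_signal = signal.total / n_bins if n_bins else 0.0
    if control is not None:
        if set(control.counts) != set(signal.counts) or any(
            len(control.counts[c]) != len(signal.counts[c]) for c in signal.counts
        ):
            raise ValueError("signal and control tracks are not aligned")
        for arr in control.counts.values():
            if (arr < 0).any():
                raise ValueError("negative control counts")
        total_control = control.total
        ratio = signal.total / total_control if total_control > 0 else 0.0
    calls = {}
    for chrom, obs in signal.counts.items():
        lam = np.full(len(obs), mean_signal, dtype=float)
        if control is not None:
            lam = np.maximum(control.counts[chrom] * ratio, lam)
        # P(X >= obs) = sf(obs - 1); an observation of 0 is never a call.
        pvals = stats.poisson.sf(obs - 1, lam)
        out = ((pvals <= p_threshold) & (obs > 0)).astype(np.uint8)
        calls[chrom] = out
    return BinaryTrack(calls, signal.binsize)


def merge_binaries(
    tracks: list[BinaryTrack],
    chromsizes: ChromSizes,
    chunk_limit: int = 1_000_000,
):
    """Stack per-dataset binary tracks into chromosome-chunked matrices.

    Column order follows the order of ``tracks`` (i.e. the dataset-descriptor
    order), independent of how datasets were batched upstream.  Each chunk
    covers at most ``chunk_limit`` bases and never spans chromosomes; tags are
    "chrN" for unsplit chromosomes and "chrN.k" otherwise.

    Returns a list of ``(chrom, start_bin, matrix, tag)`` tuples in genome
    order.
    """
    from .hmm_core import ObservationChunk

    if not tracks:
        raise MergeError("no tracks to merge")
    binsize = tracks[0].binsize
    for i, tr in enumerate(tracks):
        if tr.binsize != binsize:
            raise MergeError(f"track {i} has binsize {tr.binsize} != {binsize}")
        for chrom in chromsizes:
            expect = chromsizes.n_bins(chrom, binsize)
            if chrom not in tr.calls or len(tr.calls[chrom]) != expect:
                raise MergeError(f"track {i} has mismatched bin count on {chrom}")
    bins_per_chunk = max(1, chunk_limit // binsize)
    chunks = []
    for chrom in chromsizes:
        stacked = np.column_stack([tr.calls[chrom] for tr in tracks]).astype(np.uint8)
        n = stacked.shape[0]
        n_parts = -(-n // bins_per_chunk)
        for k in range(n_parts):
            lo, hi = k * bins_per_chunk, min((k + 1) * bins_per_chunk, n)
            tag = chrom if n_parts == 1 else f"{chrom}.{k}"
            chunks.append(ObservationChunk(chrom=chrom, start_bin=lo, data=stacked[lo:hi], tag=tag))
    return chunks


def split_descriptor_table(
    descriptors: list[DatasetDescriptor], batch_size: int = 10
) -> list[list[DatasetDescriptor]]:
    """Split a dataset table into consecutive batches of at most ``batch_size``."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return [descriptors[i : i + batch_size] for i in range(0, len(descriptors), batch_size)]
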