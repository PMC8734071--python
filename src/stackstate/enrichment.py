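"""Overlap statistics used to characterize chromatin states.

Fold enrichment of state s in annotation x follows the uniform genome-wide
background identity::

    FE(x, s) = (#SX * #G) / (#S * #X)

with #S the bases assigned to the state, #X the annotated bases, #SX their
overlap and #G the genome size.  All counting is at single-base resolution,
so annotations need not respect the 200-bp segmentation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ChromSizes, merge_intervals
from .segmentation import Segmentation, state_coverage

__all__ = [
    "AnnotationSet",
    "AnchorSet",
    "EnrichmentTable",
    "fold_enrichment",
    "relative_enrichment",
    "positional_enrichment",
    "sampled_overlap_probabilities",
]


@dataclass
class AnnotationSet:
    """A labeled set of merged, non-overlapping genomic intervals."""

    label: str
    intervals: dict  # chrom -> (n, 2) int64 array, sorted, non-overlapping

    def __post_init__(self):
        merged = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"{self.label}/{chrom}: empty or inverted interval")
            merged[chrom] = merge_intervals(arr)
        self.intervals = merged

    @property
    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values()))

    def clipped(self, chromsizes: ChromSizes) -> "AnnotationSet":
        """Restrict to chromosomes in ``chromsizes``, clipping at their ends."""
        out = {}
        for chrom, arr in self.intervals.items():
            if chrom not in chromsizes:
                continue
            arr = np.clip(arr, 0, chromsizes[chrom])
            arr = arr[arr[:, 0] < arr[:, 1]]
            if len(arr):
                out[chrom] = arr
        return AnnotationSet(self.label, out)


@dataclass
class AnchorSet:
    """Labeled single-base anchor points (e.g. TSS), with strand."""

    label: str
    chrom: np.ndarray
    position: np.ndarray
    strand: np.ndarray

    def __len__(self) -> int:
        return len(self.position)

    @classmethod
    def from_records(cls, label: str, records) -> "AnchorSet":
        records = list(records)
        chrom = np.array([r[0] for r in records], dtype=object)
        pos = np.array([r[1] for r in records], dtype=np.int64)
        strand = np.array([r[2] for r in records], dtype=object)
        return cls(label, chrom, pos, strand)


@dataclass
class EnrichmentTable:
    """States x annotations fold enrichments plus the marginal rows/columns."""

    fe: pd.DataFrame  # index: state label, columns: annotation label
    genome_fraction: pd.Series  # per annotation, #X / #G
    state_coverage: pd.Series  # per state, #S / #G

    def to_tsv(self, path) -> None:
        table = self.fe.copy()
        table.insert(0, "Genome %", 100.0 * self.state_coverage.to_numpy())
        bottom = pd.DataFrame(
            [[100.0] + list(100.0 * self.genome_fraction.to_numpy())],
            index=["Base"],
            columns=table.columns,
        )
        pd.concat([table, bottom]).to_csv(path, sep="\t", float_format="%.6g")


def _state_base_counts(seg: Segmentation) -> np.ndarray:
    counts = np.zeros(seg.n_states, dtype=np.int64)
    for chrom in seg.chromsizes:
        lengths = seg.chromsizes.bin_lengths(chrom, seg.binsize)
        np.add.at(counts, seg.states(chrom), lengths)
    return counts


def _overlap_by_state(seg: Segmentation, annot: AnnotationSet) -> np.ndarray:
    """Per-state base overlap with a (clipped) annotation, at 1-bp resolution."""
    b = seg.binsize
    counts = np.zeros(seg.n_states, dtype=np.int64)
    for chrom, arr in annot.intervals.items():
        if chrom not in seg.chromsizes:
            continue
        states = seg.states(chrom)
        for s, e in arr:
            b0, b1 = s // b, (e - 1) // b
            bins = np.arange(b0, b1 + 1)
            lo = np.maximum(s, bins * b)
            hi = np.minimum(e, (bins + 1) * b)
            np.add.at(counts, states[bins], hi - lo)
    return counts


def fold_enrichment(seg: Segmentation, annotations) -> EnrichmentTable:
    """States x annotations fold-enrichment table at base resolution.

    An annotation with no bases on the segmented chromosomes gets NaN for
    every state; a state with zero coverage gets a NaN row.
    """
    annotations = list(annotations)
    G = seg.chromsizes.total_bases
    s_counts = _state_base_counts(seg)
    labels = [seg.state_label(s) for s in range(seg.n_states)]
    fe = np.full((seg.n_states, len(annotations)), np.nan)
    x_fracs = []
    for j, annot in enumerate(annotations):
        clipped = annot.clipped(seg.chromsizes)
        X = clipped.total_bases
        x_fracs.append(X / G)
        if X == 0:
            continue
        sx = _overlap_by_state(seg, clipped)
        with np.errstate(divide="ignore", invalid="ignore"):
            col = (sx * G) / (s_counts * X)
        col[s_counts == 0] = np.nan
        fe[:, j] = col
    names = [a.label for a in annotations]
    return EnrichmentTable(
        fe=pd.DataFrame(fe, index=labels, columns=names),
        genome_fraction=pd.Series(x_fracs, index=names),
        state_coverage=pd.Series(s_counts / G, index=labels),
    )


def relative_enrichment(
    seg: Segmentation, foreground: AnnotationSet, background: AnnotationSet
) -> pd.Series:
    """Per-state FE(foreground) / FE(background), each against the whole genome.

    Used for variant-set analyses where a matched background (e.g. common
    variants) controls for generic accessibility of the tested positions.
    NaN where the background enrichment is zero or undefined.
    """
    if foreground.clipped(seg.chromsizes).total_bases == 0:
        raise ValueError("empty foreground set")
    table = fold_enrichment(seg, [foreground, background])
    fg = table.fe.iloc[:, 0]
    bg = table.fe.iloc[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fg / bg
    ratio[bg == 0] = np.nan
    ratio.name = f"{foreground.label}/{background.label}"
    return ratio


def positional_enrichment(
    seg: Segmentation,
    anchors: AnchorSet,
    window: int = 25_000,
    step: int = 200,
) -> pd.DataFrame:
    """State enrichment at signed offsets around anchor points.

    Offset 0 is the bin containing the anchor base; positive offsets run in
    the anchor's 5'->3' direction (minus-strand anchors are flipped).  For
    each offset, enrichment is the fraction of in-bounds anchors whose
    offset bin carries the state, divided by the genome-wide fraction of bins
    in that state.  Anchors whose offset bin falls off the chromosome are
    skipped for that offset only.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    if seg.binsize != step:
        raise ValueError("step must equal the segmentation bin size")
    half = window // step
    offsets = np.arange(-half, half + 1)
    n_bins_total = 0
    bin_counts = np.zeros(seg.n_states, dtype=np.int64)
    for chrom in seg.chromsizes:
        st = seg.states(chrom)
        np.add.at(bin_counts, st, 1)
        n_bins_total += len(st)
    genome_frac = bin_counts / n_bins_total

    counts = np.zeros((seg.n_states, len(offsets)), dtype=np.int64)
    totals = np.zeros(len(offsets), dtype=np.int64)
    sign = np.where(anchors.strand == "-", -1, 1)
    anchor_bin = anchors.position // step
    for chrom in seg.chromsizes:
        mask = anchors.chrom == chrom
        if not mask.any():
            continue
        st = seg.states(chrom)
        ab = anchor_bin[mask]
        sg = sign[mask]
        for k, off in enumerate(offsets):
            b = ab + sg * off
            ok = (b >= 0) & (b < len(st))
            totals[k] += int(ok.sum())
            np.add.at(counts[:, k], st[b[ok]], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = counts / totals
        enr = frac / genome_frac[:, None]
    labels = [seg.state_label(s) for s in range(seg.n_states)]
    return pd.DataFrame(enr, index=labels, columns=offsets * step)


def sampled_overlap_probabilities(
    seg: Segmentation,
    external: dict,
    sample_groups: dict,
    n_bins: int = 100,
    repetitions: int = 21,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimated probability that a bin of each state overlaps each external
    state, per sample group.

    For every state of ``seg``, ``n_bins`` of its assigned bins are sampled
    uniformly (with replacement when fewer exist); for each external sample
    the frequency of each external state among the sampled bins is recorded.
    Frequencies are averaged over ``repetitions`` resamplings and then over
    the samples of each group.  Rows are NaN for states with no assigned
    bins.  Column index: (group, external state).
    """
    rng = np.random.default_rng(seed)
    ext_states = {name: s.all_states() for name, s in external.items()}
    n_ext = max(int(v.max()) for v in ext_states.values()) + 1
    full = seg.all_states()
    for name, v in ext_states.items():
        if len(v) != len(full):
            raise ValueError(f"external segmentation {name!r} not aligned to seg bins")
    groups = sorted(set(sample_groups.values()))
    samples_by_group = {g: [s for s, gg in sample_groups.items() if gg == g] for g in groups}
    out = np.full((seg.n_states, len(groups) * n_ext), np.nan)
    for s in range(seg.n_states):
        assigned = np.flatnonzero(full == s)
        if len(assigned) == 0:
            continue
        # freq[sample, ext_state], averaged over repetitions
        freq = {name: np.zeros(n_ext) for name in external}
        for _ in range(repetitions):
            replace = len(assigned) < n_bins
            pick = rng.choice(assigned, size=n_bins, replace=replace)
            for name, v in ext_states.items():
                freq[name] += np.bincount(v[pick], minlength=n_ext) / n_bins
        for name in freq:
            freq[name] /= repetitions
        for gi, g in enumerate(groups):
            members = samples_by_group[g]
            if not members:
                continue
            avg = np.mean([freq[m] for m in members], axis=0)
            out[s, gi * n_ext : (gi + 1) * n_ext] = avg
    columns = pd.MultiIndex.from_product([groups, range(n_ext)], names=["group", "ext_state"])
    labels = [seg.state_label(s) for s in range(seg.n_states)]
    return pd.DataFrame(out, index=labels, columns=columns)
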