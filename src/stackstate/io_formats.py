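"""Readers and writers for the on-disk formats the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention); 200-bp bins
are ``[200*i, 200*(i+1))``.  Readers accept gzipped files transparently when
the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "ReadSet",
    "DatasetDescriptor",
    "FormatError",
    "ParseError",
    "read_chrom_sizes",
    "read_reads",
    "write_binarized_chunk",
    "read_binarized_chunk",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "read_annotation_bed",
    "read_dataset_table",
    "write_dataset_table",
    "read_expression_matrix",
    "read_gene_info",
    "save_model",
    "load_model",
]


class FormatError(ValueError):
    """A file violates the expected dialect."""


class ParseError(FormatError):
    """A line could not be parsed; the message names the line number."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name -> length (bases) map."""

    sizes: dict

    def __post_init__(self):
        for name, length in self.sizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def total_bases(self) -> int:
        return sum(self.sizes.values())

    def n_bins(self, chrom: str, binsize: int = 200) -> int:
        return -(-self.sizes[chrom] // binsize)

    def bin_lengths(self, chrom: str, binsize: int = 200) -> np.ndarray:
        """Per-bin base lengths; the final bin may be truncated."""
        n = self.n_bins(chrom, binsize)
        out = np.full(n, binsize, dtype=np.int64)
        rem = self.sizes[chrom] - (n - 1) * binsize
        out[-1] = rem
        return out


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ReadSet:
    """Aligned-read intervals (chrom, start, end, strand)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.start)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadSet):
            return NotImplemented
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.array_equal(self.strand, other.strand)
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple], n_dropped: int = 0) -> "ReadSet":
        records = list(records)
        if not records:
            empty_s = np.empty(0, dtype=object)
            empty_i = np.empty(0, dtype=np.int64)
            return cls(empty_s, empty_i, empty_i.copy(), empty_s.copy(), n_dropped)
        chrom, start, end, strand = zip(*records)
        return cls(
            np.asarray(chrom, dtype=object),
            np.asarray(start, dtype=np.int64),
            np.asarray(end, dtype=np.int64),
            np.asarray(strand, dtype=object),
            n_dropped,
        )


@dataclass(frozen=True)
class DatasetDescriptor:
    """One row of a cell_mark table: sample label, "<EID>-<mark>" feature name,
    signal path, optional control path."""

    sample: str
    feature: str
    signal_path: str
    control_path: str | None = None


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column (name, length) chrom.sizes TSV."""
    sizes: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-delimited columns")
            name = parts[0]
            if name in sizes:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = int(parts[1])
    return ChromSizes(sizes)


def read_reads(path, chromsizes: ChromSizes | None = None, format: str = "tagAlign") -> ReadSet:
    """Read a tagAlign / BED file of aligned reads.

    Both dialects are BED3 plus an optional strand in column 6.  Reads on
    chromosomes absent from ``chromsizes`` are dropped; the count of dropped
    reads is logged and stored on the returned :class:`ReadSet`.
    """
    if format not in ("tagAlign", "BED"):
        raise ValueError(f"unknown read format {format!r}")
    records = []
    n_dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-delimited columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            if chromsizes is not None and chrom not in chromsizes:
                n_dropped += 1
                continue
            records.append((chrom, start, end, strand))
    if n_dropped:
        logger.warning("%s: dropped %d reads on chromosomes absent from ChromSizes", path, n_dropped)
    return ReadSet.from_records(records, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Binarized chunk files: two header lines (sample TAB chrom-tag; feature names)
# followed by one tab-delimited row of {0,1,2} per 200-bp bin.
# ---------------------------------------------------------------------------

def write_binarized_chunk(matrix, sample: str, chrom_tag: str, feature_names, path) -> None:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("chunk matrix must be 2-D (bins x datasets)")
    if not np.isin(matrix, (0, 1, 2)).all():
        raise ValueError("chunk values must be in {0, 1, 2}")
    feature_names = list(feature_names)
    if len(feature_names) != matrix.shape[1]:
        raise ValueError("feature_names length must equal column count")
    with _open_text(path, "wt") as fh:
        fh.write(f"{sample}\t{chrom_tag}\n")
        fh.write("\t".join(feature_names) + "\n")
        for row in matrix:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_binarized_chunk(path):
    """Read a binarized chunk file -> (matrix, sample, chrom_tag, feature_names)."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected 'sample<TAB>chrom_tag'")
        sample, chrom_tag = header
        feature_names = fh.readline().rstrip("\n").split("\t")
        ncol = len(feature_names)
        rows = []
        for lineno, line in enumerate(fh, 3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncol:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(parts)} columns, header has {ncol}"
                )
            rows.append(parts)
    matrix = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.empty((0, ncol), dtype=np.uint8)
    )
    if rows and not np.isin(matrix, (0, 1, 2)).all():
        raise FormatError(f"{path}: values outside {{0,1,2}}")
    return matrix, sample, chrom_tag, feature_names


# ---------------------------------------------------------------------------
# Segmentation / annotation BED
# ---------------------------------------------------------------------------

def write_segmentation_bed(seg, path, labels: dict | None = None, rgb: dict | None = None) -> None:
    """Write a segmentation as 4-column BED (9-column when ``rgb`` given).

    Maximal runs of the same state are merged into single lines; the last
    interval of each chromosome is truncated at the chromosome end.
    """
    with _open_text(path, "wt") as fh:
        for chrom in seg.chromsizes:
            length = seg.chromsizes[chrom]
            pos = 0
            for state, nbins in seg.runs[chrom]:
                end = min(pos + nbins * seg.binsize, length)
                name = labels[state] if labels else f"S{state + 1}"
                if rgb is not None:
                    fh.write(
                        f"{chrom}\t{pos}\t{end}\t{name}\t0\t.\t{pos}\t{end}\t{rgb[state]}\n"
                    )
                else:
                    fh.write(f"{chrom}\t{pos}\t{end}\t{name}\n")
                pos = end


def read_segmentation_bed(path, chromsizes: ChromSizes, binsize: int = 200, labels: dict | None = None):
    """Read a segmentation BED back into per-chromosome bin-state arrays.

    Returns a dict chrom -> int array of per-bin states.  ``labels`` maps
    state label -> state index; default labels "S<k>" map to k-1.
    """
    states = {
        chrom: np.full(chromsizes.n_bins(chrom, binsize), -1, dtype=np.int64)
        for chrom in chromsizes
    }
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if chrom not in chromsizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if labels is not None:
                state = labels[name]
            else:
                state = int(name.lstrip("S").split("_")[0]) - 1
            b0, b1 = start // binsize, -(-end // binsize)
            states[chrom][b0:b1] = state
    for chrom, arr in states.items():
        if (arr < 0).any():
            raise FormatError(f"{path}: chromosome {chrom} has unannotated bins")
    return states


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or book-ended [start, end) intervals (n x 2 array)."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(intervals, dtype=np.int64)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def read_annotation_bed(path, label: str | None = None, merge: bool = True, strict: bool = False):
    """Read a BED file into an :class:`~stackstate.enrichment.AnnotationSet`.

    Book-ended/overlapping intervals are merged by default; under
    ``strict=True`` an overlap raises :class:`FormatError`.
    """
    from .enrichment import AnnotationSet

    by_chrom: dict[str, list] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            by_chrom.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    intervals = {}
    for chrom, ivals in by_chrom.items():
        arr = np.array(sorted(ivals), dtype=np.int64)
        if strict and (arr[1:, 0] < arr[:-1, 1]).any():
            raise FormatError(f"{path}: overlapping intervals on {chrom}")
        intervals[chrom] = merge_intervals(arr) if merge else arr
    if label is None:
        label = str(path)
    return AnnotationSet(label=label, intervals=intervals)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_dataset_table(path) -> list[DatasetDescriptor]:
    """Read a 3/4-column cell_mark table (sample, feature, signal, [control])."""
    out = []
    seen = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            if parts[1] in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature name {parts[1]!r}")
            seen.add(parts[1])
            out.append(
                DatasetDescriptor(parts[0], parts[1], parts[2], parts[3] if len(parts) > 3 else None)
            )
    return out


def write_dataset_table(descriptors: Iterable[DatasetDescriptor], path) -> None:
    with _open_text(path, "wt") as fh:
        for d in descriptors:
            cols = [d.sample, d.feature, d.signal_path]
            if d.control_path is not None:
                cols.append(d.control_path)
            fh.write("\t".join(cols) + "\n")


def save_model(params, outdir, manifest: dict | None = None) -> None:
    """Serialize a model as three TSV tables (emissions with feature-name
    header, transitions, initial) plus an optional JSON run manifest."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    names = params.feature_names or [f"F{d}" for d in range(params.n_features)]
    pd.DataFrame(params.emissions, columns=names).to_csv(
        os.path.join(outdir, "emissions.tsv"), sep="\t", index=False
    )
    pd.DataFrame(params.transitions).to_csv(
        os.path.join(outdir, "transitions.tsv"), sep="\t", index=False, header=False
    )
    pd.DataFrame(params.initial).to_csv(
        os.path.join(outdir, "initial.tsv"), sep="\t", index=False, header=False
    )
    if manifest is not None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def load_model(indir):
    """Load a model saved by :func:`save_model`."""
    import os

    from .hmm_core import HMMParams

    em = pd.read_csv(os.path.join(indir, "emissions.tsv"), sep="\t")
    tr = pd.read_csv(os.path.join(indir, "transitions.tsv"), sep="\t", header=None)
    init = pd.read_csv(os.path.join(indir, "initial.tsv"), sep="\t", header=None)
    return HMMParams(
        emissions=em.to_numpy(),
        transitions=tr.to_numpy(),
        initial=init.to_numpy().ravel(),
        feature_names=list(em.columns),
    )


def read_expression_matrix(path) -> pd.DataFrame:
    """Gene-by-sample expression matrix TSV (gene IDs in the first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_info(path) -> pd.DataFrame:
    """Gene coordinate table: gene_id, chrom, start, end, strand, gene_type."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["gene_id", "chrom", "start", "end", "strand", "gene_type"],
        header=None,
        comment="#",
    )
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: gene with start >= end")
    return df.set_index("gene_id")
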