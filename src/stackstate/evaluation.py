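"""AUROC evaluation of a segmentation's power to predict external annotations.

The genome is split into 200-bp bins, half train / half test at random.  On
the training half, each state's fold enrichment for the target annotation is
computed at base resolution; states are ranked by decreasing enrichment and
test bins are predicted positive prefix by prefix along that ranking.  A test
bin counts as a true positive when it overlaps the target by at least one
base.  The ROC curve has one point per ranking prefix and the AUROC is its
trapezoidal area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import AnnotationSet
from .segmentation import Segmentation

__all__ = ["ROCResult", "predictive_auroc"]


@dataclass
class ROCResult:
    fpr: np.ndarray  # non-decreasing, starts at 0, ends at 1
    tpr: np.ndarray
    auroc: float
    state_ranking: np.ndarray  # states in decreasing train-enrichment order
    seed: int


def _bin_labels_and_overlaps(seg: Segmentation, target: AnnotationSet):
    """Per-bin base overlap with the target, concatenated over chromosomes."""
    b = seg.binsize
    parts = []
    clipped = target.clipped(seg.chromsizes)
    for chrom in seg.chromsizes:
        n = seg.chromsizes.n_bins(chrom, b)
        ov = np.zeros(n, dtype=np.int64)
        for s, e in clipped.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)):
            b0, b1 = s // b, (e - 1) // b
            bins = np.arange(b0, b1 + 1)
            lo = np.maximum(s, bins * b)
            hi = np.minimum(e, (bins + 1) * b)
            ov[bins] += hi - lo
        parts.append(ov)
    return np.concatenate(parts)


def _bin_lengths(seg: Segmentation) -> np.ndarray:
    return np.concatenate(
        [seg.chromsizes.bin_lengths(c, seg.binsize) for c in seg.chromsizes]
    )


def predictive_auroc(
    seg: Segmentation,
    target: AnnotationSet,
    split: float = 0.5,
    seed: int = 0,
) -> ROCResult | None:
    """ROC of state-ranked prediction of ``target`` on held-out bins.

    Returns ``None`` when the target overlaps no test bin (AUROC undefined).
    Ties in training enrichment are broken toward the lower state index, so
    results are deterministic given the seed.
    """
    if not (0.0 < split < 1.0):
        raise ValueError("split must be in (0, 1)")
    states = seg.all_states()
    overlaps = _bin_labels_and_overlaps(seg, target)
    lengths = _bin_lengths(seg)
    n = len(states)
    rng = np.random.default_rng(seed)
    train_mask = rng.random(n) < split
    test_mask = ~train_mask

    # train-side fold enrichment restricted to training bins, base resolution
    S = seg.n_states
    s_bases = np.bincount(states[train_mask], weights=lengths[train_mask], minlength=S)
    sx_bases = np.bincount(states[train_mask], weights=overlaps[train_mask], minlength=S)
    g_bases = lengths[train_mask].sum()
    x_bases = overlaps[train_mask].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = (sx_bases * g_bases) / (s_bases * x_bases)
    fe = np.where(np.isfinite(fe), fe, -np.inf)
    # decreasing enrichment, ties toward the lower state index
    ranking = np.lexsort((np.arange(S), -fe))

    labels = overlaps[test_mask] > 0
    test_states = states[test_mask]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0:
        return None
    pos_per_state = np.bincount(test_states[labels], minlength=S)
    neg_per_state = np.bincount(test_states[~labels], minlength=S)
    tp = np.concatenate(([0], np.cumsum(pos_per_state[ranking])))
    fp = np.concatenate(([0], np.cumsum(neg_per_state[ranking])))
    tpr = tp / n_pos
    fpr = fp / n_neg if n_neg > 0 else np.ones_like(tp, dtype=float)
    auroc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auroc=auroc, state_ranking=ranking, seed=seed)
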