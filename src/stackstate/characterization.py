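"""State-level summaries: expression, per-base signals, tissue-group
structure of the emission matrix, and compact summary-dataset selection.

The feature columns of the stacked model carry metadata (epigenome ID, mark,
tissue group), which these analyses slice in different ways: averaging
emissions per mark-group cell, testing group specificity with one-sided
Mann-Whitney tests under a Bonferroni family correction, and greedily picking
a small feature subset whose Naive-Bayes state predictions agree with the
full model's annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hmm_core import HMMParams
from .segmentation import Segmentation

__all__ = [
    "DatasetMetadata",
    "TestResult",
    "DEFAULT_CV_MARKS",
    "DEFAULT_TEST_MARKS",
    "expression_by_state",
    "expression_summary",
    "positional_expression_table",
    "positional_expression",
    "mean_signal_by_state",
    "emission_cv",
    "differential_emission_tests",
    "greedy_summary_selection",
    "naive_bayes_states",
]

# marks strongly associated with promoter/enhancer activity
DEFAULT_CV_MARKS = ("DNase", "H3K27ac", "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac")
# the eight most widely profiled marks
DEFAULT_TEST_MARKS = (
    "H3K9me3",
    "H3K4me1",
    "H3K4me3",
    "H3K27me3",
    "H3K36me3",
    "H3K27ac",
    "H3K9ac",
    "DNase",
)


def DatasetMetadata(eids, marks, groups, feature_names=None) -> pd.DataFrame:
    """Per-feature metadata table aligned to the emission columns.

    Columns: ``eid``, ``mark``, ``group``; index: feature name
    "<EID>-<mark>" unless explicit names are given.
    """
    eids = list(eids)
    marks = list(marks)
    groups = list(groups)
    if not (len(eids) == len(marks) == len(groups)):
        raise ValueError("eids, marks, groups must have equal length")
    if feature_names is None:
        feature_names = [f"{e}-{m}" for e, m in zip(eids, marks)]
    df = pd.DataFrame({"eid": eids, "mark": marks, "group": groups}, index=feature_names)
    if df.index.duplicated().any():
        raise ValueError("feature names must be unique")
    return df


@dataclass
class TestResult:
    """One differential-emission test family with its Bonferroni correction."""

    table: pd.DataFrame  # columns: state, mark, group, n_in, n_out, p_value, significant
    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_bins(start: int, end: int, binsize: int) -> np.ndarray:
    """Bins that totally or partially overlap [start, end)."""
    return np.arange(start // binsize, (end - 1) // binsize + 1)


def expression_by_state(seg: Segmentation, genes: pd.DataFrame, expression: pd.Series) -> np.ndarray:
    """bp-normalized average expression per state for one sample.

    For state s the value is ``sum_{i in B_s} sum_{g in G_i} E_g / L_g``
    divided by ``sum_{i in B_s} sum_{g in G_i} 1 / L_g`` where B_s are the
    bins assigned to s and G_i the genes overlapping (totally or partially)
    bin i.  Weighting by 1/length keeps long genes from dominating through
    their many bins.  States overlapping no gene get NaN.
    """
    num = np.zeros(seg.n_states)
    den = np.zeros(seg.n_states)
    by_chrom = {c: seg.states(c) for c in seg.chromsizes}
    for gene_id, row in genes.iterrows():
        if row["chrom"] not in by_chrom:
            continue
        e_g = float(expression[gene_id])
        l_g = float(row["end"] - row["start"])
        states = by_chrom[row["chrom"]]
        bins = _gene_bins(int(row["start"]), int(row["end"]), seg.binsize)
        bins = bins[bins < len(states)]
        np.add.at(num, states[bins], e_g / l_g)
        np.add.at(den, states[bins], 1.0 / l_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def expression_summary(seg: Segmentation, genes: pd.DataFrame, expr_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-state mean and coefficient of variation of the bp-normalized
    average expression across samples (columns of ``expr_matrix``)."""
    values = np.column_stack(
        [expression_by_state(seg, genes, expr_matrix[c]) for c in expr_matrix.columns]
    )
    mean = np.nanmean(values, axis=1)
    sd = np.nanstd(values, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    labels = [seg.state_label(s) for s in range(seg.n_states)]
    return pd.DataFrame({"mean": mean, "cv": cv}, index=labels)


def _outer_tss(row) -> int:
    """5'-most annotated start: gene start on +, last base (end-1) on -."""
    if row["strand"] == "+":
        return int(row["start"])
    if row["strand"] == "-":
        return int(row["end"]) - 1
    raise ValueError(f"gene without strand: {row.name}")


def positional_expression_table(
    seg: Segmentation,
    genes: pd.DataFrame,
    expression: pd.Series,
    window: int = 25_000,
    step: int = 200,
) -> pd.DataFrame:
    """Raw states x offsets average-expression table for one sample.

    Offsets are strand-oriented multiples of ``step`` from -window to +window
    (2*window/step + 1 columns; 251 at the defaults); offset 0 is the bin
    containing the outer TSS.  Cell (s, k) averages the expression of genes
    that have a bin assigned to state s at offset k; NaN where no gene
    contributes.
    """
    half = window // step
    offsets = np.arange(-half, half + 1)
    S = seg.n_states
    total = np.zeros((S, len(offsets)))
    count = np.zeros((S, len(offsets)), dtype=np.int64)
    by_chrom = {c: seg.states(c) for c in seg.chromsizes}
    for gene_id, row in genes.iterrows():
        if row["chrom"] not in by_chrom:
            continue
        tss = _outer_tss(row)
        sign = 1 if row["strand"] == "+" else -1
        e_g = float(expression[gene_id])
        states = by_chrom[row["chrom"]]
        tss_bin = tss // step
        bins = tss_bin + sign * offsets
        ok = (bins >= 0) & (bins < len(states))
        st = states[bins[ok]]
        ks = np.flatnonzero(ok)
        total[st, ks] += e_g
        count[st, ks] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        avg = total / count
    avg[count == 0] = np.nan
    labels = [seg.state_label(s) for s in range(S)]
    return pd.DataFrame(avg, index=labels, columns=offsets * step)


def positional_expression(
    seg: Segmentation,
    genes: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    window: int = 25_000,
    step: int = 200,
    smooth_window: int = 21,
) -> pd.DataFrame:
    """TSS-centered positional expression, smoothed and averaged over samples.

    Each sample's raw table is smoothed along offsets with a centered moving
    average of width ``smooth_window`` (NaN cells are ignored within the
    window); the first and last ``smooth_window // 2`` offsets are dropped
    (251 -> 231 columns at the defaults).  The per-sample tables are then
    averaged.
    """
    if smooth_window % 2 != 1:
        raise ValueError("smooth_window must be odd")
    margin = smooth_window // 2
    tables = []
    for c in expr_matrix.columns:
        raw = positional_expression_table(seg, genes, expr_matrix[c], window, step)
        arr = raw.to_numpy()
        n_off = arr.shape[1]
        smoothed = np.full((arr.shape[0], n_off - 2 * margin), np.nan)
        for j in range(margin, n_off - margin):
            win = arr[:, j - margin : j + margin + 1]
            with np.errstate(invalid="ignore"):
                smoothed[:, j - margin] = np.nanmean(win, axis=1)
        tables.append(smoothed)
    out = np.nanmean(np.stack(tables), axis=0)
    half = window // step
    offsets = (np.arange(-half + margin, half - margin + 1)) * step
    labels = [seg.state_label(s) for s in range(seg.n_states)]
    return pd.DataFrame(out, index=labels, columns=offsets)


# ---------------------------------------------------------------------------
# Per-base signal
# ---------------------------------------------------------------------------

def mean_signal_by_state(seg: Segmentation, positions: pd.DataFrame) -> np.ndarray:
    """Unweighted mean of per-base values (e.g. CpG methylation fractions)
    within each state; NaN-valued positions are treated as missing, as are
    states containing no measured position.

    ``positions``: DataFrame with columns chrom, pos, value.
    """
    total = np.zeros(seg.n_states)
    count = np.zeros(seg.n_states, dtype=np.int64)
    for chrom, grp in positions.groupby("chrom"):
        if chrom not in seg.chromsizes:
            continue
        states = seg.states(chrom)
        vals = grp["value"].to_numpy(dtype=float)
        pos = grp["pos"].to_numpy(dtype=np.int64)
        ok = np.isfinite(vals) & (pos >= 0) & (pos < seg.chromsizes[chrom])
        st = states[pos[ok] // seg.binsize]
        np.add.at(total, st, vals[ok])
        np.add.at(count, st, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = total / count
    out[count == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Emission-matrix structure across tissue groups
# ---------------------------------------------------------------------------

def emission_cv(
    params: HMMParams,
    metadata: pd.DataFrame,
    marks=DEFAULT_CV_MARKS,
    state_groups: dict | None = None,
) -> pd.DataFrame:
    """Coefficient of variation of per-tissue-group mean emissions.

    For each state and mark, datasets are averaged within each tissue group
    (groups with no dataset for the mark are excluded), and the CV
    (sample sd / mean) is taken across group means.  With ``state_groups``
    (name -> list of state indices) the per-state CVs are averaged within
    each state group.  NaN where the cross-group mean is zero.
    """
    S = params.n_states
    rows = np.zeros((S, len(marks)))
    for j, mark in enumerate(marks):
        sel = metadata["mark"] == mark
        groups = sorted(set(metadata.loc[sel, "group"]))
        if not groups:
            rows[:, j] = np.nan
            continue
        group_means = np.column_stack(
            [
                params.emissions[:, np.flatnonzero((sel & (metadata["group"] == g)).to_numpy())].mean(axis=1)
                for g in groups
            ]
        )
        mean = group_means.mean(axis=1)
        sd = group_means.std(axis=1, ddof=1) if len(groups) > 1 else np.zeros(S)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean
        cv[mean == 0] = np.nan
        rows[:, j] = cv
    per_state = pd.DataFrame(rows, columns=list(marks))
    if state_groups is None:
        return per_state
    out = {name: per_state.iloc[idx].mean(axis=0) for name, idx in state_groups.items()}
    return pd.DataFrame(out).T


def _mannwhitney_greater(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-sided (x stochastically greater) Mann-Whitney p-values, vectorized
    over the leading axis: exact U-distribution for samples of at most 20,
    tie-corrected normal approximation for larger ones."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    method = "exact" if max(x.shape[1], y.shape[1]) <= 20 else "asymptotic"
    return np.atleast_1d(
        sps.mannwhitneyu(x, y, alternative="greater", method=method, axis=-1).pvalue
    )


def differential_emission_tests(
    params: HMMParams,
    metadata: pd.DataFrame,
    marks=DEFAULT_TEST_MARKS,
    alpha: float = 0.05,
) -> TestResult:
    """Which (state, mark, tissue group) combinations show significantly
    elevated emissions in-group versus out-of-group.

    A test is constructed for every state and every (mark, group) pair with
    at least one in-group and one out-of-group dataset of that mark; the
    family size m is the number of constructed tests and the Bonferroni
    threshold is alpha / m.
    """
    groups = sorted(set(metadata["group"]))
    records = []
    for mark in marks:
        sel = (metadata["mark"] == mark).to_numpy()
        if not sel.any():
            continue
        for g in groups:
            in_cols = np.flatnonzero(sel & (metadata["group"] == g).to_numpy())
            out_cols = np.flatnonzero(sel & (metadata["group"] != g).to_numpy())
            if len(in_cols) == 0 or len(out_cols) == 0:
                continue
            pvals = _mannwhitney_greater(
                params.emissions[:, in_cols], params.emissions[:, out_cols]
            )
            for s in range(params.n_states):
                records.append((s, mark, g, len(in_cols), len(out_cols), float(pvals[s])))
    table = pd.DataFrame(
        records, columns=["state", "mark", "group", "n_in", "n_out", "p_value"]
    )
    m = len(table)
    table["significant"] = table["p_value"] < alpha / m
    return TestResult(table=table, alpha=alpha, n_tests=m)


# ---------------------------------------------------------------------------
# Greedy Naive-Bayes summary-dataset selection
# ---------------------------------------------------------------------------

def naive_bayes_states(
    params: HMMParams, observations: np.ndarray, features, state_priors: np.ndarray
) -> np.ndarray:
    """Most probable state per row under a Naive-Bayes model restricted to a
    feature subset, with empirical state priors."""
    features = list(features)
    log_scores = np.tile(np.log(state_priors), (observations.shape[0], 1))
    for d in features:
        o = observations[:, d]
        log_e = np.log(params.emissions[:, d])
        log_ne = np.log1p(-params.emissions[:, d])
        log_scores += np.where(o[:, None] == 1, log_e[None, :], log_ne[None, :])
    return np.argmax(log_scores, axis=1)


def greedy_summary_selection(
    params: HMMParams,
    observations: np.ndarray,
    assignments: np.ndarray,
    k: int = 80,
) -> tuple[list[int], list[float]]:
    """Greedily pick k features whose Naive-Bayes predictions best reproduce
    the full-model state assignments on a sampled set of bins.

    At each step the candidate feature maximizing agreement (fraction of bins
    where the restricted Naive-Bayes argmax equals the full-model assignment)
    is added; ties break toward the lower feature index.  Returns the ordered
    feature indices and the agreement after each addition.
    """
    D = params.n_features
    if k > D:
        raise ValueError(f"k={k} exceeds the number of features {D}")
    observations = np.asarray(observations)
    assignments = np.asarray(assignments)
    N = observations.shape[0]
    priors = np.bincount(assignments, minlength=params.n_states) / N
    priors = np.clip(priors, 1e-12, None)
    log_e = np.log(np.clip(params.emissions, 1e-12, 1.0))
    log_ne = np.log(np.clip(1.0 - params.emissions, 1e-12, 1.0))
    base = np.tile(np.log(priors), (N, 1))  # running log-score with selected features
    selected: list[int] = []
    agreements: list[float] = []
    remaining = list(range(D))
    for _ in range(k):
        best_f, best_acc = None, -1.0
        for f in remaining:
            o = observations[:, f]
            cand = base + np.where(o[:, None] == 1, log_e[None, :, f], log_ne[None, :, f])
            acc = float(np.mean(np.argmax(cand, axis=1) == assignments))
            if acc > best_acc:
                best_f, best_acc = f, acc
        o = observations[:, best_f]
        base += np.where(o[:, None] == 1, log_e[None, :, best_f], log_ne[None, :, best_f])
        selected.append(best_f)
        agreements.append(best_acc)
        remaining.remove(best_f)
    return selected, agreements
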