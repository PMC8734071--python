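# Methods

## Model

`stackstate` segments a genome into chromatin states with a hidden Markov
model whose observation at each 200-bp bin is a vector of binary
presence/absence calls, one per epigenomic dataset ("stacked" features: all
marks from all cell types enter one model). Conditional on the hidden state
`s`, calls are independent Bernoulli variables with per-dataset probabilities
`e[s, d]`; the state sequence is first-order Markov with transition matrix
`a` and initial distribution `π`. The free-parameter count used for AIC/BIC
is `k = S·D + S(S−1) + (S−1)`: one parameter per Bernoulli emission, and one
lost degree of freedom per transition row and for `π`. AIC = `2k − 2L` and
BIC = `k·ln n − 2L`, where `L` is the sampled log-likelihood of the final
training iteration and `n` the number of bins it was evaluated on.

Observations are organised as chunks of at most 1 Mb (5,000 bins). Chunks
are modeled as independent sequences, each starting from `π`; transitions
across chunk boundaries are not modeled. This matches the file-per-region
layout that makes training tractable at ~1000 features, at the cost of a
slight edge effect at chunk boundaries.

### Numerical stabilization of emission products

With D ≈ 1000 features the joint emission probability of a bin is a product
of up to 1000 factors and underflows double precision. The forward–backward
pass therefore works with *relative* emission products: starting from 1 for
every state, each feature's factor (`e[s,d]` or `1 − e[s,d]`; the missing
code 2 skips the feature) is multiplied in, and after every feature the
products across states are divided by their maximum. The discarded log
maxima are accumulated per position, so the per-chunk log-likelihood
returned from the scaled forward recursion is exact, not merely relative.
Tests verify agreement with an exhaustive path-sum oracle to 1e-8 and with a
log-space product oracle to 1e-10 down to emissions of 1e-6.

### Training

Baum–Welch with two departures from the textbook algorithm:

- **Pseudo-counts** (default 1) are added to every sufficient statistic in
  the M-step: `e = (present + c) / (present + absent + 2c)`, and analogously
  for transition rows and `π`. This keeps parameters strictly interior when
  subsampled iterations never visit a configuration.
- **Chunk subsampling**: each iteration draws `n_sampled_chunks` (default
  300) chunks uniformly without replacement (with replacement when fewer
  exist) and runs its E-step on that sample only. The recorded likelihood
  trace is evaluated on each iteration's own sample, so it is not monotone;
  convergence checking on it is disabled by default (`convergence_delta =
  −1`) and training runs `max_iterations` (default 200) iterations. In the
  no-sampling, zero-pseudo-count limit the implementation is classical EM
  and its likelihood trace is verified non-decreasing.

Initialization is seeded-random: emissions uniform on (1e-3, 1 − 1e-3),
transition rows and `π` from a flat Dirichlet. Because a single random start
can settle into a local optimum in which two generating states merge,
`train_best` implements a short-run/long-run strategy: 12 short runs of 15
iterations from different seeded starts, selection by total log-likelihood
over all chunks, then one long run continued from the winner. On the
recovery benchmark the good and bad basins separate within ~15 iterations,
so this is far more robust than one long run at equal cost. All training is
bitwise reproducible given the seed.

Decoding is max-posterior per bin (not Viterbi), with exact ties broken
toward the lower state index.

## Binarization

Reads are shifted 100 bases toward their 3′ end and the shifted 5′ positions
are counted per 200-bp bin. A bin is called present when
`P(X ≥ observed | X ~ Poisson(λ)) ≤ 1e-4`, with
`λ = max(control_count × depth_ratio, global mean signal per bin)` and
`depth_ratio` the total-signal to total-control ratio; without a control the
global mean is used everywhere. The raw per-bin control count is used
without windowed smoothing — the simplest defensible choice; with sparse
controls this makes per-bin rates noisy and the calls conservative, which
the read-simulation tests account for. Calls are monotone in the signal
count by construction. Descriptor tables are processed in batches of at most
10 datasets, and merged observation matrices always follow descriptor order
regardless of batch processing order.

## Enrichment statistics

Fold enrichment is `FE(x, s) = (#SX · #G)/(#S · #X)` counted at single-base
resolution, so annotations need not respect the bin grid; `#G` counts all
bases of chromosomes present in the segmentation (uniform genome-wide
background), and input annotation intervals are merged per label before
counting so overlapping inputs cannot inflate `#X`. Relative enrichment
(e.g. variant sets against a matched background) is the ratio of two such
enrichments, each against the whole genome. Positional enrichment records,
for each signed strand-oriented offset from a set of anchor bases, the
fraction of anchors whose offset bin carries a state, normalized by that
state's genome-wide bin fraction; anchors whose offset bin falls off the
chromosome are skipped for that offset only (anchor-wise skipping, chosen
over renormalizing by covered offsets). Sampled overlap probabilities against
per-sample external segmentations draw 100 assigned bins per state, tally
external-state frequencies per sample, and average over 21 resamplings and
then over samples within a group; states with fewer assigned bins than the
sample size are sampled with replacement, and unassigned states are reported
missing.

## ROC evaluation

Bins are split 50/50 into train and test by seeded coin flips. Per-state
fold enrichment for the target is computed on training bins only (base
resolution); states are ranked by decreasing enrichment, ties toward the
lower index. Test bins are predicted positive prefix-by-prefix along the
ranking; a test bin is positive when it overlaps the target by at least one
base (any-overlap labeling; the natural alternatives — majority overlap or
base counting on the test side — change little on grid-aligned targets, and
bins were chosen to match the split unit). AUROC is the trapezoidal area of
the resulting step curve and matches a reference rank-based ROC
implementation exactly on the induced bin scores.

## State characterization

- **Expression by state**: bp-normalized average
  `Σ_{i∈B_s} Σ_{g∈G_i} E_g/L_g / Σ_{i∈B_s} Σ_{g∈G_i} 1/L_g` with any-overlap
  gene-bin assignment and `E = log(RPKM + 1)` expression; also per-state
  mean and coefficient of variation across samples.
- **TSS-centered positional expression**: offsets −25 kb…+25 kb in 200-bp
  steps (251 columns), strand-oriented, offset 0 being the bin containing
  the outer TSS (5′-most start on the gene's strand); per (state, offset)
  the mean expression over contributing genes, smoothed along offsets with a
  centered width-21 moving average whose first and last 10 offsets are
  dropped (231 retained), then averaged over samples.
- **Per-base signals** (e.g. CpG methylation fractions): unweighted mean of
  non-missing values over positions in each state.
- **Emission CV**: for six promoter/enhancer-associated marks, emissions are
  averaged per (mark, tissue-group) cell over the datasets present, the
  coefficient of variation (sample sd, n−1 denominator) is taken across
  group means, and per-state CVs may be averaged within state groups.
- **Differential-emission tests**: for every state and every (mark, group)
  pair with at least one in-group and one out-of-group dataset, a one-sided
  Mann–Whitney test of "in-group emissions greater", exact U-distribution
  for samples of ≤ 20, tie-corrected normal approximation above; the family
  is Bonferroni-corrected at `α / m` with `m` the number of constructed
  tests. On the reference panel layout (8 marks × 19 groups × 100 states
  with three sparsely profiled marks) the family has 14,200 tests and a
  0.05-level threshold of 3.5e-6.
- **Greedy summary selection**: features are added one at a time to maximize
  agreement between the full-model bin assignments and the argmax of a
  Naive-Bayes classifier restricted to the selected features, with empirical
  state frequencies as priors, evaluated on a fixed sampled set of bins;
  ties break toward the lower feature index. The agreement metric and priors
  are this package's reconstruction of the procedure's published outline.

## Synthetic data

The generators emulate the structure of the real inputs — per-bin Bernoulli
calls from a known HMM, Poisson read sets whose binarization recovers a
known truth track, annotation sets with closed-form expected enrichments,
and expression tables with chosen per-state effects — at desk scale. The
default scenario is 2 chromosomes × 1 Mb, 10 features, 5 well-separated
states (on-probability 0.9, off 0.1, stay 0.95); benchmarks that need more
data use the same generator at 50k–200k bins. These fixtures establish
correctness of the machinery, not realism: they contain no read-mappability
or GC structure, no correlated features within a cell type, no replicate
structure, and far fewer features than a real compendium, so passing tests
demonstrate algorithmic fidelity rather than biological performance.

## Numerical and design choices

- Double precision throughout; posterior rows renormalized after the
  stabilized recursion; forward scaling constants checked finite, with the
  failing position reported.
- Exact posterior ties in decoding and enrichment-ranking ties both resolve
  to the lower index for determinism.
- Coordinates are 0-based half-open everywhere; bins are `[200i, 200(i+1))`
  and the final bin of each chromosome is kept truncated (base-accurate
  coverage weighting).
- The binarized-file dialect (two header lines: sample TAB chunk tag, then
  feature names) and the `chrN.k` chunk tags mirror the upstream ecosystem's
  layout as a compatibility assumption; the missing code 2 is tolerated
  everywhere even though the stacked workflow emits none.
- Reads on chromosomes absent from the size table are dropped with a logged
  count rather than an error, since real tagAlign files carry unplaced
  contigs.
- Problem sizes used by the test suite and the acceptance script (50k-bin EM
  monotonicity, 200k-bin recovery, 100 enumeration instances at T ≤ 8) were
  chosen so the whole suite completes in a few minutes on one CPU while
  still exercising the asymptotic regime of each check.

## Known limitations

- Cross-chunk transitions are not modeled; state runs spanning a 1-Mb
  boundary are decoded from the initial distribution on the far side.
- The AIC/BIC parameter count and the evaluation unit (bins of the sampled
  subset) are documented conventions; other tools may count differently, so
  criteria values are comparable within this package, not across tools.
- Binarization uses unsmoothed per-bin control rates; sparse controls make
  calls conservative.
- The greedy summary-selection objective is a reconstruction (see above).
- No multithreaded training: reproducibility is guaranteed for the
  single-threaded path only.
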