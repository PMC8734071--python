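"""Relate states to gene expression and test tissue-group specificity of the
emission parameters.

Run:  python examples/04_expression_and_tests.py
"""

import numpy as np

from stackstate import (
    HMMParams,
    default_config,
    make_toy_expression,
    make_toy_genes,
    simulate_genome,
)
from stackstate.characterization import (
    DatasetMetadata,
    differential_emission_tests,
    expression_summary,
)

config = default_config(seed=21)
seg, _ = simulate_genome(config)

# toy genes whose expression rises with their majority state index
genes = make_toy_genes(config.chromsizes, n_genes=300, gene_length=1_000, seed=21)
expr = make_toy_expression(
    genes, seg, state_effects=[0.5, 1.0, 2.0, 3.0, 4.0], noise_sd=0.2, n_samples=4, seed=21
)
summary = expression_summary(seg, genes, expr)
print("bp-normalized average expression per state (mean over 4 samples):")
print(summary.round(3).to_string())
print("the mean column recovers the simulated effect ordering; cv is the "
      "coefficient of variation of the per-sample state averages.\n")

# differential-emission tests: does one tissue group emit a mark more highly?
rng = np.random.default_rng(21)
meta = DatasetMetadata(
    eids=[f"E{i:03d}" for i in range(40)],
    marks=["H3K4me1"] * 40,
    groups=["Brain"] * 10 + ["Blood"] * 10 + ["ESC"] * 10 + ["Muscle"] * 10,
)
emissions = rng.uniform(0.1, 0.4, size=(5, 40))
emissions[2, :10] += 0.5  # state 3 is Brain-specific for this mark
params = HMMParams(
    emissions=np.clip(emissions, 0, 1),
    transitions=np.full((5, 5), 0.2),
    initial=np.full(5, 0.2),
)
result = differential_emission_tests(params, meta, marks=("H3K4me1",))
hits = result.table[result.table["significant"]]
print(f"{result.n_tests} one-sided Mann-Whitney tests; "
      f"Bonferroni threshold {result.threshold:.2e}")
print(hits[["state", "mark", "group", "p_value"]].to_string(index=False))
print("only the constructed Brain-specific state clears the corrected threshold.")
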