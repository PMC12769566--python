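"""Classify homoeolog pairs by expression dominance per tissue.

A 2000-pair fully retained panel is simulated with 10% A-dominant, 80%
balanced and 10% B-dominant pairs across 10 tissues x 3 replicates; the
classifier recovers the per-tissue proportions and the stable/dynamic split.
"""

import tetralog as tl

config = tl.SimConfig(seed=11, n_chromosomes_per_subgenome=2,
                      genes_per_chromosome=1000, retention_rates=(1, 0, 0),
                      dominance_proportions=(0.10, 0.80, 0.10))
_, _, truth = tl.gen_genome(config)
tpm, samples = tl.gen_expression(truth, config)

calls, stability = tl.dominance_calls(tpm, samples, truth.pairs())
summary = tl.dominance_summary(calls, stability)
print(summary.round(1).to_string(index=False))
print(f"\nstable pairs: {summary.attrs['stable_pct']:.1f}%  "
      f"dynamic: {summary.attrs['dynamic_pct']:.1f}%")
excluded = (calls["category"] == "excluded").mean()
print(f"tissue calls excluded by the replicate-outlier rule: {excluded:.1%}")
# Percentages per tissue sum to 100 over assessable pairs; the recovered
# proportions track the planted 10/80/10 within binomial sampling error.
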