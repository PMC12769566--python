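"""Assembly summary, telomere scan and the small published-resource formulas.

Uses the published JK-8 per-chromosome lengths for the anchoring arithmetic
and a simulated genome for the telomere scan.
"""

import tetralog as tl
from tetralog import datasets

summary = tl.assembly_summary(datasets.CHROMOSOME_LENGTHS_BP,
                              datasets.ANCHORED_SEQUENCE_IDS)
print(f"sequences: {summary.n_sequences}  total: {summary.total_bp:,} bp")
print(f"N50: {summary.n50_bp:,} bp  N90: {summary.n90_bp:,} bp")
print(f"anchored: {summary.anchored_bp:,} bp "
      f"({summary.anchored_fraction_pct}% of the recomputed total)")
delta = datasets.REPORTED_TOTAL_ASSEMBLY_BP - summary.total_bp
print(f"published total exceeds the recomputed sum by {delta} bp")

print(f"\nSNP density: "
      f"{tl.marker_density(datasets.HIGH_QUALITY_SNPS, datasets.ASSEMBLY_SIZE_MB)}"
      f" per Mb")
print(f"TF fraction: {tl.proportion(datasets.TF_GENES, datasets.ANNOTATED_GENES)}%")
print(f"mineral concentration example (R=10 mg/L, V=25 mL, DF=1, S=0.5 g): "
      f"{tl.mineral_concentration(10, 25, 1, 0.5):.0f} mg/kg")

sequences, _, _ = tl.gen_genome(tl.SimConfig(seed=3, telomere_motif_copies=50))
print("\ntelomere scan of a simulated genome (50 motif copies planted per end):")
for rep in tl.telomere_scan(sequences, min_copies=10):
    print(f"  {rep.chromosome}: 5' {rep.copies_5prime} copies, "
          f"3' {rep.copies_3prime} copies -> {rep.classification}")
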