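# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Coordinates and formats

Internally all intervals are 0-based half-open. GFF3 is emitted 1-based
inclusive, BED 0-based half-open; the LSV report table is 1-based inclusive.
Homology hits use the 12-column tabular dialect (qseqid … bitscore). All
tabular I/O goes through pandas, FASTA through Biopython.

## Synteny and fractionation

**Hit filter.** A hit is kept iff E-value ≤ `evalue_max` (default 1e-20) and
bitscore ≥ (1 − `drop_fraction`) × the best bitscore among that query's hits
*passing the E-value cut* (default drop 0.4, boundary inclusive so the best
hit always survives). Computing the per-query maximum after the E-value cut
is the stricter and more internally consistent reading; both thresholds are
exposed. Duplicate (query, subject) rows collapse to the max-bitscore row.
The filter is idempotent.

**Chaining.** Collinear chains are found per (anchor chromosome, subgenome
chromosome) with a standard sparse dynamic programme over gene order
indices: chain score = Σ match scores − `gap_penalty` × Σ skipped gene
positions on both axes, anchor order strictly increasing, target order
strictly increasing (parallel) or decreasing (antiparallel), per-step gaps
capped at `max_gap_genes` (default 25). Secondary chains come from greedy
peel-off (report best, remove its anchors, repeat) down to `min_pairs`
(default 6). The DP is verified against exhaustive enumeration on small
instances. Match score defaults to the hit bitscore.

`gap_penalty` defaults to 0.1 × the mean match score per skipped position.
With bitscore-scale match scores a heavier penalty (e.g. 0.5×) makes the
optimal chain break at runs of two or more fractionated genes, shedding tail
fragments shorter than `min_pairs`; 0.1× bridges gaps up to roughly nine
skipped positions — consistent with collinearity tools whose gap penalties
are small relative to match scores — while still discouraging diffuse
chains. The parameter is exposed everywhere.

**Assignment and classes.** Each anchor keeps only its pair from the highest
scoring chain (ties: longer chain, then lexicographic chain key —
deterministic). One row per anchor: both homoeologs present → fully
retained; exactly one → partially fractionated; none → fully fractionated.
The three classes always partition the anchor set. Subgenome membership
comes from the chromosome-name suffix (…A/…B) unless an explicit map is
given.

## Expression dominance

RE_B = TPM(B)/(TPM(A)+TPM(B)) per replicate; RE_A + RE_B = 1 wherever
defined. Pairs with combined TPM < 1 (strict) in *any* sample are excluded
globally before any tissue-level computation. Within a tissue the replicate
RE_B values are screened with a two-sided Grubbs test at α = 0.05 (critical
value from the t distribution); any significant replicate excludes the pair
*for that tissue only* — other tissues still count, and the pair still gets
a stability label over its remaining tissues. For n > 25 replicates the
Grubbs rule is numerically a Bonferroni z-score rule and the implementation
falls back to it; a plain z-score method is also selectable. Grubbs was
chosen because the replicate groups are tiny (typically 3) and the screen
targets a single discordant replicate; the exact test is configurable since
different studies use different outlier screens.

Categories use closed boundaries at the dominant ends: RE_B ≤ 0.2
A-dominant, ≥ 0.8 B-dominant, otherwise balanced. A pair is *stable* when
all non-excluded tissue categories agree (vacuously stable with a single
assessable tissue), *dynamic* otherwise; pairs with no assessable tissue get
no label. Swapping every pair's A/B assignment maps RE_B → 1 − RE_B and
mirrors A-dominant ↔ B-dominant calls exactly.

## LSV detection

Counts → per-accession TPM (per-kilobase rate scaled to 1e6; an all-zero
accession column is an error naming the accession) → per-gene ratio against
the reference accession. Genes with reference TPM < `ref_floor` (default
0.1) are masked and never enter a window. Smoothing slides a `window` of 20
unmasked gene slots by `step` 5; the trailing incomplete window is dropped
(constant-variance means), and window bounds run from its first gene's start
to its last gene's end.

Calls: runs of ≥ `min_consecutive` (2) windows with mean ≤ `del_threshold`
(0.35) or ≥ `dup_threshold` (1.65), merged into one event from first to last
contributing gene, kept only when the span exceeds `min_span_bp` (40 000).
The thresholds are this package's own defaults, placed symmetrically between
the homozygous copy-ratio expectations (deletion 0, duplication 2) and the
heterozygous levels (0.5 / 1.5): they call homozygous events robustly and
deliberately do not call heterozygous ones, whose expected ratios sit inside
the pass band; lowering the margins to catch heterozygous events raises the
false-call rate sharply at realistic dispersion. All four parameters are
exposed in the API and CLI. Events at *identical* first/last gene indices
across accessions merge into one call with a carrier list; the reference
accession is never called. Calls are invariant to rescaling any single
accession's counts (TPM invariance).

Proximity classes for SV intervals: genic on ≥ 1 bp overlap with a gene
body, else by distance to the nearest gene (≤ 1 kb, ≤ 3 kb, intergenic),
checked in that order.

Phenotype linkage: per trait × dataset, Tukey fences Q1 − k·IQR / Q3 + k·IQR
(k = 1.5) with linear-interpolation quartiles computed over **all**
accessions of the dataset, not only carriers; a carrier is reported when its
value lies strictly outside the fences. Traits with fewer than four
non-missing values are skipped with a warning.

## Ks clock

Ks values ≤ 0.001 are dropped (strict) before the log transform — they are
dominated by estimation artifacts at near-identical sequences. A Gaussian
mixture is fitted to ln(Ks) by EM (scikit-learn, 5 seeded restarts per
order), the order k ∈ 1..4 chosen by BIC; input is sorted first so the fit
is order-invariant and deterministic under a fixed seed. The peak is
exp(mean) of the highest-weight component by default (lowest-mean rule
available, for mixtures where an old large-Ks component dominates by
weight).

Clock arithmetic: λ = Ks_cal / (2 T_cal) evaluated at both calibration
bounds; T = Kŝ / (2λ), equivalently Kŝ·T_cal/Ks_cal — linear in the peak and
an exact round trip at Kŝ = Ks_cal. With the rice / broomcorn millet
calibration (Ks = 0.57038, 41.4–51.8 My) a peak of 0.048 yields 3.48–4.36
My. Published little millet work prints a 3.39–4.25 My window alongside a
peak of "≈ 0.048"; those two printed numbers are mutually inconsistent under
this formula (3.39–4.25 corresponds to a peak near 0.0467). The formula, not
any printed interval, is what this module reproduces.

## Resource statistics

N50 (N90): length of the smallest sequence in the minimal descending-sorted
prefix reaching ≥ 50% (90%) of the total; verified against a brute-force
cumulative-sum oracle. Telomere scan: count the 7-bp motif AAACCCT and its
reverse complement in each terminal window (default 100 kb; halved with a
warning for short sequences) — the motif cannot overlap itself, so naive
counting equals non-overlapping scanning — and classify an end as telomeric
at ≥ `min_copies` (default 10) on either strand; classification is
strand-symmetric. Proportions and marker densities round half-even to the
requested decimals. The bundled published JK-8 per-chromosome lengths sum to
850,463,339 bp, 300 bp less than the published total 850,463,639; the
summary reports the recomputed sum and the discrepancy is surfaced rather
than silently matched (the anchored fraction is 97.7% either way).
Concentration: C = R·V·DF/S (mg/kg), rejecting non-positive sample mass.

## Synthetic data

The generator's defaults are the study conditions the pipeline is validated
under. Layout: `n_chromosomes_per_subgenome` anchor chromosomes ×
`genes_per_chromosome` genes, mirrored onto ChrNA/ChrNB; retention rates
default to (0.632, 0.092, 0.276), the class frequencies observed across the
little millet anchor set. Gene lengths are log-normal (mean 2 kb), intergenic
gaps exponential (mean 1.5 kb), telomere motifs planted at both ends
(forward 5′, reverse complement 3′). Homology: one high-bitscore hit per
retained copy, with both copies of a query sharing a base score (real
homoeolog alignments score comparably, keeping true hits above the drop
floor), plus 10% decoys that share a query with a true hit at 0.2–0.55× its
best score — half also failing the E-value cut — so both filter rules are
exercised.

Expression is built pair-total-first: a log-normal total per pair × tissue is
split by a planted RE_B drawn inside the target category's band (A-dominant
0.03–0.18, balanced 0.30–0.70, B-dominant 0.82–0.97), then multiplied by
per-gene log-normal replicate noise (sdlog 0.15). Dominance proportions
default to (0.10, 0.80, 0.10) over 10 tissues × 3 replicates. A "dynamic"
pair has one tissue's label redrawn from the *same* proportions — keeping
every tissue's marginal exactly at the planted triple — with the redraw rate
scaled by 1/(1 − Σp²) so the expected realised dynamic fraction equals
`dynamic_fraction` (default 0.21). A small fraction of pairs (2%) is forced
under the combined-TPM floor in one sample.

Coverage counts are negative binomial (dispersion 0.1 by default, 0 =
Poisson) with mean ∝ base depth × gene length × copy ratio; planted LSVs set
carrier copy ratios (hom DEL 0, het DEL 0.5, het DUP 1.5, hom DUP 2) and the
reference accession is pinned at 1. Phenotypes are normal per trait with
planted extreme values for chosen carriers; Ks values come from a log-normal
mixture (default one component at ln 0.048, sdlog 0.4) with optional ≤ 0.001
injections.

Determinism: each generator draws from a child stream spawned from the one
config seed at a fixed index, so outputs are byte-identical for identical
configs regardless of call order, and no global random state is touched.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (mappability, GC bias,
multi-mapping over repeats), tandem duplicates and translocated homoeologs,
correlated expression across tissues, heterozygous-carrier mosaicism,
population structure among accessions, and Ks estimation noise from
alignment/codon-model error. Recovery statements hold under the stated noise
models only.

## Problem sizes

Validation runs use desk-scale panels chosen to make the statistical
tolerances meaningful: 2000 retained pairs × 10 tissues × 3 replicates for
dominance recovery (3-binomial-SD bands against generator truth), 50
accessions × 1000 genes with five planted homozygous LSVs of 25–60 genes for
recall/false-call bounds, 1500–3000 anchors for retention recovery, n = 5000
per Ks fit over 20 seeds, and 200 random ≤ 12-anchor instances for the
chaining oracle. Full-study scales (tens of thousands of anchors, 300
accessions) run with the same code paths and scale linearly in genes ×
accessions.

## Known limitations

- Detection thresholds are tuned for homozygous events; heterozygous LSVs
  require narrower margins and correspondingly cleaner coverage.
- Carrier merging requires *identical* gene coordinates; noise at event
  edges can split near-identical events across accessions into separate
  calls (visible as duplicated spans with single carriers).
- The chain DP assumes unique order indices per gene; tandem arrays collapse
  to their representative order position.
- Mixture order selection by BIC can under-split heavily overlapping Ks
  components; the peak rule is configurable but no automatic
  component-identity check is attempted.
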