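"""Published summary figures for the little millet (Panicum sumatrense)
cv. JK-8 chromosome-scale assembly and its 300-accession diversity panel.

These constants are inputs to the resource-statistics helpers; nothing in
the pipeline depends on them otherwise.
"""

# Per-chromosome lengths (bp) of the JK-8 v2 assembly; "UA" is the pool of
# unanchored scaffolds.
CHROMOSOME_LENGTHS_BP: dict[str, int] = {
    "Chr1A": 43_243_116,
    "Chr1B": 43_137_277,
    "Chr2A": 53_162_992,
    "Chr2B": 53_115_015,
    "Chr3A": 61_397_489,
    "Chr3B": 50_789_506,
    "Chr4A": 36_975_915,
    "Chr4B": 35_829_819,
    "Chr5A": 47_000_000,
    "Chr5B": 50_323_433,
    "Chr6A": 41_209_881,
    "Chr6B": 37_846_408,
    "Chr7A": 39_612_390,
    "Chr7B": 37_794_386,
    "Chr8A": 41_957_870,
    "Chr8B": 40_861_194,
    "Chr9A": 58_551_545,
    "Chr9B": 57_786_484,
    "UA": 19_868_619,
}

ANCHORED_SEQUENCE_IDS: tuple[str, ...] = tuple(
    name for name in CHROMOSOME_LENGTHS_BP if name != "UA"
)

# The published total differs from the sum of the published per-sequence
# lengths by 300 bp; assembly_summary() recomputes from the lengths and the
# discrepancy is surfaced rather than silently matched.
REPORTED_TOTAL_ASSEMBLY_BP = 850_463_639

ASSEMBLY_SIZE_MB = 850.6          # contig-level assembly span
HIFI_YIELD_GB = 70.1              # PacBio HiFi raw yield

ANNOTATED_GENES = 59_045
TF_GENES = 3_503
SYNTENIC_GENES = 41_070           # syntelogs of broomcorn millet anchors

# Homoeolog retention classes over broomcorn millet anchor genes
FULLY_RETAINED_PAIRS = 19_147
PARTIALLY_FRACTIONATED = 2_776
FULLY_FRACTIONATED = 8_367

HIGH_QUALITY_SNPS = 249_511

# Rice / broomcorn millet molecular-clock calibration
CALIBRATION_KS = 0.57038
CALIBRATION_T_MIN_MY = 41.4
CALIBRATION_T_MAX_MY = 51.8
SUBGENOME_KS_PEAK = 0.048         # A/B homoeolog Ks mode

TISSUES: tuple[str, ...] = ("GS", "RD", "PU", "YL", "YR", "CM", "VS", "PE", "PM", "PL")

TELOMERE_MOTIF = "AAACCCT"
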