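"""Small, exactly testable resource statistics: assembly summaries (N50/N90,
anchored fraction), telomere-motif scanning at chromosome ends, marker
density, rounded proportions and the ICP-OES mineral-concentration formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import TELOMERE_MOTIF

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AssemblySummary:
    n_sequences: int
    total_bp: int
    n50_bp: int
    n90_bp: int
    anchored_bp: int
    anchored_fraction_pct: float


def _nx(sorted_desc: np.ndarray, total: int, fraction: float) -> int:
    cumulative = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cumulative, fraction * total))
    return int(sorted_desc[idx])


def assembly_summary(lengths: dict[str, int], anchored_ids=()) -> AssemblySummary:
    """Summarise an assembly from per-sequence lengths.

    N50 is the length of the smallest sequence in the minimal prefix of the
    descending-sorted lengths whose cumulative sum reaches at least half the
    total (N90 analogous at 90%). The anchored fraction is the share of total
    bases in the sequences named by ``anchored_ids``.
    """
    if not lengths:
        raise ValueError("no sequence lengths given")
    values = np.asarray(list(lengths.values()), dtype=np.int64)
    if (values <= 0).any():
        raise ValueError("sequence lengths must be positive")
    total = int(values.sum())
    desc = np.sort(values)[::-1]
    anchored = int(sum(lengths[name] for name in anchored_ids))
    return AssemblySummary(
        n_sequences=len(values),
        total_bp=total,
        n50_bp=_nx(desc, total, 0.5),
        n90_bp=_nx(desc, total, 0.9),
        anchored_bp=anchored,
        anchored_fraction_pct=proportion(anchored, total, decimals=1),
    )


@dataclass(frozen=True)
class TelomereReport:
    chromosome: str
    copies_5prime: int
    copies_3prime: int
    classification: str  # both_ends | one_end | none


def _motif_copies(window: str, motif: str) -> int:
    # AAACCCT cannot overlap itself, so non-overlapping count == naive count
    return max(window.upper().count(motif), window.upper().count(reverse_complement(motif)))


def telomere_scan(
    sequences: dict[str, str],
    motif: str = TELOMERE_MOTIF,
    terminal_window: int = 100_000,
    min_copies: int = 10,
) -> list[TelomereReport]:
    """Count telomere-motif copies (either strand) in each chromosome's
    terminal windows and classify ends as telomeric when the copy count
    reaches ``min_copies``."""
    reports = []
    for name, seq in sequences.items():
        window = terminal_window
        if len(seq) < 2 * terminal_window:
            window = len(seq) // 2
            warnings.warn(
                f"{name} shorter than twice the terminal window; "
                f"using {window} bp per end",
                stacklevel=2,
            )
        five = _motif_copies(seq[:window], motif)
        three = _motif_copies(seq[-window:] if window else "", motif)
        telomeric_ends = (five >= min_copies) + (three >= min_copies)
        classification = {0: "none", 1: "one_end", 2: "both_ends"}[telomeric_ends]
        reports.append(TelomereReport(name, five, three, classification))
    return reports


def marker_density(n_markers: int, genome_size_mb: float, decimals: int = 1) -> float:
    """Markers per megabase, rounded half-even."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return float(np.round(n_markers / genome_size_mb, decimals))


def proportion(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage 100*n/d, rounded half-even to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return float(np.round(100.0 * numerator / denominator, decimals))


def mineral_concentration(reading_mg_per_l: float, volume_ml: float,
                          dilution_factor: float, sample_mass_g: float) -> float:
    """Element concentration in mg/kg from an ICP-OES reading:
    C = R x V x DF / S."""
    if sample_mass_g <= 0:
        raise ValueError("sample mass must be positive")
    return reading_mg_per_l * volume_ml * dilution_factor / sample_mass_g
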