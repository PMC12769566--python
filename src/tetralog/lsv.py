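"""Read-depth large structural variant (LSV) screening over a gene-level
coverage matrix.

Per-gene counts are TPM-normalised per accession, divided by the reference
accession's TPM to give gene-ordered coverage-ratio tracks, smoothed with a
sliding window (gene units), and runs of extreme windows are merged into
deletion/duplication calls with a minimum genomic span. Calls at identical
gene coordinates across accessions are merged with a carrier list. Planted
or published phenotype tables can then be screened for Tukey-fence outliers
among LSV carriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-accession TPM: counts are converted to per-kilobase rates and each
    column scaled to sum to 1e6."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero coverage column(s): {list(zero.index)}")
    return rate.div(totals, axis=1) * 1e6


@dataclass
class RatioTrack:
    accession: str
    chromosome: str
    gene_ids: np.ndarray          # gene order along the chromosome
    order_index: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    ratio: np.ndarray             # NaN where the gene is masked
    masked: np.ndarray            # True where reference TPM < floor


def coverage_ratio(tpm: pd.DataFrame, genes: pd.DataFrame, reference: str,
                   ref_floor: float = 0.1) -> list[RatioTrack]:
    """Per accession x chromosome ratio tracks, sample TPM over reference TPM.

    Genes whose reference TPM is below ``ref_floor`` are masked (NaN) and
    skipped by smoothing rather than producing unstable or infinite ratios.
    """
    if reference not in tpm.columns:
        raise KeyError(f"reference accession {reference!r} not in matrix")
    genes = genes.set_index("gene_id").reindex(tpm.index)
    ref = tpm[reference].to_numpy(dtype=float)
    masked_all = ref < ref_floor
    tracks = []
    for chrom, grp in genes.groupby("chromosome", sort=True):
        grp = grp.sort_values("order_index")
        pos = [tpm.index.get_loc(g) for g in grp.index]
        pos = np.asarray(pos, dtype=int)
        mask = masked_all[pos]
        for accession in tpm.columns:
            values = tpm[accession].to_numpy(dtype=float)[pos]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(mask, np.nan, values / np.where(mask, np.nan, ref[pos]))
            tracks.append(RatioTrack(
                accession=accession, chromosome=chrom,
                gene_ids=grp.index.to_numpy(),
                order_index=grp["order_index"].to_numpy(dtype=int),
                starts=grp["start"].to_numpy(dtype=int),
                ends=grp["end"].to_numpy(dtype=int),
                ratio=ratio, masked=mask))
    return tracks


@dataclass
class WindowTrack:
    accession: str
    chromosome: str
    window: int
    step: int
    first_gene_order: np.ndarray
    last_gene_order: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray
    mean_ratio: np.ndarray

    def __len__(self):
        return len(self.mean_ratio)


def smooth(track: RatioTrack, window: int = 20, step: int = 5) -> WindowTrack:
    """Sliding-window means over the unmasked genes of one track.

    Windows hold exactly ``window`` unmasked gene slots and advance by
    ``step`` slots; a trailing incomplete window is dropped. Window genomic
    bounds run from the start of its first gene to the end of its last.
    """
    keep = ~track.masked
    ratio = track.ratio[keep]
    orders = track.order_index[keep]
    starts = track.starts[keep]
    ends = track.ends[keep]
    n = len(ratio)
    if n < window:
        warnings.warn(
            f"{track.accession}/{track.chromosome}: only {n} unmasked genes "
            f"for window {window}; empty track", stacklevel=2)
        empty = np.empty(0)
        return WindowTrack(track.accession, track.chromosome, window, step,
                           empty.astype(int), empty.astype(int),
                           empty.astype(int), empty.astype(int), empty)
    first = np.arange(0, n - window + 1, step)
    cum = np.concatenate([[0.0], np.cumsum(ratio)])
    means = (cum[first + window] - cum[first]) / window
    return WindowTrack(
        accession=track.accession, chromosome=track.chromosome,
        window=window, step=step,
        first_gene_order=orders[first], last_gene_order=orders[first + window - 1],
        start_bp=starts[first], end_bp=ends[first + window - 1],
        mean_ratio=means)


@dataclass
class LSVCall:
    chromosome: str
    kind: str                     # DEL | DUP
    first_gene_order: int
    last_gene_order: int
    start_bp: int                 # 0-based half-open internally
    end_bp: int
    span_bp: int
    n_genes: int
    mean_ratio: float
    carriers: list[str] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def call_lsvs(windows: list[WindowTrack], reference: str,
              del_threshold: float = 0.35, dup_threshold: float = 1.65,
              min_consecutive: int = 2, min_span_bp: int = 40_000) -> list[LSVCall]:
    """Merge runs of extreme smoothed windows into LSV calls.

    A run of at least ``min_consecutive`` consecutive windows with mean ratio
    <= ``del_threshold`` (or >= ``dup_threshold``) becomes one event spanning
    from the first to the last contributing gene; events whose genomic span is
    not greater than ``min_span_bp`` are discarded. Events at identical gene
    coordinates across accessions are merged, accumulating carriers. The
    reference accession is never called.
    """
    if del_threshold >= dup_threshold:
        raise ValueError("deletion threshold must be below duplication threshold")
    merged: dict[tuple, LSVCall] = {}
    for wt in windows:
        if wt.accession == reference or len(wt) == 0:
            continue
        for kind, hit in (("DEL", wt.mean_ratio <= del_threshold),
                          ("DUP", wt.mean_ratio >= dup_threshold)):
            for run_start, run_end in _runs(hit, min_consecutive):
                first_order = int(wt.first_gene_order[run_start])
                last_order = int(wt.last_gene_order[run_end - 1])
                start = int(wt.start_bp[run_start])
                end = int(wt.end_bp[run_end - 1])
                span = end - start
                if span <= min_span_bp:
                    continue
                key = (wt.chromosome, kind, first_order, last_order)
                if key not in merged:
                    merged[key] = LSVCall(
                        chromosome=wt.chromosome, kind=kind,
                        first_gene_order=first_order, last_gene_order=last_order,
                        start_bp=start, end_bp=end, span_bp=span,
                        n_genes=last_order - first_order + 1,
                        mean_ratio=float(wt.mean_ratio[run_start:run_end].mean()))
                merged[key].carriers.append(wt.accession)
    return sorted(merged.values(),
                  key=lambda c: (c.chromosome, c.start_bp, c.kind))


def _runs(hit: np.ndarray, min_len: int):
    """Maximal runs of True of length >= min_len, as (start, end) slices."""
    runs = []
    i, n = 0, len(hit)
    while i < n:
        if hit[i]:
            j = i
            while j < n and hit[j]:
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def lsv_table(calls: list[LSVCall]) -> pd.DataFrame:
    """Report table with 1-based inclusive genomic coordinates."""
    rows = [{
        "chromosome": c.chromosome, "type": c.kind,
        "start": c.start_bp + 1, "end": c.end_bp,
        "span_bp": c.span_bp, "n_genes": c.n_genes,
        "first_gene_order": c.first_gene_order, "last_gene_order": c.last_gene_order,
        "mean_ratio": round(c.mean_ratio, 4),
        "n_carriers": c.n_carriers, "carriers": ",".join(c.carriers),
    } for c in calls]
    return pd.DataFrame(rows, columns=[
        "chromosome", "type", "start", "end", "span_bp", "n_genes",
        "first_gene_order", "last_gene_order", "mean_ratio",
        "n_carriers", "carriers"])


PROXIMITY_CLASSES = ("genic", "within_1kb", "within_3kb", "intergenic")


def annotate_proximity(sv_intervals: pd.DataFrame, genes: pd.DataFrame,
                       near_bp: int = 1000, far_bp: int = 3000) -> pd.Series:
    """Classify each SV interval (0-based half-open, columns chromosome/
    start/end) against gene bodies: ``genic`` on >= 1 bp overlap, otherwise by
    distance to the nearest gene (<= 1 kb, <= 3 kb, intergenic)."""
    classes = []
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chromosome")}
    for row in sv_intervals.itertuples(index=False):
        grp = by_chrom.get(row.chromosome)
        if grp is None:
            classes.append("intergenic")
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = (starts < row.end) & (ends > row.start)
        if overlap.any():
            classes.append("genic")
            continue
        gap = np.minimum(np.abs(starts - row.end), np.abs(row.start - ends)).min()
        if gap <= near_bp:
            classes.append("within_1kb")
        elif gap <= far_bp:
            classes.append("within_3kb")
        else:
            classes.append("intergenic")
    return pd.Series(classes, index=sv_intervals.index, name="proximity")


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """(lower, upper) Tukey fences with linear-interpolation quartiles."""
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def iqr_outliers(phenotypes: pd.DataFrame, carriers: dict[str, list[str]] | None = None,
                 k: float = 1.5, min_values: int = 4) -> pd.DataFrame:
    """Tukey-fence outlier report per trait x dataset.

    ``phenotypes``: columns accession, dataset, then one column per trait.
    Quartiles use all accessions in the dataset; only accessions listed in
    ``carriers`` (mapping accession -> LSV descriptions; None = screen all)
    are reported when their value falls strictly outside the fences.
    """
    trait_cols = [c for c in phenotypes.columns if c not in ("accession", "dataset")]
    rows = []
    for (dataset, trait), grp in (
            phenotypes.melt(id_vars=["accession", "dataset"], value_vars=trait_cols,
                            var_name="trait", value_name="value")
            .groupby(["dataset", "trait"], sort=True)):
        values = grp["value"].dropna()
        if len(values) == 0:
            warnings.warn(f"trait {trait!r} in {dataset!r} all missing; skipped",
                          stacklevel=2)
            continue
        if len(values) < min_values:
            warnings.warn(f"trait {trait!r} in {dataset!r} has <{min_values} values; skipped",
                          stacklevel=2)
            continue
        lower, upper = tukey_fences(values.to_numpy(), k=k)
        for r in grp.itertuples(index=False):
            if carriers is not None and r.accession not in carriers:
                continue
            if pd.isna(r.value) or lower <= r.value <= upper:
                continue
            rows.append({
                "accession": r.accession, "trait": trait, "dataset": dataset,
                "value": r.value, "lower_fence": lower, "upper_fence": upper,
                "direction": "high" if r.value > upper else "low",
                "lsvs": ";".join(carriers[r.accession]) if carriers else "",
            })
    return pd.DataFrame(rows, columns=[
        "accession", "trait", "dataset", "value",
        "lower_fence", "upper_fence", "direction", "lsvs"])


def carriers_of(calls: list[LSVCall]) -> dict[str, list[str]]:
    """Accession -> descriptions of the LSVs it carries."""
    out: dict[str, list[str]] = {}
    for call in calls:
        desc = f"{call.chromosome}:{call.start_bp + 1}-{call.end_bp}:{call.kind}"
        for acc in call.carriers:
            out.setdefault(acc, []).append(desc)
    return out


def lsv_pipeline(counts: pd.DataFrame, genes: pd.DataFrame, reference: str,
                 ref_floor: float = 0.1, window: int = 20, step: int = 5,
                 del_threshold: float = 0.35, dup_threshold: float = 1.65,
                 min_consecutive: int = 2, min_span_bp: int = 40_000
                 ) -> list[LSVCall]:
    """Counts -> TPM -> ratio tracks -> smoothing -> LSV calls."""
    lengths = genes.set_index("gene_id")["length"]
    tpm = tpm_normalize(counts, lengths)
    tracks = coverage_ratio(tpm, genes, reference, ref_floor=ref_floor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        windows = [smooth(t, window=window, step=step) for t in tracks]
    return call_lsvs(windows, reference, del_threshold=del_threshold,
                     dup_threshold=dup_threshold,
                     min_consecutive=min_consecutive, min_span_bp=min_span_bp)
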