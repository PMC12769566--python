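"""Synthetic allotetraploid study generator with planted truth.

Emulates the data a two-subgenome (A/B) genome study consumes: a reference
("anchor") gene set mirrored onto subgenome chromosomes with configurable
homoeolog retention, BLAST-style homology hits with decoys, tissue x replicate
TPM matrices with planted relative-expression dominance, negative-binomial
per-gene coverage counts with planted deletions/duplications, phenotype tables
with planted outliers among variant carriers, and log-normal Ks mixtures.

Every generator draws from child streams spawned deterministically from one
seed, so identical ``SimConfig`` objects yield byte-identical output files
regardless of which generators are invoked or in what order.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .datasets import TELOMERE_MOTIF, TISSUES
from .genomestats import reverse_complement

COPY_RATIO = {
    ("DEL", "hom"): 0.0,
    ("DEL", "het"): 0.5,
    ("DUP", "het"): 1.5,
    ("DUP", "hom"): 2.0,
}

# child-stream indices, one per generator (fixed so outputs are independent
# of generator call order)
_STREAMS = {"genome": 0, "homology": 1, "expression": 2,
            "coverage": 3, "phenotypes": 4, "ks": 5}


@dataclass(frozen=True)
class LsvSpec:
    """A planted large structural variant, in gene-order coordinates."""
    chromosome: str
    start_gene: int          # 0-based order index of the first affected gene
    n_genes: int
    kind: str                # DEL | DUP
    zygosity: str            # hom | het
    carriers: tuple[str, ...]

    def __post_init__(self):
        if (self.kind, self.zygosity) not in COPY_RATIO:
            raise ValueError(f"unknown LSV type {self.kind}/{self.zygosity}")
        if self.n_genes < 1 or self.start_gene < 0:
            raise ValueError("LSV gene span must be non-empty")
        if not self.carriers:
            raise ValueError("LSV needs at least one carrier")


@dataclass(frozen=True)
class PhenotypeSpec:
    trait: str
    mean: float
    sd: float
    # planted outliers as (accession, value); values chosen by the caller
    outliers: tuple[tuple[str, float], ...] = ()


def _check_triple(name: str, triple) -> None:
    if len(triple) != 3 or any(p < 0 for p in triple):
        raise ValueError(f"{name} must be three non-negative probabilities")
    if abs(sum(triple) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(triple)})")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel."""

    seed: int = 0
    # genome layout
    n_chromosomes_per_subgenome: int = 2
    genes_per_chromosome: int = 200
    gene_length_mean_bp: int = 2000
    gene_length_sdlog: float = 0.25
    intergenic_mean_bp: int = 1500
    telomere_motif_copies: int = 50
    # retention: (fully retained, partially fractionated, fully fractionated)
    retention_rates: tuple[float, float, float] = (0.632, 0.092, 0.276)
    # expression
    dominance_proportions: tuple[float, float, float] = (0.10, 0.80, 0.10)
    dynamic_fraction: float = 0.21
    n_tissues: int = 10
    n_replicates: int = 3
    expression_noise_sdlog: float = 0.15
    low_expression_fraction: float = 0.02
    # coverage panel
    n_accessions: int = 50
    reference_accession: str = "JK-8"
    base_depth: float = 50.0
    coverage_dispersion: float = 0.1
    planted_lsvs: tuple[LsvSpec, ...] = ()
    # phenotypes
    phenotype_specs: tuple[PhenotypeSpec, ...] = ()
    # Ks mixture: (weight, meanlog, sdlog) per component
    ks_components: tuple[tuple[float, float, float], ...] = (
        (1.0, math.log(0.048), 0.40),
    )
    n_ks: int = 5000
    low_ks_fraction: float = 0.0
    # homology decoys (share a query with true hits, low bitscore)
    decoy_fraction: float = 0.10

    def __post_init__(self):
        for name in ("n_chromosomes_per_subgenome", "genes_per_chromosome",
                     "gene_length_mean_bp", "intergenic_mean_bp",
                     "n_tissues", "n_replicates", "n_accessions", "n_ks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        _check_triple("retention_rates", self.retention_rates)
        _check_triple("dominance_proportions", self.dominance_proportions)
        if abs(sum(w for w, _, _ in self.ks_components) - 1.0) > 1e-9:
            raise ValueError("ks_components weights must sum to 1")
        if any(sd <= 0 for _, _, sd in self.ks_components):
            raise ValueError("ks_components sdlog must be positive")
        if self.expression_noise_sdlog < 0 or self.coverage_dispersion < 0:
            raise ValueError("noise parameters must be non-negative")
        for lsv in self.planted_lsvs:
            if self.reference_accession in lsv.carriers:
                raise ValueError("reference accession cannot carry a planted LSV")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.Generator(np.random.PCG64(children[_STREAMS[stream]]))

    def accessions(self) -> list[str]:
        panel = [f"LM-{i:03d}" for i in range(1, self.n_accessions)]
        return [self.reference_accession] + panel

    def tissues(self) -> list[str]:
        if self.n_tissues == len(TISSUES):
            return list(TISSUES)
        return [f"T{i + 1}" for i in range(self.n_tissues)]


@dataclass
class PlantedTruth:
    """Machine-readable record of everything the generators planted."""

    retention: dict[str, str] = field(default_factory=dict)      # ref gene -> class
    homeologs: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    ref_genes: pd.DataFrame | None = None
    target_genes: pd.DataFrame | None = None
    true_hits: set[tuple[str, str]] = field(default_factory=set)
    dominance: pd.DataFrame | None = None    # pair_id, tissue, label, re_b
    stability: dict[str, str] = field(default_factory=dict)
    low_expressed_pairs: set[str] = field(default_factory=set)
    lsvs: list[dict] = field(default_factory=list)               # with bp coords
    phenotype_outliers: list[dict] = field(default_factory=list)
    ks_components: list[tuple[float, float, float]] = field(default_factory=list)

    def pairs(self) -> pd.DataFrame:
        rows = [
            {"pair_id": ref, "gene_A": a, "gene_B": b}
            for ref, (a, b) in self.homeologs.items()
            if a is not None and b is not None
        ]
        return pd.DataFrame(rows, columns=["pair_id", "gene_A", "gene_B"])

    def to_json(self) -> dict:
        out = {
            "retention": self.retention,
            "homeologs": {k: list(v) for k, v in self.homeologs.items()},
            "true_hits": sorted(self.true_hits),
            "stability": self.stability,
            "low_expressed_pairs": sorted(self.low_expressed_pairs),
            "lsvs": self.lsvs,
            "phenotype_outliers": self.phenotype_outliers,
            "ks_components": [list(c) for c in self.ks_components],
        }
        for name in ("ref_genes", "target_genes", "dominance"):
            frame = getattr(self, name)
            out[name] = None if frame is None else frame.to_dict(orient="list")
        return out


# ---------------------------------------------------------------------------
# genome layout and sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def gen_genome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame, PlantedTruth]:
    """Lay out a mirrored two-subgenome genome.

    Each reference anchor chromosome ``Ref{c}`` of ``genes_per_chromosome``
    genes is mirrored onto target chromosomes ``Chr{c}A`` and ``Chr{c}B``;
    per-anchor retention classes decide which homoeolog copies exist. Target
    chromosome sequences carry telomere motif repeats at both ends (forward
    motif at the 5' end, reverse complement at the 3' end). Internal gene
    coordinates are 0-based half-open.
    """
    rng = config.rng("genome")
    truth = PlantedTruth()
    classes = ("fully_retained", "partially_fractionated", "fully_fractionated")

    ref_rows, tgt_rows = [], []
    sequences: dict[str, str] = {}
    for c in range(1, config.n_chromosomes_per_subgenome + 1):
        ref_chrom = f"Ref{c}"
        present: dict[str, list[tuple[str, str]]] = {"A": [], "B": []}
        pos = 0
        for j in range(config.genes_per_chromosome):
            ref_id = f"REF{c}g{j + 1:04d}"
            cls = classes[rng.choice(3, p=np.asarray(config.retention_rates))]
            truth.retention[ref_id] = cls
            length = max(300, int(rng.lognormal(
                math.log(config.gene_length_mean_bp), config.gene_length_sdlog)))
            ref_rows.append({"gene_id": ref_id, "chromosome": ref_chrom,
                             "start": pos, "end": pos + length, "strand": "+"})
            pos += length + int(rng.exponential(config.intergenic_mean_bp)) + 100
            if cls == "fully_retained":
                kept = ("A", "B")
            elif cls == "partially_fractionated":
                kept = ("A",) if rng.random() < 0.5 else ("B",)
            else:
                kept = ()
            a_id = b_id = None
            for sub in kept:
                gid = f"LM{c}{sub}g{j + 1:04d}"
                present[sub].append((ref_id, gid))
                if sub == "A":
                    a_id = gid
                else:
                    b_id = gid
            truth.homeologs[ref_id] = (a_id, b_id)

        for sub in ("A", "B"):
            chrom = f"Chr{c}{sub}"
            telomere = TELOMERE_MOTIF * config.telomere_motif_copies
            parts = [telomere, _random_dna(rng, 2000)]
            pos = len(telomere) + 2000
            for _, gid in present[sub]:
                length = max(300, int(rng.lognormal(
                    math.log(config.gene_length_mean_bp), config.gene_length_sdlog)))
                gap = int(rng.exponential(config.intergenic_mean_bp)) + 100
                tgt_rows.append({"gene_id": gid, "chromosome": chrom,
                                 "start": pos, "end": pos + length,
                                 "strand": "+" if rng.random() < 0.8 else "-"})
                parts.append(_random_dna(rng, length + gap))
                pos += length + gap
            parts.append(_random_dna(rng, 2000))
            parts.append(reverse_complement(TELOMERE_MOTIF) * config.telomere_motif_copies)
            sequences[chrom] = "".join(parts)

    truth.ref_genes = io._with_order_index(pd.DataFrame(ref_rows))
    truth.target_genes = io._with_order_index(pd.DataFrame(tgt_rows))
    annotation = truth.target_genes.copy()
    return sequences, annotation, truth


# ---------------------------------------------------------------------------
# homology hits
# ---------------------------------------------------------------------------

def gen_homology(truth: PlantedTruth, config: SimConfig) -> pd.DataFrame:
    """Emit a 12-column BLAST-style hit table: one high-bitscore hit per
    retained homoeolog copy, plus ``decoy_fraction`` low-bitscore decoy hits
    that share a query with a true hit (so they exercise the bitscore-drop
    filter, not only the E-value cut)."""
    rng = config.rng("homology")
    rows = []
    max_score: dict[str, float] = {}
    for ref_id, (a_id, b_id) in truth.homeologs.items():
        # homoeolog hits of one query share a base score (both copies align
        # comparably well), keeping true hits above the bitscore-drop floor
        base = float(rng.uniform(300, 600))
        for subject in (a_id, b_id):
            if subject is None:
                continue
            score = base * float(rng.uniform(0.85, 1.0))
            max_score[ref_id] = max(max_score.get(ref_id, 0.0), score)
            truth.true_hits.add((ref_id, subject))
            rows.append(_hit_row(rng, ref_id, subject, score,
                                 evalue=10.0 ** -rng.uniform(40, 150)))
    queries_with_hits = sorted(max_score)
    n_decoys = int(round(config.decoy_fraction * len(rows)))
    targets = truth.target_genes["gene_id"].to_numpy()
    for i in range(n_decoys):
        query = queries_with_hits[int(rng.integers(len(queries_with_hits)))]
        subject = str(rng.choice(targets))
        score = float(rng.uniform(0.2, 0.55)) * max_score[query]
        # half the decoys also fail the E-value cut
        evalue = 1e-30 if i % 2 == 0 else 1e-10
        rows.append(_hit_row(rng, query, subject, score, evalue=evalue))
    hits = pd.DataFrame(rows, columns=io.BLAST6_COLUMNS)
    return hits.sort_values(["qseqid", "bitscore"],
                            ascending=[True, False]).reset_index(drop=True)


def _hit_row(rng, query, subject, score, evalue):
    length = int(rng.integers(200, 500))
    return {
        "qseqid": query, "sseqid": subject,
        "pident": round(float(rng.uniform(80, 99.5)), 2),
        "length": length,
        "mismatch": int(rng.integers(0, 30)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1, "qend": length, "sstart": 1, "send": length,
        "evalue": float(evalue), "bitscore": round(float(score), 1),
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_RE_B_BANDS = {  # planted final RE_B per dominance label
    "A_dominant": (0.03, 0.18),
    "balanced": (0.30, 0.70),
    "B_dominant": (0.82, 0.97),
}
_LABELS = ("A_dominant", "balanced", "B_dominant")


def gen_expression(truth: PlantedTruth, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM matrix (genes x tissue-replicate samples) plus a sample sheet.

    Retained pairs are built total-first: the pair total TPM is log-normal and
    split by the planted RE_B for that pair and tissue, then multiplied by
    per-replicate log-normal noise. Singleton genes get independent baseline
    expression. A ``low_expression_fraction`` of pairs is forced below the
    combined-TPM-of-1 floor in one sample.
    """
    rng = config.rng("expression")
    tissues = config.tissues()
    pairs = truth.pairs()
    if pairs.empty:
        raise ValueError("no retained pairs; generate the genome first")

    n_pairs = len(pairs)
    props = np.asarray(config.dominance_proportions)
    base_label = rng.choice(3, size=n_pairs, p=props)
    # A "dynamic" pair has one tissue's label redrawn from the SAME planted
    # proportions, keeping every tissue's marginal exactly at the planted
    # triple. A redraw only realises a dynamic pair when the new label
    # differs (probability 1 - sum(p^2)), so the redraw rate is scaled up to
    # make the expected realised dynamic fraction equal dynamic_fraction.
    p_change = 1.0 - float((props ** 2).sum())
    redraw_rate = min(1.0, config.dynamic_fraction / p_change) if p_change > 0 else 0.0
    dynamic = rng.random(n_pairs) < redraw_rate
    sample_ids, meta_rows = [], []
    for tissue in tissues:
        for rep in range(1, config.n_replicates + 1):
            sample_ids.append(f"{tissue}_{rep}")
            meta_rows.append({"sample_id": f"{tissue}_{rep}",
                              "tissue": tissue, "replicate": rep})
    samples = pd.DataFrame(meta_rows)

    genes = truth.target_genes["gene_id"].tolist()
    matrix = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=sample_ids)

    dom_rows = []
    low_pairs = rng.choice(n_pairs, size=int(round(config.low_expression_fraction * n_pairs)),
                           replace=False)
    low_pairs = set(int(i) for i in low_pairs)
    for i, row in enumerate(pairs.itertuples(index=False)):
        labels = np.full(len(tissues), base_label[i])
        if dynamic[i] and len(tissues) > 1:
            t = int(rng.integers(len(tissues)))
            labels[t] = int(rng.choice(3, p=props))
        truth.stability[row.pair_id] = "dynamic" if len(set(labels)) > 1 else "stable"
        low_sample = int(rng.integers(len(sample_ids))) if i in low_pairs else -1
        if low_sample >= 0:
            truth.low_expressed_pairs.add(row.pair_id)
        for t, tissue in enumerate(tissues):
            label = _LABELS[labels[t]]
            lo, hi = _RE_B_BANDS[label]
            re_b = float(rng.uniform(lo, hi))
            total = float(rng.lognormal(math.log(30.0), 0.8)) + 2.0
            dom_rows.append({"pair_id": row.pair_id, "tissue": tissue,
                             "label": label, "re_b": re_b})
            for rep in range(config.n_replicates):
                col = f"{tissue}_{rep + 1}"
                noise_a = rng.lognormal(0.0, config.expression_noise_sdlog)
                noise_b = rng.lognormal(0.0, config.expression_noise_sdlog)
                tpm_a = total * (1.0 - re_b) * noise_a
                tpm_b = total * re_b * noise_b
                if sample_ids.index(col) == low_sample:
                    scale = 0.5 / max(tpm_a + tpm_b, 1e-9)
                    tpm_a, tpm_b = tpm_a * scale, tpm_b * scale
                matrix.at[row.gene_A, col] = tpm_a
                matrix.at[row.gene_B, col] = tpm_b

    paired_genes = set(pairs["gene_A"]) | set(pairs["gene_B"])
    singles = [g for g in genes if g not in paired_genes]
    if singles:
        base = rng.lognormal(math.log(15.0), 1.0, size=(len(singles), len(sample_ids)))
        noise = rng.lognormal(0.0, config.expression_noise_sdlog,
                              size=(len(singles), len(sample_ids)))
        matrix.loc[singles, :] = base * noise

    truth.dominance = pd.DataFrame(dom_rows)
    return matrix, samples


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def gen_coverage(truth: PlantedTruth, config: SimConfig) -> pd.DataFrame:
    """Gene x accession raw count matrix.

    Counts are negative binomial with mean ``base_depth * (length/1kb) *
    copy_ratio`` and dispersion ``coverage_dispersion`` (0 reduces to
    Poisson). Planted LSVs scale the copy ratio in their carriers
    (hom DEL 0, het DEL 0.5, het DUP 1.5, hom DUP 2); the reference accession
    is always copy ratio 1.
    """
    rng = config.rng("coverage")
    genes = truth.target_genes
    if genes is None:
        raise ValueError("generate the genome first")
    accessions = config.accessions()
    lengths = genes["length"].to_numpy(dtype=float)
    mean = config.base_depth * lengths / 1000.0

    ratio = np.ones((len(genes), len(accessions)))
    acc_index = {a: k for k, a in enumerate(accessions)}
    gene_pos = {(c, o): i for i, (c, o) in
                enumerate(zip(genes["chromosome"], genes["order_index"]))}
    truth.lsvs = []
    for lsv in config.planted_lsvs:
        idx = []
        for o in range(lsv.start_gene, lsv.start_gene + lsv.n_genes):
            key = (lsv.chromosome, o)
            if key not in gene_pos:
                raise ValueError(f"planted LSV exceeds {lsv.chromosome} gene count")
            idx.append(gene_pos[key])
        for acc in lsv.carriers:
            if acc not in acc_index:
                raise ValueError(f"unknown carrier accession {acc}")
            ratio[idx, acc_index[acc]] = COPY_RATIO[(lsv.kind, lsv.zygosity)]
        sub = genes.iloc[idx]
        truth.lsvs.append({
            "chromosome": lsv.chromosome, "kind": lsv.kind,
            "zygosity": lsv.zygosity, "carriers": list(lsv.carriers),
            "first_gene": sub["gene_id"].iloc[0], "last_gene": sub["gene_id"].iloc[-1],
            "first_order": int(lsv.start_gene),
            "last_order": int(lsv.start_gene + lsv.n_genes - 1),
            "start_bp": int(sub["start"].min()), "end_bp": int(sub["end"].max()),
            "span_bp": int(sub["end"].max() - sub["start"].min()),
            "n_genes": int(lsv.n_genes),
        })
    ratio[:, acc_index[config.reference_accession]] = 1.0

    mu = mean[:, None] * ratio
    if config.coverage_dispersion > 0:
        n = 1.0 / config.coverage_dispersion
        counts = np.where(mu > 0, rng.negative_binomial(n, n / (n + np.maximum(mu, 1e-12))), 0)
    else:
        counts = rng.poisson(mu)
    return pd.DataFrame(counts, index=pd.Index(genes["gene_id"], name="gene_id"),
                        columns=accessions)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def default_phenotype_specs(config: SimConfig) -> tuple[PhenotypeSpec, ...]:
    """Grain micronutrient traits on the scale of the study panel (ppm)."""
    return (
        PhenotypeSpec("Fe", 133.0, 30.0),
        PhenotypeSpec("Zn", 30.0, 6.0),
        PhenotypeSpec("Ca", 1000.0, 200.0),
    )


def gen_phenotypes(truth: PlantedTruth, config: SimConfig,
                   dataset: str = "pooled") -> pd.DataFrame:
    """Per-accession trait table (normal traits, planted extreme values)."""
    rng = config.rng("phenotypes")
    specs = config.phenotype_specs or default_phenotype_specs(config)
    accessions = config.accessions()
    table = pd.DataFrame({"accession": accessions, "dataset": dataset})
    truth.phenotype_outliers = []
    for spec in specs:
        if spec.sd < 0:
            raise ValueError("trait sd must be non-negative")
        values = rng.normal(spec.mean, spec.sd, size=len(accessions))
        col = pd.Series(values, index=accessions)
        for accession, value in spec.outliers:
            if accession not in col.index:
                raise ValueError(f"unknown accession {accession}")
            col[accession] = value
            truth.phenotype_outliers.append(
                {"accession": accession, "trait": spec.trait,
                 "dataset": dataset, "value": value})
        table[spec.trait] = col.to_numpy()
    return table


# ---------------------------------------------------------------------------
# Ks values
# ---------------------------------------------------------------------------

def gen_ks(config: SimConfig, truth: PlantedTruth | None = None) -> pd.DataFrame:
    """Sample Ks values from a mixture of log-normals; a ``low_ks_fraction``
    of entries is replaced with values <= 0.001 to exercise the filter."""
    rng = config.rng("ks")
    weights = np.asarray([w for w, _, _ in config.ks_components])
    comp = rng.choice(len(weights), size=config.n_ks, p=weights)
    meanlogs = np.asarray([m for _, m, _ in config.ks_components])
    sdlogs = np.asarray([s for _, _, s in config.ks_components])
    ks = rng.lognormal(meanlogs[comp], sdlogs[comp])
    n_low = int(round(config.low_ks_fraction * config.n_ks))
    if n_low:
        ks[rng.choice(config.n_ks, size=n_low, replace=False)] = rng.uniform(0, 0.001, n_low)
    if truth is not None:
        truth.ks_components = list(config.ks_components)
    return pd.DataFrame({"pair_id": [f"pair{i + 1:05d}" for i in range(config.n_ks)],
                         "ks": ks})


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    truth: PlantedTruth
    sequences: dict[str, str]
    annotation: pd.DataFrame
    hits: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame
    counts: pd.DataFrame
    phenotypes: pd.DataFrame
    ks: pd.DataFrame


def simulate_all(config: SimConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run every generator and optionally write the full file set."""
    sequences, annotation, truth = gen_genome(config)
    hits = gen_homology(truth, config)
    tpm, samples = gen_expression(truth, config)
    counts = gen_coverage(truth, config)
    phenotypes = gen_phenotypes(truth, config)
    ks = gen_ks(config, truth)
    data = SimulatedDataset(config, truth, sequences, annotation, hits,
                            tpm, samples, counts, phenotypes, ks)
    if outdir is not None:
        write_dataset(data, outdir)
    return data


def write_dataset(data: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(data.sequences, outdir / "genome.fasta")
    io.write_gff3(data.annotation, outdir / "genes.gff3")
    io.write_bed(data.annotation, outdir / "genes.bed")
    io.write_gff3(data.truth.ref_genes, outdir / "anchors.gff3")
    io.write_bed(data.truth.ref_genes, outdir / "anchors.bed")
    io.write_blast6(data.hits, outdir / "hits.blast6.tsv")
    io.write_matrix(data.tpm, outdir / "tpm.tsv")
    io.write_table(data.samples, outdir / "samples.tsv")
    io.write_matrix(data.counts, outdir / "coverage_counts.tsv")
    io.write_table(data.phenotypes, outdir / "phenotypes.tsv")
    io.write_table(data.ks, outdir / "ks.tsv")
    truth_dict = data.truth.to_json()
    truth_dict["config"] = _config_to_json(data.config)
    io.write_json(truth_dict, outdir / "truth.json")


def _config_to_json(config: SimConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["planted_lsvs"] = [dataclasses.asdict(l) for l in config.planted_lsvs]
    raw["phenotype_specs"] = [dataclasses.asdict(p) for p in config.phenotype_specs]
    return raw
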