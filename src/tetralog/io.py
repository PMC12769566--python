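"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; everything tabular (BLAST outfmt-6, GFF3 gene
features, BED, TSV matrices) is handled with pandas so round-trips are
lossless and typed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_blast6(hits: pd.DataFrame, path: str | Path) -> None:
    hits.loc[:, BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_blast6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS)


def genes_to_gff3(genes: pd.DataFrame, source: str = "tetralog") -> pd.DataFrame:
    """Convert an internal gene table (0-based half-open) to GFF3 rows
    (1-based inclusive)."""
    return pd.DataFrame(
        {
            "seqid": genes["chromosome"],
            "source": source,
            "type": "gene",
            "start": genes["start"] + 1,
            "end": genes["end"],
            "score": ".",
            "strand": genes["strand"],
            "phase": ".",
            "attributes": "ID=" + genes["gene_id"],
        }
    )


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "tetralog") -> None:
    rows = genes_to_gff3(genes, source=source)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 file back into the internal 0-based
    half-open gene table, ordered along each chromosome."""
    raw = pd.read_csv(path, sep="\t", comment="#", names=GFF3_COLUMNS)
    raw = raw[raw["type"] == "gene"].copy()
    raw["gene_id"] = raw["attributes"].str.extract(r"ID=([^;]+)")
    genes = pd.DataFrame(
        {
            "gene_id": raw["gene_id"],
            "chromosome": raw["seqid"],
            "start": raw["start"] - 1,
            "end": raw["end"],
            "strand": raw["strand"],
        }
    )
    return _with_order_index(genes)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = genes[["chromosome", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = genes["strand"].values
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t",
        names=["chromosome", "start", "end", "gene_id", "score", "strand"],
    )
    genes = bed[["gene_id", "chromosome", "start", "end", "strand"]].copy()
    return _with_order_index(genes)


def _with_order_index(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    genes["order_index"] = genes.groupby("chromosome").cumcount()
    genes["length"] = genes["end"] - genes["start"]
    return genes


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
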