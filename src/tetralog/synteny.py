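"""Syntelog construction and homoeolog retention classification.

Homology hits are filtered (E-value cut plus per-query bitscore-drop rule),
turned into order-indexed anchor pairs, chained by a max-score collinear
dynamic programme in both orientations (greedy peel-off for secondary
chains), reduced so each reference gene keeps only its pair from the highest
scoring chain, and finally written as one syntelog row per reference anchor
with a retention class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RETENTION_CLASSES = ("fully_retained", "partially_fractionated", "fully_fractionated")


def filter_hits(hits: pd.DataFrame, evalue_max: float = 1e-20,
                drop_fraction: float = 0.4) -> pd.DataFrame:
    """Per-query homology hit filter.

    A hit is retained iff its E-value is at most ``evalue_max`` and its
    bitscore is at least ``(1 - drop_fraction)`` times the best bitscore among
    that query's hits passing the E-value cut (boundary inclusive). Duplicate
    (query, subject) rows are collapsed to the max-bitscore one first.
    """
    if hits.empty:
        return hits.copy()
    if (hits["bitscore"] <= 0).any():
        raise ValueError("bitscores must be positive")
    dedup = (hits.sort_values("bitscore", ascending=False)
                 .drop_duplicates(["qseqid", "sseqid"], keep="first"))
    passing = dedup[dedup["evalue"] <= evalue_max].copy()
    if passing.empty:
        return passing
    best = passing.groupby("qseqid")["bitscore"].transform("max")
    floor = (1.0 - drop_fraction) * best
    kept = passing[passing["bitscore"] >= floor - 1e-12]
    return kept.sort_values(["qseqid", "bitscore"],
                            ascending=[True, False]).reset_index(drop=True)


@dataclass(frozen=True)
class AnchorPair:
    ref_gene: str
    tgt_gene: str
    ref_order: int
    tgt_order: int
    score: float


@dataclass
class Chain:
    pairs: list[AnchorPair]
    orientation: str  # parallel | antiparallel
    score: float
    key: str = ""

    def __len__(self):
        return len(self.pairs)


def chain_anchors(pairs: list[AnchorPair] | pd.DataFrame,
                  min_pairs: int = 6,
                  max_gap_genes: int = 25,
                  gap_penalty: float | None = None) -> list[Chain]:
    """Collinear chaining over one (reference chromosome, target chromosome)
    anchor dot-plot.

    The dynamic programme maximises sum of match scores minus ``gap_penalty``
    per skipped gene position (on either axis), subject to strictly increasing
    reference order and strictly increasing (parallel) or strictly decreasing
    (antiparallel) target order, with at most ``max_gap_genes`` skipped
    positions per axis per step. Chains are peeled off greedily: the best
    chain is reported, its anchors removed, and the programme re-run until no
    chain of at least ``min_pairs`` anchors remains.

    ``gap_penalty`` defaults to 0.1 x the mean match score, small enough to
    bridge fractionation gaps yet penalise diffuse chains.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    if isinstance(pairs, pd.DataFrame):
        pairs = [AnchorPair(r.ref_gene, r.tgt_gene, int(r.ref_order),
                            int(r.tgt_order), float(r.score))
                 for r in pairs.itertuples(index=False)]
    if not pairs:
        return []
    if gap_penalty is None:
        gap_penalty = 0.1 * float(np.mean([p.score for p in pairs]))

    remaining = list(pairs)
    chains: list[Chain] = []
    while True:
        best = None
        for orientation in ("parallel", "antiparallel"):
            cand = _best_chain(remaining, orientation, max_gap_genes, gap_penalty)
            if cand is not None and (best is None or cand.score > best.score or
                                     (cand.score == best.score and len(cand) > len(best))):
                best = cand
        if best is None or len(best) < min_pairs:
            break
        chains.append(best)
        used = set(id(p) for p in best.pairs)
        remaining = [p for p in remaining if id(p) not in used]
        if not remaining:
            break
    return chains


def _best_chain(pairs: list[AnchorPair], orientation: str,
                max_gap: int, gap_penalty: float) -> Chain | None:
    sign = 1 if orientation == "parallel" else -1
    order = sorted(range(len(pairs)),
                   key=lambda i: (pairs[i].ref_order, sign * pairs[i].tgt_order))
    n = len(order)
    dp = np.array([pairs[i].score for i in order], dtype=float)
    back = np.full(n, -1, dtype=int)
    for a in range(n):
        pa = pairs[order[a]]
        for b in range(a):
            pb = pairs[order[b]]
            dref = pa.ref_order - pb.ref_order
            dtgt = sign * (pa.tgt_order - pb.tgt_order)
            if dref < 1 or dtgt < 1:
                continue
            if dref - 1 > max_gap or dtgt - 1 > max_gap:
                continue
            cand = dp[b] + pa.score - gap_penalty * ((dref - 1) + (dtgt - 1))
            if cand > dp[a] + 1e-12:
                dp[a] = cand
                back[a] = b
    if n == 0:
        return None
    end = int(np.argmax(dp))
    idx = []
    a = end
    while a != -1:
        idx.append(order[a])
        a = int(back[a])
    idx.reverse()
    return Chain([pairs[i] for i in idx], orientation, float(dp[end]))


def best_chain_assignment(chains: list[Chain]) -> pd.DataFrame:
    """Keep, for each reference gene, only its anchor pair from the highest
    scoring chain (ties: longer chain, then lexicographically smaller chain
    key)."""
    for rank, chain in enumerate(chains):
        if not chain.key:
            chain.key = f"chain{rank:05d}"
    best: dict[str, tuple] = {}
    for chain in sorted(chains, key=lambda c: (-c.score, -len(c), c.key)):
        for pair in chain.pairs:
            if pair.ref_gene not in best:
                best[pair.ref_gene] = (pair, chain.key)
    rows = [{"ref_gene": p.ref_gene, "tgt_gene": p.tgt_gene,
             "score": p.score, "chain": key}
            for p, key in best.values()]
    return pd.DataFrame(rows, columns=["ref_gene", "tgt_gene", "score", "chain"])


def classify_retention(homeolog_a: str | None, homeolog_b: str | None) -> str:
    if homeolog_a and homeolog_b:
        return "fully_retained"
    if homeolog_a or homeolog_b:
        return "partially_fractionated"
    return "fully_fractionated"


def build_syntelog_table(assignment_a: pd.DataFrame, assignment_b: pd.DataFrame,
                         ref_genes: pd.DataFrame) -> pd.DataFrame:
    """One row per reference anchor gene with its (possibly absent) A and B
    homoeologs and the retention class."""
    slots = {}
    for label, assignment in (("homeolog_A", assignment_a), ("homeolog_B", assignment_b)):
        if not assignment.empty and assignment["ref_gene"].duplicated().any():
            raise RuntimeError(
                "reference gene assigned twice within one subgenome; "
                "best_chain_assignment contract violated")
        slots[label] = ({} if assignment.empty else
                        dict(zip(assignment["ref_gene"], assignment["tgt_gene"])))
    rows = []
    for ref in ref_genes["gene_id"]:
        a = slots["homeolog_A"].get(ref)
        b = slots["homeolog_B"].get(ref)
        rows.append({"reference_id": ref, "homeolog_A": a, "homeolog_B": b,
                     "retention_class": classify_retention(a, b)})
    return pd.DataFrame(rows)


def subgenome_of(chromosome: str) -> str | None:
    """Subgenome letter from the chromosome-name suffix convention
    (Chr1A -> A)."""
    if chromosome and chromosome[-1] in ("A", "B"):
        return chromosome[-1]
    return None


def build_syntelogs(hits: pd.DataFrame, ref_genes: pd.DataFrame,
                    tgt_genes: pd.DataFrame,
                    subgenome_map: dict[str, str] | None = None,
                    evalue_max: float = 1e-20, drop_fraction: float = 0.4,
                    min_pairs: int = 6, max_gap_genes: int = 25,
                    gap_penalty: float | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synteny pipeline: filter hits, chain per chromosome pair within
    each subgenome, resolve each reference gene to its best chain, and build
    the syntelog table. Returns (syntelog table, chain report)."""
    kept = filter_hits(hits, evalue_max=evalue_max, drop_fraction=drop_fraction)
    ref_meta = ref_genes.set_index("gene_id")
    tgt_meta = tgt_genes.set_index("gene_id")
    if subgenome_map is None:
        subgenome_map = {c: subgenome_of(c) for c in tgt_genes["chromosome"].unique()}

    merged = kept.merge(ref_meta[["chromosome", "order_index"]],
                        left_on="qseqid", right_index=True)
    merged = merged.merge(tgt_meta[["chromosome", "order_index"]],
                          left_on="sseqid", right_index=True,
                          suffixes=("_ref", "_tgt"))
    merged["subgenome"] = merged["chromosome_tgt"].map(subgenome_map)

    assignments = {}
    report_rows = []
    for sub in ("A", "B"):
        chains_all: list[Chain] = []
        part = merged[merged["subgenome"] == sub]
        for (ref_chrom, tgt_chrom), grp in part.groupby(
                ["chromosome_ref", "chromosome_tgt"], sort=True):
            pairs = [AnchorPair(r.qseqid, r.sseqid, int(r.order_index_ref),
                                int(r.order_index_tgt), float(r.bitscore))
                     for r in grp.itertuples(index=False)]
            found = chain_anchors(pairs, min_pairs=min_pairs,
                                  max_gap_genes=max_gap_genes,
                                  gap_penalty=gap_penalty)
            for rank, chain in enumerate(found):
                chain.key = f"{ref_chrom}:{tgt_chrom}:{rank:03d}"
                report_rows.append({
                    "chain": chain.key, "subgenome": sub,
                    "ref_chromosome": ref_chrom, "tgt_chromosome": tgt_chrom,
                    "orientation": chain.orientation, "n_pairs": len(chain),
                    "score": chain.score,
                })
            chains_all.extend(found)
        assignments[sub] = best_chain_assignment(chains_all)

    table = build_syntelog_table(assignments["A"], assignments["B"], ref_genes)
    report = pd.DataFrame(report_rows, columns=[
        "chain", "subgenome", "ref_chromosome", "tgt_chromosome",
        "orientation", "n_pairs", "score"])
    return table, report
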