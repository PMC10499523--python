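"""Gene/transcript/exon models from GFF3 and the positional queries they answer.

The AS-type classifier needs three things from an annotation: the exon
intervals of each transcript, the merged exon union of each gene, and which
exon intervals are first or last in some transcript (strand-aware). Gene
assignment of junctions is deliberately tolerant: a junction belongs to a gene
when both of its flanking exonic positions fall inside the gene's span and the
strands are compatible — exact exon-boundary matches are *not* required, since
real junction sets routinely contain unannotated introns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .junction_data import Junction

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Interval, ...]  # sorted, 1-based inclusive, non-overlapping

    def __post_init__(self) -> None:
        ex = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", ex)
        if not ex:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]
    exon_union: tuple[Interval, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_union", merge_intervals(
            iv for t in self.transcripts for iv in t.exons
        ))

    @property
    def span(self) -> Interval:
        return self.exon_union[0][0], self.exon_union[-1][1]

    @property
    def exons(self) -> set[Interval]:
        """All distinct exon intervals across transcripts (unmerged)."""
        return {iv for t in self.transcripts for iv in t.exons}


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def parse_gff3(path: str | Path, allowed_chroms: set[str] | None = None) -> list[GeneModel]:
    """Parse a GFF3 into gene models, optionally keeping only some chromosomes.

    Accepts ``mRNA`` or ``transcript`` features with Parent-linked exons; exons
    whose parent transcript cannot be resolved are skipped with a warning. The
    file need not be sorted.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    tx_types = [ft for ft in ("mRNA", "transcript") if ft in set(db.featuretypes())]
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if allowed_chroms is not None and gene.seqid not in allowed_chroms:
            continue
        transcripts = []
        for ttype in tx_types:
            for tx in db.children(gene, featuretype=ttype, order_by="start"):
                exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
                if not exons:
                    warnings.warn(f"transcript {tx.id} has no exons; skipped")
                    continue
                transcripts.append(Transcript(tx.id, tuple(exons)))
        if not transcripts:
            warnings.warn(f"gene {gene.id} has no transcripts; skipped")
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, tuple(transcripts)))
    genes.sort(key=lambda g: (g.chrom, g.span, g.gene_id))
    return genes


def first_last_exons(gene: GeneModel) -> tuple[set[Interval], set[Interval]]:
    """Union over transcripts of (first-exon intervals, last-exon intervals).

    Strand-aware: on '+' the first exon of a transcript is its lowest-coordinate
    exon; on '-' its highest-coordinate exon. Unknown strand is treated as '+'.
    """
    first: set[Interval] = set()
    last: set[Interval] = set()
    flip = gene.strand == "-"
    for tx in gene.transcripts:
        lo, hi = tx.exons[0], tx.exons[-1]
        first.add(hi if flip else lo)
        last.add(lo if flip else hi)
    return first, last


def _strand_compatible(junction_strand: str, gene_strand: str) -> bool:
    return junction_strand == "." or gene_strand == "." or junction_strand == gene_strand


def _union_overlap(lo: int, hi: int, union: Sequence[Interval]) -> int:
    ov = 0
    for s, e in union:
        ov += max(0, min(hi, e) - max(lo, s) + 1)
    return ov


def assign_junctions_to_genes(
    junctions: Iterable[Junction | str], genes: Sequence[GeneModel]
) -> dict[str, str | None]:
    """Map each junction to at most one gene, or None.

    A junction is assignable to a gene iff both flanking exonic positions
    (start-1 and end+1) fall within the gene's span and the strands are
    compatible. Ties go to the gene with the most exon-union overlap with the
    interval [start-1, end+1], then to the lexicographically smaller gene_id.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, str | None] = {}
    for j in junctions:
        if isinstance(j, str):
            j = Junction.from_key(j)
        lo, hi = j.upstream_exonic, j.downstream_exonic
        candidates = []
        for g in by_chrom.get(j.chrom, []):
            gs, ge = g.span
            if gs <= lo and hi <= ge and _strand_compatible(j.strand, g.strand):
                candidates.append((-_union_overlap(lo, hi, g.exon_union), g.gene_id))
        out[j.key] = min(candidates)[1] if candidates else None
    return out


def assign_clusters_to_genes(
    cluster_of: Mapping[str, str], gene_of_junction: Mapping[str, str | None]
) -> dict[str, str | None]:
    """Assign each LC the gene most of its junctions map to (ties: smaller id)."""
    votes: dict[str, dict[str, int]] = {}
    for key, lc in cluster_of.items():
        gene = gene_of_junction.get(key)
        if gene is not None:
            votes.setdefault(lc, {}).setdefault(gene, 0)
            votes[lc][gene] += 1
    out: dict[str, str | None] = {lc: None for lc in set(cluster_of.values())}
    for lc, counts in votes.items():
        out[lc] = min(counts, key=lambda g: (-counts[g], g))
    return out
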