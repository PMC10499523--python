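"""LeafCutter-style junction clusters: construction, filtering, split and prune.

A cluster (LC) is a connected component of the graph whose vertices are
junctions and whose edges join any two junctions that share a start or an end
coordinate, computed separately per chromosome and strand. The refinement pass
applied before testing is:

1. drop poorly covered junctions (more than ``min_reads`` JSR in fewer than
   ``min_samples`` samples);
2. build clusters on the survivors;
3. drop junctions whose count is below 10% of the per-sample mean JSR count of
   their LC in *every* sample;
4. split LCs whose members lost connectivity, and prune LCs with < 2 junctions.

Unknown-strand junctions (``.``) cluster only with each other, which prevents
chimeric clusters across antisense gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .junction_data import Junction, JunctionCountTable


@dataclass(frozen=True)
class LeafCluster:
    lc_id: str
    junction_keys: tuple[str, ...]
    chrom: str
    strand: str

    def __len__(self) -> int:
        return len(self.junction_keys)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _components(junctions: Sequence[Junction]) -> list[list[int]]:
    """Connected components of the shared-start-or-end graph (indices)."""
    uf = _UnionFind(len(junctions))
    by_start: dict[int, int] = {}
    by_end: dict[int, int] = {}
    for i, j in enumerate(junctions):
        if j.start in by_start:
            uf.union(by_start[j.start], i)
        else:
            by_start[j.start] = i
        if j.end in by_end:
            uf.union(by_end[j.end], i)
        else:
            by_end[j.end] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(junctions)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def _make_clusters(keys: Iterable[str]) -> list[LeafCluster]:
    juncs = [Junction.from_key(k) for k in keys]
    by_cs: dict[tuple[str, str], list[Junction]] = {}
    for j in juncs:
        by_cs.setdefault((j.chrom, j.strand), []).append(j)
    raw: list[tuple[tuple, list[Junction]]] = []
    for (chrom, strand), members in by_cs.items():
        for comp in _components(members):
            comp_j = sorted((members[i] for i in comp))
            sort_key = (chrom, strand, comp_j[0].start, comp_j[0].end)
            raw.append((sort_key, comp_j))
    raw.sort(key=lambda t: t[0])
    clusters = []
    for i, (sk, comp_j) in enumerate(raw, start=1):
        chrom, strand = sk[0], sk[1]
        clusters.append(
            LeafCluster(
                lc_id=f"{chrom}:clu{i}:{strand}",
                junction_keys=tuple(j.key for j in comp_j),
                chrom=chrom,
                strand=strand,
            )
        )
    return clusters


def build_clusters(table: JunctionCountTable) -> list[LeafCluster]:
    """Connected components per chrom+strand; singletons are returned too."""
    return _make_clusters(table.counts.index)


def cluster_map(clusters: Iterable[LeafCluster]) -> dict[str, str]:
    return {k: lc.lc_id for lc in clusters for k in lc.junction_keys}


def filter_low_support(
    table: JunctionCountTable, min_reads: int = 10, min_samples: int = 2
) -> JunctionCountTable:
    """Keep junctions with more than ``min_reads`` JSR in >= ``min_samples`` samples."""
    n_supported = (table.counts > min_reads).sum(axis=1)
    keep = table.counts.index[n_supported >= min_samples]
    return JunctionCountTable(table.counts.loc[keep], table.samples.reset_index())


def filter_relative_abundance(
    table: JunctionCountTable, clusters: Sequence[LeafCluster], frac: float = 0.10
) -> JunctionCountTable:
    """Drop junctions below ``frac`` of their LC's per-sample mean count in all samples.

    The mean is taken per sample over the LC's member junctions (the junction
    itself included); a junction survives if it reaches the threshold in at
    least one sample.
    """
    lc_of = cluster_map(clusters)
    lc = pd.Series({k: lc_of[k] for k in table.counts.index})
    means = table.counts.groupby(lc).transform("mean")
    below_everywhere = (table.counts < frac * means).all(axis=1)
    keep = table.counts.index[~below_everywhere]
    return JunctionCountTable(table.counts.loc[keep], table.samples.reset_index())


def split_and_prune(
    table: JunctionCountTable, clusters: Sequence[LeafCluster]
) -> tuple[JunctionCountTable, list[LeafCluster]]:
    """Re-split filtered LCs into connected sub-LCs and prune those with < 2 junctions.

    Junction rows of pruned LCs are removed from the table; lc_ids are
    regenerated deterministically from (chrom, strand, leftmost coordinate).
    """
    present = set(table.counts.index)
    surviving: list[str] = []
    for lc in clusters:
        surviving.extend(k for k in lc.junction_keys if k in present)
    refreshed = _make_clusters(surviving)
    kept = [lc for lc in refreshed if len(lc) >= 2]
    kept_keys = [k for lc in kept for k in lc.junction_keys]
    kept_keys = [k for k in table.counts.index if k in set(kept_keys)]
    out = JunctionCountTable(table.counts.loc[kept_keys], table.samples.reset_index())
    # renumber ids on the final set so ordinals are gapless
    final = _make_clusters(out.counts.index)
    return out, [lc for lc in final if len(lc) >= 2]


def refine(
    table: JunctionCountTable,
    min_reads: int = 10,
    min_samples: int = 2,
    frac: float = 0.10,
) -> tuple[JunctionCountTable, list[LeafCluster]]:
    """Full refinement pass: support filter -> cluster -> 10% filter -> split/prune."""
    table = filter_low_support(table, min_reads=min_reads, min_samples=min_samples)
    clusters = build_clusters(table)
    table = filter_relative_abundance(table, clusters, frac=frac)
    return split_and_prune(table, clusters)


def write_cluster_table(
    clusters: Sequence[LeafCluster],
    path,
    gene_of: Mapping[str, str | None] | None = None,
) -> None:
    rows = []
    for lc in clusters:
        gene = gene_of.get(lc.lc_id) if gene_of else None
        for k in lc.junction_keys:
            rows.append({"lc_id": lc.lc_id, "junction": k, "gene_id": gene or "NA"})
    pd.DataFrame(rows, columns=["lc_id", "junction", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_cluster_table(path) -> tuple[list[LeafCluster], dict[str, str | None]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters = []
    gene_of: dict[str, str | None] = {}
    for lc_id, grp in df.groupby("lc_id", sort=False):
        keys = tuple(grp["junction"])
        j0 = Junction.from_key(keys[0])
        clusters.append(LeafCluster(lc_id, keys, j0.chrom, j0.strand))
        gene = grp["gene_id"].iloc[0]
        gene_of[lc_id] = None if gene in ("NA", "", None) or pd.isna(gene) else gene
    return clusters, gene_of
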