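"""Alternative-splicing-type classification of differentially spliced clusters.

Each DS-LC is labelled with any subset of {SE, MXE, A5SS, A3SS, AFE, ALE}
(possibly empty = "unknown") from junction geometry plus the gene annotation:

* SE — an exact triad: an inclusion junction ending at the exon's start-1, an
  inclusion junction starting at the exon's end+1, and a skip junction sharing
  both outer endpoints; at least two of the three must have |dPSI| >= 0.1.
* MXE — two LCs of one gene: the upstream (lower-coordinate) LC has >= 2
  qualifying junctions sharing a start with distinct ends, the downstream one
  >= 2 sharing an end with distinct starts.
* A5SS / A3SS — strand-resolved: donor = start on '+', end on '-'. A5SS needs
  >= 2 qualifying junctions sharing the acceptor, differing in donor, with all
  donor-adjacent positions inside one merged-exon interval; A3SS is the mirror.
* AFE / ALE — a qualifying junction whose flanking exonic position lies inside
  a first-exon (resp. last-exon) interval of the gene.

Classification is a pure function of (geometry, dPSI, annotation); junctions
without |dPSI| >= 0.1 are ignored for all types (for SE the 2-of-3 rule plays
that role).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import GeneModel, Interval, first_last_exons
from .junction_data import Junction

AS_TYPES = ("SE", "MXE", "A5SS", "A3SS", "AFE", "ALE")
DPSI_MIN = 0.1


@dataclass
class ASClassification:
    lc_id: str
    types: frozenset[str]
    evidence: dict[str, list] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return ",".join(sorted(self.types)) if self.types else "unknown"


def _qualifying(junctions: Sequence[Junction], dpsi: Mapping[str, float]) -> list[Junction]:
    out = []
    for j in junctions:
        v = dpsi.get(j.key, np.nan)
        if v is not None and not pd.isna(v) and abs(v) >= DPSI_MIN:
            out.append(j)
    return out


def _in_interval(pos: int, iv: Interval) -> bool:
    return iv[0] <= pos <= iv[1]


def _containing_interval(pos: int, union: Sequence[Interval]) -> Interval | None:
    for iv in union:
        if _in_interval(pos, iv):
            return iv
    return None


def classify_se(
    junctions: Sequence[Junction], dpsi: Mapping[str, float], gene: GeneModel
) -> list | None:
    """Skipped exon: the exact (inclusion, inclusion, skip) triad around an exon."""
    evidence = []
    for s, e in sorted(gene.exons):
        j1s = [j for j in junctions if j.end == s - 1]
        j2s = [j for j in junctions if j.start == e + 1]
        for j1 in j1s:
            for j2 in j2s:
                skips = [j for j in junctions if j.start == j1.start and j.end == j2.end]
                for j0 in skips:
                    n_q = sum(
                        1 for j in (j0, j1, j2)
                        if not pd.isna(dpsi.get(j.key, np.nan))
                        and abs(dpsi[j.key]) >= DPSI_MIN
                    )
                    if n_q >= 2:
                        evidence.append(
                            {"exon": [s, e], "junctions": [j1.key, j2.key, j0.key]}
                        )
    return evidence or None


def classify_mxe(
    lcs: Mapping[str, Sequence[Junction]], dpsi: Mapping[str, float]
) -> dict[str, list] | None:
    """Mutually exclusive exons across ordered pairs of one gene's LCs.

    Returns evidence per participating lc_id, or None. Upstream/downstream is
    by genomic coordinate.
    """
    if len(lcs) < 2:
        return None
    order = sorted(lcs, key=lambda lc: min(j.start for j in lcs[lc]))
    hits: dict[str, list] = {}
    for i, up in enumerate(order):
        for down in order[i + 1:]:
            upq = _qualifying(lcs[up], dpsi)
            downq = _qualifying(lcs[down], dpsi)
            up_ok = None
            for s in {j.start for j in upq}:
                grp = [j for j in upq if j.start == s]
                if len({j.end for j in grp}) >= 2:
                    up_ok = grp
                    break
            down_ok = None
            for e in {j.end for j in downq}:
                grp = [j for j in downq if j.end == e]
                if len({j.start for j in grp}) >= 2:
                    down_ok = grp
                    break
            if up_ok and down_ok:
                ev = {
                    "upstream": [j.key for j in up_ok],
                    "downstream": [j.key for j in down_ok],
                }
                hits.setdefault(up, []).append(ev)
                hits.setdefault(down, []).append(ev)
    return hits or None


def _classify_alt_ss(
    junctions: Sequence[Junction],
    dpsi: Mapping[str, float],
    gene: GeneModel,
    alt_side: str,
) -> list | None:
    """Shared one splice site, distinct on the other, alternates within one exon.

    ``alt_side='donor'`` gives A5SS (junctions exit an exon at different
    points), ``'acceptor'`` gives A3SS. Requires a known strand.
    """
    strand = gene.strand
    if strand not in {"+", "-"}:
        return None
    q = _qualifying(junctions, dpsi)

    def donor(j: Junction) -> int:
        return j.start if strand == "+" else j.end

    def acceptor(j: Junction) -> int:
        return j.end if strand == "+" else j.start

    def adjacent(j: Junction, side: str) -> int:
        coord = donor(j) if side == "donor" else acceptor(j)
        return coord - 1 if coord in (j.start,) else coord + 1

    shared_side = "acceptor" if alt_side == "donor" else "donor"
    shared_of = acceptor if alt_side == "donor" else donor
    alt_of = donor if alt_side == "donor" else acceptor

    evidence = []
    shared_vals = {}
    for j in q:
        shared_vals.setdefault(shared_of(j), []).append(j)
    for sv, grp in sorted(shared_vals.items()):
        if len({alt_of(j) for j in grp}) < 2:
            continue
        # all alternate-side flanking positions must sit in one merged exon
        by_iv: dict[Interval, list[Junction]] = {}
        for j in grp:
            iv = _containing_interval(adjacent(j, alt_side), gene.exon_union)
            if iv is not None:
                by_iv.setdefault(iv, []).append(j)
        for iv, members in sorted(by_iv.items()):
            if len({alt_of(j) for j in members}) >= 2:
                evidence.append(
                    {"exon": list(iv), "junctions": sorted(j.key for j in members)}
                )
    return evidence or None


def classify_a5ss(junctions, dpsi, gene: GeneModel):
    return _classify_alt_ss(junctions, dpsi, gene, alt_side="donor")


def classify_a3ss(junctions, dpsi, gene: GeneModel):
    return _classify_alt_ss(junctions, dpsi, gene, alt_side="acceptor")


def classify_afe_ale(
    junctions: Sequence[Junction], dpsi: Mapping[str, float], gene: GeneModel
) -> tuple[list | None, list | None]:
    """(AFE evidence, ALE evidence): qualifying junctions touching first/last exons."""
    first, last = first_last_exons(gene)
    afe, ale = [], []
    for j in _qualifying(junctions, dpsi):
        for pos in (j.upstream_exonic, j.downstream_exonic):
            for iv in first:
                if _in_interval(pos, iv):
                    afe.append({"exon": list(iv), "junction": j.key})
            for iv in last:
                if _in_interval(pos, iv):
                    ale.append({"exon": list(iv), "junction": j.key})
    return (afe or None), (ale or None)


def classify_all(
    lc_junctions: Mapping[str, Sequence[Junction | str]],
    dpsi: Mapping[str, float],
    gene_of: Mapping[str, str | None],
    genes: Mapping[str, GeneModel],
) -> dict[str, ASClassification]:
    """Classify every LC; the union of per-type calls, empty set = unknown."""
    parsed: dict[str, list[Junction]] = {
        lc: [j if isinstance(j, Junction) else Junction.from_key(j) for j in js]
        for lc, js in lc_junctions.items()
    }
    out: dict[str, ASClassification] = {}
    by_gene: dict[str, dict[str, list[Junction]]] = {}
    for lc, js in parsed.items():
        g = gene_of.get(lc)
        if g is not None:
            by_gene.setdefault(g, {})[lc] = js

    mxe_hits: dict[str, list] = {}
    for g, lcs in by_gene.items():
        hits = classify_mxe(lcs, dpsi)
        if hits:
            mxe_hits.update(hits)

    for lc, js in parsed.items():
        types: set[str] = set()
        evidence: dict[str, list] = {}
        g = gene_of.get(lc)
        gene = genes.get(g) if g is not None else None
        if gene is not None:
            se = classify_se(js, dpsi, gene)
            if se:
                types.add("SE")
                evidence["SE"] = se
            a5 = classify_a5ss(js, dpsi, gene)
            if a5:
                types.add("A5SS")
                evidence["A5SS"] = a5
            a3 = classify_a3ss(js, dpsi, gene)
            if a3:
                types.add("A3SS")
                evidence["A3SS"] = a3
            afe, ale = classify_afe_ale(js, dpsi, gene)
            if afe:
                types.add("AFE")
                evidence["AFE"] = afe
            if ale:
                types.add("ALE")
                evidence["ALE"] = ale
        if lc in mxe_hits:
            types.add("MXE")
            evidence["MXE"] = mxe_hits[lc]
        out[lc] = ASClassification(lc, frozenset(types), evidence)
    return out
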