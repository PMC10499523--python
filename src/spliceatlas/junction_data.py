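"""Junction identity, junction-by-sample count tables, sample metadata and PSI.

A splice junction is an intron interval identified by ``chrom:start:end:strand``
with ``start``/``end`` the first and last intronic bases, 1-based inclusive.
On-disk ``.junc`` files use the BED dialect (0-based half-open over the intron);
:func:`read_junc_files` converts on the way in. Strand ``.`` means unknown and
is part of the identity: the same interval on opposite strands is two junctions.

PSI (percent spliced in) of a junction in one sample is its junction-spanning
read (JSR) count divided by the total JSR count of its cluster in that sample.
When the cluster total is 0 the PSI is *undefined* and stored as NaN — never 0,
so zero-coverage samples cannot drag group means toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, MetadataError, ParseError

SAMPLE_SHEET_COLUMNS = ["sample_id", "dataset", "cell_type", "condition", "donor"]


@dataclass(frozen=True, order=True)
class Junction:
    """One splice junction: an intron interval with genomic identity."""

    chrom: str
    start: int  # first intronic base, 1-based
    end: int    # last intronic base, 1-based
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContractError(f"junction start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ContractError(f"invalid strand {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}:{self.end}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "Junction":
        chrom, start, end, strand = key.rsplit(":", 3)
        return cls(chrom, int(start), int(end), strand)

    # Positions immediately outside the intron; the AS classifier anchors on
    # these because they are the exonic bases the junction "connects".
    @property
    def upstream_exonic(self) -> int:
        return self.start - 1

    @property
    def downstream_exonic(self) -> int:
        return self.end + 1


def junction_key(chrom: str, start: int, end: int, strand: str = ".") -> str:
    return f"{chrom}:{start}:{end}:{strand}"


def parse_junction_key(key: str) -> Junction:
    return Junction.from_key(key)


@dataclass
class JunctionCountTable:
    """Junction-by-sample matrix of non-negative integer JSR counts.

    ``counts`` is a DataFrame indexed by junction key with one column per
    sample_id; ``samples`` is the sample sheet indexed by sample_id.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.copy()
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise MetadataError(f"samples missing from sheet: {missing}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)) or np.any(vals < 0):
                raise ContractError("counts must be non-negative integers")
            self.counts = self.counts.round().astype(np.int64)

    @property
    def junction_keys(self) -> list[str]:
        return list(self.counts.index)

    @property
    def junctions(self) -> pd.DataFrame:
        """Junction identity parsed out of the index (chrom/start/end/strand)."""
        recs = [Junction.from_key(k) for k in self.counts.index]
        return pd.DataFrame(
            {
                "chrom": [j.chrom for j in recs],
                "start": [j.start for j in recs],
                "end": [j.end for j in recs],
                "strand": [j.strand for j in recs],
            },
            index=self.counts.index,
        )

    def subset_junctions(self, keys: Sequence[str]) -> "JunctionCountTable":
        keep = [k for k in self.counts.index if k in set(keys)]
        return JunctionCountTable(self.counts.loc[keep], self.samples.reset_index())

    def subset_samples(self, sample_ids: Sequence[str]) -> "JunctionCountTable":
        return JunctionCountTable(
            self.counts[list(sample_ids)], self.samples.loc[list(sample_ids)].reset_index()
        )


@dataclass
class PSIMatrix:
    """Per-sample junction usage fractions within each cluster (NaN = undefined)."""

    psi: pd.DataFrame
    samples: pd.DataFrame
    cluster_of: pd.Series  # junction key -> LC id

    def __post_init__(self) -> None:
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet {path} missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample_id in sheet: {dup}")
    return sheet


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.reset_index() if samples.index.name == "sample_id" else samples
    out.to_csv(path, sep="\t", index=False)


def _parse_junc_line(line: str, path: str, lineno: int) -> tuple[str, int, str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        fields = line.split()
    if len(fields) < 6:
        raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
    chrom, start0, end0, _name, count, strand = fields[:6]
    try:
        start0_i, end0_i, count_i = int(start0), int(end0), int(count)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate or count") from exc
    if count_i < 0:
        raise ParseError(f"{path}:{lineno}: negative count {count_i}")
    if strand not in {"+", "-", "."}:
        raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
    if end0_i <= start0_i:
        raise ParseError(f"{path}:{lineno}: empty or inverted interval")
    # BED half-open 0-based intron [start0, end0) -> 1-based inclusive
    key = junction_key(chrom, start0_i + 1, end0_i, strand)
    return key, count_i, strand


def read_junc_files(
    paths: Mapping[str, str | Path] | Iterable[str | Path],
    sample_sheet: pd.DataFrame,
) -> JunctionCountTable:
    """Read per-sample .junc files into one table, union of junctions, 0-filled.

    ``paths`` maps sample_id -> file; a plain iterable of paths uses each file's
    stem as its sample_id. Every sample must appear in ``sample_sheet``.
    """
    if not isinstance(paths, Mapping):
        paths = {Path(p).stem: p for p in paths}
    sheet = sample_sheet.copy()
    if "sample_id" not in sheet.columns:
        sheet = sheet.reset_index()
    known = set(sheet["sample_id"])
    per_sample: dict[str, dict[str, int]] = {}
    for sample_id, path in paths.items():
        if sample_id not in known:
            raise MetadataError(f"sample {sample_id!r} not in sample sheet")
        cnts: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                key, count, _ = _parse_junc_line(line, str(path), lineno)
                cnts[key] = cnts.get(key, 0) + count
        per_sample[sample_id] = cnts
    all_keys = sorted(
        {k for cnts in per_sample.values() for k in cnts},
        key=lambda k: (Junction.from_key(k).chrom, Junction.from_key(k).start,
                       Junction.from_key(k).end, Junction.from_key(k).strand),
    )
    mat = pd.DataFrame(
        {sid: [per_sample[sid].get(k, 0) for k in all_keys] for sid in paths},
        index=pd.Index(all_keys, name="junction"),
        dtype=np.int64,
    )
    keep = sheet[sheet["sample_id"].isin(paths)].set_index("sample_id")
    return JunctionCountTable(mat, keep.reset_index())


def compute_psi(table: JunctionCountTable, clusters: Mapping[str, str]) -> PSIMatrix:
    """PSI[j, s] = counts[j, s] / total counts of j's cluster in sample s.

    Undefined (NaN) exactly where the cluster total is 0. Raises
    :class:`ContractError` if any junction lacks a cluster assignment.
    """
    missing = [k for k in table.counts.index if k not in clusters]
    if missing:
        raise ContractError(f"junctions without cluster assignment: {missing[:5]}")
    lc = pd.Series({k: clusters[k] for k in table.counts.index}, name="lc_id")
    totals = table.counts.groupby(lc).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = table.counts / totals.where(totals > 0)
    return PSIMatrix(psi.astype(float), table.samples.reset_index(), lc)


def write_count_table(table: JunctionCountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="junction")


def read_count_table(path: str | Path, sample_sheet: pd.DataFrame) -> JunctionCountTable:
    counts = pd.read_csv(path, sep="\t", index_col="junction").astype(np.int64)
    return JunctionCountTable(counts, sample_sheet)


def write_psi(psi: PSIMatrix, path: str | Path) -> None:
    out = psi.psi.copy()
    out.insert(0, "lc_id", psi.cluster_of)
    out.to_csv(path, sep="\t", index_label="junction", na_rep="NA")


def read_psi(path: str | Path, sample_sheet: pd.DataFrame) -> PSIMatrix:
    raw = pd.read_csv(path, sep="\t", index_col="junction", na_values="NA")
    cluster_of = raw.pop("lc_id").astype(str)
    return PSIMatrix(raw.astype(float), sample_sheet, cluster_of)
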