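"""Regulator (splicing factor / transcription factor) inference by correlation.

Candidate regulators come from user-supplied GO membership lists (RNA splicing,
GO:0008380, for SFs; mRNA transcription, GO:0009299, for TFs). A regulator is
kept when it is expressed (>= 10 raw reads in >= 1 sample in >= 2 datasets)
and differentially expressed between cell types (one-way ANOVA on
reads-per-million, p <= 0.05). Its expression pattern is then correlated
(Pearson, across samples) with junction PSI patterns: non-AFE junctions for
SFs, AFE junctions for TFs, restricted to DS junctions shared by >= 2 datasets
with max |dPSI| >= 0.2.

Pattern clustering follows the conventions of the analysis: junction PSI
profiles with standardized-Euclidean distance and complete linkage, regulator
expression profiles with correlation distance and average linkage, each tree
cut to 10 flat clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway, pearsonr

from .errors import ContractError

MIN_DEFINED_FOR_CORR = 3


@dataclass
class ExpressionTable:
    """Gene-by-sample raw counts with reads-per-million normalization."""

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def normalized(self) -> pd.DataFrame:
        depth = self.counts.sum(axis=0)
        return self.counts / depth.where(depth > 0) * 1e6


def read_expression(path: str | Path, samples: pd.DataFrame) -> ExpressionTable:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionTable(counts, samples)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    expr.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class RegulatorSet:
    role: str  # "SF" | "TF"
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.role not in {"SF", "TF"}:
            raise ContractError(f"role must be SF or TF, got {self.role!r}")
        if not self.gene_ids:
            raise ContractError("regulator set is empty")

    @classmethod
    def from_file(cls, role: str, path: str | Path) -> "RegulatorSet":
        ids = frozenset(
            line.strip() for line in open(path) if line.strip() and not line.startswith("#")
        )
        return cls(role, ids)


@dataclass
class RegulatorCorrelation:
    role: str
    r: pd.DataFrame  # regulator x junction Pearson r, NaN = undefined
    regulator_clusters: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    junction_clusters: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def filter_regulators(
    expr_by_dataset: Mapping[str, ExpressionTable],
    regulator_set: RegulatorSet,
    focal_dataset: str,
    min_reads: int = 10,
    min_datasets: int = 2,
    anova_alpha: float = 0.05,
) -> list[str]:
    """Expressed-in->=2-datasets plus ANOVA-differential regulators for one dataset."""
    if len(expr_by_dataset) < min_datasets:
        raise ContractError("need at least two datasets for the expression criterion")
    focal = expr_by_dataset[focal_dataset]
    cell_types = focal.samples["cell_type"]
    if cell_types.nunique() < 2:
        raise ContractError("ANOVA needs at least two cell types")
    kept = []
    norm = focal.normalized
    for gene in sorted(regulator_set.gene_ids):
        n_expressed = sum(
            1
            for expr in expr_by_dataset.values()
            if gene in expr.counts.index and (expr.counts.loc[gene] >= min_reads).any()
        )
        if n_expressed < min_datasets or gene not in norm.index:
            continue
        groups = [
            norm.loc[gene, cell_types.index[cell_types == ct]].to_numpy()
            for ct in cell_types.unique()
        ]
        if any(len(g) < 2 for g in groups):
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = f_oneway(*groups)
        if np.isfinite(p) and p <= anova_alpha:
            kept.append(gene)
    return kept


def select_junctions(
    max_dpsi_by_dataset: Mapping[str, pd.Series],
    afe_junctions_by_dataset: Mapping[str, set[str]],
    focal_dataset: str,
    role: str,
    min_shared_datasets: int = 2,
    min_dpsi: float = 0.2,
) -> list[str]:
    """DS junctions usable for regulator correlation in one dataset.

    ``max_dpsi_by_dataset`` maps dataset -> per-junction max |dPSI| over its
    DS-LCs; ``afe_junctions_by_dataset`` lists junctions in AFE-classified
    LCs. SF analysis excludes AFE junctions; TF analysis keeps only them.
    """
    focal = max_dpsi_by_dataset[focal_dataset]
    afe = afe_junctions_by_dataset.get(focal_dataset, set())
    out = []
    for key, md in focal.items():
        if pd.isna(md) or md < min_dpsi:
            continue
        n_ds = sum(1 for d, s in max_dpsi_by_dataset.items() if key in s.index)
        if n_ds < min_shared_datasets:
            continue
        is_afe = key in afe
        if (role == "SF" and not is_afe) or (role == "TF" and is_afe):
            out.append(key)
    return sorted(out)


def correlate(
    expr: ExpressionTable,
    psi: pd.DataFrame,
    regulators: Sequence[str],
    junctions: Sequence[str],
    role: str = "SF",
) -> RegulatorCorrelation:
    """Pearson r between regulator expression and junction PSI across samples.

    Samples with undefined PSI are dropped pairwise; correlations with a
    zero-variance vector or < 3 defined pairs are NaN (never imputed as 0).
    """
    shared = [s for s in expr.counts.columns if s in psi.columns]
    norm = expr.normalized[shared]
    pmat = psi[shared]
    r = pd.DataFrame(np.nan, index=list(regulators), columns=list(junctions))
    for g in regulators:
        if g not in norm.index:
            continue
        ev = norm.loc[g].to_numpy(dtype=float)
        for j in junctions:
            if j not in pmat.index:
                continue
            pv = pmat.loc[j].to_numpy(dtype=float)
            ok = np.isfinite(pv) & np.isfinite(ev)
            if ok.sum() < MIN_DEFINED_FOR_CORR:
                continue
            x, y = ev[ok], pv[ok]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r.loc[g, j] = float(pearsonr(x, y)[0])
    return RegulatorCorrelation(role=role, r=r)


def _cut(z: np.ndarray, n_items: int, n_clusters: int) -> np.ndarray:
    k = min(n_clusters, n_items)
    if k < n_clusters:
        warnings.warn(f"only {n_items} items; lowering cluster count to {k}")
    return fcluster(z, t=k, criterion="maxclust")


def cluster_patterns(
    correlation: RegulatorCorrelation,
    psi: pd.DataFrame,
    expr: ExpressionTable,
    n_clusters: int = 10,
) -> RegulatorCorrelation:
    """Cut hierarchical trees over junction PSI and regulator expression profiles.

    Junctions: standardized-Euclidean distance, complete linkage. Regulators:
    correlation distance, average linkage. Undefined PSI entries are filled
    with the junction's own mean before computing distances.
    """
    junctions = [j for j in correlation.r.columns if j in psi.index]
    regulators = [g for g in correlation.r.index if g in expr.counts.index]
    if junctions:
        jmat = psi.loc[junctions]
        jmat = jmat.apply(lambda row: row.fillna(row.mean()), axis=1).to_numpy(float)
        if len(junctions) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = pdist(jmat, metric="seuclidean")
            d = np.nan_to_num(d)
            labels = _cut(linkage(d, method="complete"), len(junctions), n_clusters)
        else:
            labels = np.array([1])
        correlation.junction_clusters = pd.Series(labels, index=junctions, dtype=int)
    if regulators:
        emat = expr.normalized.loc[regulators].to_numpy(float)
        if len(regulators) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = pdist(emat, metric="correlation")
            d = np.nan_to_num(d)
            labels = _cut(linkage(d, method="average"), len(regulators), n_clusters)
        else:
            labels = np.array([1])
        correlation.regulator_clusters = pd.Series(labels, index=regulators, dtype=int)
    return correlation


def cross_dataset_regulator_correlation(
    expr_a: ExpressionTable,
    expr_b: ExpressionTable,
    regulators: Iterable[str],
    r_cutoff: float = 0.7,
) -> tuple[pd.Series, float]:
    """Correlate per-cell-type mean expression of each regulator across two datasets.

    Cell types are harmonized (CD4/CD8 averaged into T) into five means per
    dataset; the summary is the percentage of shared regulators with r above
    ``r_cutoff``. Regulators absent or constant in a dataset are skipped.
    """
    from .ds_test import harmonize_cell_type

    def cell_means(expr: ExpressionTable) -> pd.DataFrame:
        ct = expr.samples["cell_type"].map(harmonize_cell_type)
        return expr.normalized.T.groupby(ct.values).mean().T

    ma, mb = cell_means(expr_a), cell_means(expr_b)
    shared_ct = [c for c in ma.columns if c in mb.columns]
    out = {}
    for g in regulators:
        if g not in ma.index or g not in mb.index:
            continue
        x = ma.loc[g, shared_ct].to_numpy(float)
        y = mb.loc[g, shared_ct].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0 or len(shared_ct) < 3:
            continue
        out[g] = float(pearsonr(x, y)[0])
    rs = pd.Series(out, dtype=float)
    frac = float((rs > r_cutoff).mean() * 100) if len(rs) else float("nan")
    return rs, frac


def correlation_of_correlations(corr_a: pd.DataFrame, corr_b: pd.DataFrame) -> float:
    """Pearson r between two regulator-by-junction correlation matrices.

    Restricted to shared regulator x junction pairs defined in both; NaN when
    fewer than 3 such pairs exist.
    """
    regs = [g for g in corr_a.index if g in corr_b.index]
    juncs = [j for j in corr_a.columns if j in corr_b.columns]
    a = corr_a.loc[regs, juncs].to_numpy(float).ravel()
    b = corr_b.loc[regs, juncs].to_numpy(float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        return float("nan")
    return float(pearsonr(a[ok], b[ok])[0])
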