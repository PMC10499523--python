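"""Stage orchestration: simulate -> cluster -> test -> classify -> regulate -> compare.

Each stage reads and writes plain TSV/JSON under a working directory, so any
stage can be re-run in isolation and every artifact is inspectable. The
configuration (all thresholds at their published defaults) is serialized as
``config.json`` into the working directory on every run, together with a hash,
so outputs are self-describing.

Layout under ``workdir``::

    input/        annotation.gff3, samples.tsv, counts/<ds>.tsv,
                  expression/<ds>.tsv, regulators_{sf,tf}.txt, truth.json
    clusters/     <ds>_counts.tsv, <ds>_clusters.tsv, <ds>_psi.tsv
    ds/           <ds>_tests.tsv, <ds>_dpsi.tsv, <ds>_calls.tsv
                  [<ds>_condition_tests.tsv ... for condition contrasts]
    classify/     <ds>_astypes.tsv
    regulation/   <ds>_{sf,tf}_corr.tsv, <ds>_{sf,tf}_clusters.tsv, summary.tsv
    compare/      concordance.tsv
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation_model, as_classify, cluster_filter, cross_dataset
from . import ds_test as dst
from . import regulation_inference as reg
from .errors import ContractError
from .junction_data import (
    compute_psi,
    read_count_table,
    read_psi,
    read_sample_sheet,
    write_count_table,
    write_psi,
)
from .simulate import RegulatorConfig, SimulationConfig, simulate, write_world

log = logging.getLogger("spliceatlas")

SUBCOMMANDS = ("simulate", "cluster", "test", "classify", "regulate", "compare", "all")


@dataclass
class PipelineConfig:
    workdir: str = "spliceatlas_run"
    seed: int = 0
    # published analysis defaults
    alpha: float = 0.05
    dpsi_low: float = 0.1
    dpsi_high: float = 0.2
    min_reads: int = 10
    min_samples: int = 2
    corr_min_dpsi: float = 0.2
    anova_alpha: float = 0.05
    r_report_cutoff: float = 0.7
    n_clusters: int = 10
    # synthetic-world knobs (defaults are the stated world)
    n_datasets: int = 4
    n_lcs: int = 100
    frac_ds: float = 0.25
    delta: float = 0.3
    concentration: float = 30.0
    depth_mean: float = 80.0
    depth_dispersion: float = 0.3
    conditions: tuple = ("healthy",)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data["conditions"] = tuple(data.get("conditions", ("healthy",)))
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _write_config(cfg: PipelineConfig) -> None:
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    (wd / "config.json").write_text(cfg.to_json())
    log.info("config hash %s written to %s", cfg.config_hash, wd / "config.json")


# --------------------------------------------------------------------------
# result (de)serialization
# --------------------------------------------------------------------------

def results_to_frames(
    results: dict[str, dst.ClusterTestResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    trows, drows = [], []
    for lc_id, r in sorted(results.items()):
        trows.append(
            {
                "lc_id": lc_id, "comparison": "multi",
                "p": r.p_multi, "p_adj": r.p_multi_adj,
                "eligible": r.multi_eligible, "selected": r.selected,
            }
        )
        for (a, b), pr in sorted(r.pairwise.items()):
            cmp_name = f"{a}|{b}"
            trows.append(
                {
                    "lc_id": lc_id, "comparison": cmp_name,
                    "p": pr.p, "p_adj": pr.p_adj,
                    "eligible": pr.eligible, "selected": r.selected,
                }
            )
            for key, v in pr.dpsi.items():
                drows.append(
                    {"lc_id": lc_id, "comparison": cmp_name, "junction": key, "dpsi": v}
                )
    cols = ["lc_id", "comparison", "p", "p_adj", "eligible", "selected"]
    tests = pd.DataFrame(trows, columns=cols).astype({"p": float, "p_adj": float})
    dpsi = pd.DataFrame(
        drows, columns=["lc_id", "comparison", "junction", "dpsi"]
    ).astype({"dpsi": float})
    return tests, dpsi


def frames_to_results(
    tests: pd.DataFrame, dpsi: pd.DataFrame
) -> dict[str, dst.ClusterTestResult]:
    results: dict[str, dst.ClusterTestResult] = {}
    dpsi_by = {
        (lc, cmp): grp.set_index("junction")["dpsi"]
        for (lc, cmp), grp in dpsi.groupby(["lc_id", "comparison"])
    }
    for lc_id, grp in tests.groupby("lc_id"):
        junctions: list[str] = []
        res = dst.ClusterTestResult(lc_id=lc_id, junction_keys=())
        for _, row in grp.iterrows():
            p = None if pd.isna(row["p"]) else float(row["p"])
            p_adj = None if pd.isna(row["p_adj"]) else float(row["p_adj"])
            if row["comparison"] == "multi":
                res.p_multi, res.p_multi_adj = p, p_adj
                res.multi_eligible = bool(row["eligible"])
                res.selected = bool(row["selected"])
            else:
                a, b = row["comparison"].split("|")
                dp = dpsi_by.get((lc_id, row["comparison"]), pd.Series(dtype=float))
                junctions = list(dp.index) or junctions
                res.pairwise[(a, b)] = dst.PairwiseResult(
                    a, b, p, p_adj, dp, bool(row["eligible"])
                )
        res.junction_keys = tuple(junctions)
        results[lc_id] = res
    return results


def calls_to_frame(
    calls: dict[str, dst.DSCall], patterns: dict[str, str] | None = None
) -> pd.DataFrame:
    rows = []
    for lc_id, call in sorted(calls.items()):
        for key, md in call.max_dpsi.items():
            rows.append(
                {
                    "lc_id": lc_id,
                    "gene_id": call.gene_id or "NA",
                    "junction": key,
                    "max_dpsi": md,
                    "is_ds": call.is_ds,
                    "pattern": (patterns or {}).get(lc_id, call.pattern),
                    "as_types": ",".join(sorted(call.as_types)) or "unknown",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["lc_id", "gene_id", "junction", "max_dpsi", "is_ds", "pattern", "as_types"],
    )


def frame_to_calls(df: pd.DataFrame) -> dict[str, dst.DSCall]:
    calls = {}
    for lc_id, grp in df.groupby("lc_id"):
        first = grp.iloc[0]
        types = first["as_types"]
        calls[lc_id] = dst.DSCall(
            lc_id=lc_id,
            gene_id=None if first["gene_id"] == "NA" else first["gene_id"],
            max_dpsi=grp.set_index("junction")["max_dpsi"].astype(float),
            is_ds=bool(first["is_ds"]),
            pattern=str(first["pattern"]),
            as_types=frozenset() if types == "unknown" else frozenset(str(types).split(",")),
        )
    return calls


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _datasets(cfg: PipelineConfig) -> list[str]:
    return sorted(p.stem for p in (Path(cfg.workdir) / "input" / "counts").glob("*.tsv"))


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = SimulationConfig(
        seed=cfg.seed,
        n_datasets=cfg.n_datasets,
        n_lcs=cfg.n_lcs,
        frac_ds=cfg.frac_ds,
        delta=cfg.delta,
        concentration=cfg.concentration,
        depth_mean=cfg.depth_mean,
        depth_dispersion=cfg.depth_dispersion,
        conditions=tuple(cfg.conditions),
    )
    world = simulate(sim)
    write_world(world, Path(cfg.workdir) / "input")
    log.info(
        "simulated %d datasets, %d junctions",
        len(world.tables),
        len(world.tables[next(iter(world.tables))].counts),
    )


def _load_inputs(cfg: PipelineConfig):
    indir = Path(cfg.workdir) / "input"
    if not indir.exists():
        raise ContractError(
            f"missing input directory {indir}; run the simulate stage or place inputs there"
        )
    sheet = read_sample_sheet(indir / "samples.tsv")
    tables = {
        ds: read_count_table(indir / "counts" / f"{ds}.tsv",
                             sheet[sheet.dataset == ds].copy())
        for ds in sorted(p.stem for p in (indir / "counts").glob("*.tsv"))
    }
    return sheet, tables


def stage_cluster(cfg: PipelineConfig) -> None:
    sheet, tables = _load_inputs(cfg)
    outdir = Path(cfg.workdir) / "clusters"
    outdir.mkdir(parents=True, exist_ok=True)
    gff = Path(cfg.workdir) / "input" / "annotation.gff3"
    genes = annotation_model.parse_gff3(gff) if gff.exists() else []
    for ds, table in tables.items():
        refined, clusters = cluster_filter.refine(
            table, min_reads=cfg.min_reads, min_samples=cfg.min_samples
        )
        cmap = cluster_filter.cluster_map(clusters)
        gene_of_j = annotation_model.assign_junctions_to_genes(refined.counts.index, genes)
        gene_of_lc = annotation_model.assign_clusters_to_genes(cmap, gene_of_j)
        write_count_table(refined, outdir / f"{ds}_counts.tsv")
        cluster_filter.write_cluster_table(clusters, outdir / f"{ds}_clusters.tsv", gene_of_lc)
        psi = compute_psi(refined, cmap)
        write_psi(psi, outdir / f"{ds}_psi.tsv")
        log.info("%s: %d junctions in %d clusters after refinement",
                 ds, len(refined.counts), len(clusters))


def _load_clustered(cfg: PipelineConfig, ds: str):
    cdir = Path(cfg.workdir) / "clusters"
    sheet = read_sample_sheet(Path(cfg.workdir) / "input" / "samples.tsv")
    sub = sheet[sheet.dataset == ds].copy()
    counts = read_count_table(cdir / f"{ds}_counts.tsv", sub)
    clusters, gene_of = cluster_filter.read_cluster_table(cdir / f"{ds}_clusters.tsv")
    psi = read_psi(cdir / f"{ds}_psi.tsv", sub.set_index("sample_id"))
    return counts, clusters, gene_of, psi


def stage_test(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.workdir) / "ds"
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in _datasets(cfg):
        counts, clusters, gene_of, psi = _load_clustered(cfg, ds)
        cmap = cluster_filter.cluster_map(clusters)
        healthy = counts.samples[counts.samples.condition == "healthy"].index
        group_of = counts.samples["cell_type"].to_dict()
        sub = counts.counts[list(healthy)]
        if sub.empty or len(sub.columns) == 0:
            log.warning("%s: nothing to test (no junctions or no healthy samples); "
                        "writing empty results", ds)
        results = dst.run_ds_analysis(
            sub, cmap, psi, group_of,
            alpha=cfg.alpha, analysis="healthy", min_reads=cfg.min_reads,
        )
        calls, patterns = {}, {}
        for lc_id, r in results.items():
            call = dst.call_ds(
                r, gene_id=gene_of.get(lc_id), analysis="healthy",
                alpha=cfg.alpha, dpsi_low=cfg.dpsi_low, dpsi_high=cfg.dpsi_high,
            )
            if call.is_ds:
                call.pattern = dst.classify_pattern(r, alpha=cfg.alpha)
            calls[lc_id] = call
            patterns[lc_id] = call.pattern
        tests, dpsi = results_to_frames(results)
        tests.to_csv(outdir / f"{ds}_tests.tsv", sep="\t", index=False)
        dpsi.to_csv(outdir / f"{ds}_dpsi.tsv", sep="\t", index=False)
        calls_to_frame(calls, patterns).to_csv(outdir / f"{ds}_calls.tsv", sep="\t", index=False)
        n_ds = sum(c.is_ds for c in calls.values())
        log.info("%s: %d/%d LCs called DS", ds, n_ds, len(calls))
        _condition_contrasts(cfg, ds, counts, cmap, psi, gene_of, outdir)


def _condition_contrasts(cfg, ds, counts, cmap, psi, gene_of, outdir) -> None:
    samples = counts.samples
    conditions = [c for c in samples.condition.unique() if c != "healthy"]
    if not conditions:
        return
    rows_tests, rows_dpsi, rows_calls = [], [], []
    for condition in conditions:
        for ct in samples.cell_type.unique():
            sel = samples[
                (samples.cell_type == ct) & samples.condition.isin(["healthy", condition])
            ]
            if (sel.condition == "healthy").sum() < 2 or (sel.condition == condition).sum() < 2:
                continue  # mirrors excluding cell types with < 2 replicates
            sub = counts.counts[list(sel.index)]
            group_of = sel["condition"].to_dict()
            results = dst.run_ds_analysis(
                sub, cmap, psi, group_of,
                alpha=cfg.alpha, analysis="condition", min_reads=cfg.min_reads,
            )
            for lc_id, r in results.items():
                call = dst.call_ds(
                    r, gene_id=gene_of.get(lc_id), analysis="condition",
                    alpha=cfg.alpha, dpsi_low=cfg.dpsi_low, dpsi_high=cfg.dpsi_high,
                )
                t, d = results_to_frames({lc_id: r})
                t.insert(0, "cell_type", ct)
                t.insert(0, "condition", condition)
                rows_tests.append(t)
                rows_dpsi.append(d)
                for key, md in call.max_dpsi.items():
                    rows_calls.append(
                        {
                            "condition": condition, "cell_type": ct, "lc_id": lc_id,
                            "gene_id": call.gene_id or "NA", "junction": key,
                            "max_dpsi": md, "is_ds": call.is_ds,
                        }
                    )
    if rows_tests:
        rows_dpsi = [d for d in rows_dpsi if not d.empty]
        pd.concat(rows_tests).to_csv(outdir / f"{ds}_condition_tests.tsv", sep="\t", index=False)
        pd.concat(rows_dpsi).to_csv(outdir / f"{ds}_condition_dpsi.tsv", sep="\t", index=False)
        pd.DataFrame(rows_calls).to_csv(outdir / f"{ds}_condition_calls.tsv", sep="\t", index=False)


def stage_classify(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.workdir) / "classify"
    outdir.mkdir(parents=True, exist_ok=True)
    gff = Path(cfg.workdir) / "input" / "annotation.gff3"
    genes = {g.gene_id: g for g in (annotation_model.parse_gff3(gff) if gff.exists() else [])}
    for ds in _datasets(cfg):
        dsdir = Path(cfg.workdir) / "ds"
        calls = frame_to_calls(pd.read_csv(dsdir / f"{ds}_calls.tsv", sep="\t"))
        clusters, gene_of = cluster_filter.read_cluster_table(
            Path(cfg.workdir) / "clusters" / f"{ds}_clusters.tsv"
        )
        lc_junctions = {lc.lc_id: list(lc.junction_keys) for lc in clusters
                        if calls.get(lc.lc_id) and calls[lc.lc_id].is_ds}
        dpsi = {
            key: float(md)
            for call in calls.values() if call.is_ds
            for key, md in call.max_dpsi.items()
        }
        classes = as_classify.classify_all(lc_junctions, dpsi, gene_of, genes)
        rows = []
        for lc_id, cl in sorted(classes.items()):
            calls[lc_id].as_types = cl.types
            rows.append(
                {
                    "lc_id": lc_id,
                    "gene_id": gene_of.get(lc_id) or "NA",
                    "types": cl.label,
                    "evidence": json.dumps(cl.evidence, sort_keys=True),
                }
            )
        pd.DataFrame(rows, columns=["lc_id", "gene_id", "types", "evidence"]).to_csv(
            outdir / f"{ds}_astypes.tsv", sep="\t", index=False
        )
        # refresh the call table with AS types
        patterns = {lc: c.pattern for lc, c in calls.items()}
        calls_to_frame(calls, patterns).to_csv(
            dsdir / f"{ds}_calls.tsv", sep="\t", index=False
        )
        log.info("%s: %d DS-LCs classified", ds, len(classes))


def _max_dpsi_series(calls: dict[str, dst.DSCall]) -> pd.Series:
    parts = [c.max_dpsi for c in calls.values() if c.is_ds]
    return pd.concat(parts) if parts else pd.Series(dtype=float)


def stage_regulate(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.workdir) / "regulation"
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(cfg.workdir) / "input"
    sheet = read_sample_sheet(indir / "samples.tsv")
    datasets = _datasets(cfg)
    expr_by_ds = {
        ds: reg.read_expression(
            indir / "expression" / f"{ds}.tsv",
            sheet[sheet.dataset == ds].copy(),
        )
        for ds in datasets
    }
    sets = {
        "SF": reg.RegulatorSet.from_file("SF", indir / "regulators_sf.txt"),
        "TF": reg.RegulatorSet.from_file("TF", indir / "regulators_tf.txt"),
    }
    calls_by_ds = {
        ds: frame_to_calls(pd.read_csv(Path(cfg.workdir) / "ds" / f"{ds}_calls.tsv", sep="\t"))
        for ds in datasets
    }
    md_by_ds = {ds: _max_dpsi_series(calls) for ds, calls in calls_by_ds.items()}
    afe_by_ds = {
        ds: {
            key
            for call in calls.values()
            if call.is_ds and "AFE" in call.as_types
            for key in call.max_dpsi.index
        }
        for ds, calls in calls_by_ds.items()
    }
    psi_by_ds = {
        ds: read_psi(
            Path(cfg.workdir) / "clusters" / f"{ds}_psi.tsv",
            sheet[sheet.dataset == ds].set_index("sample_id"),
        ).psi
        for ds in datasets
    }
    corr: dict[tuple[str, str], reg.RegulatorCorrelation] = {}
    kept_regs: dict[tuple[str, str], list[str]] = {}
    for ds in datasets:
        for role in ("SF", "TF"):
            regulators = reg.filter_regulators(
                expr_by_ds, sets[role], ds,
                min_reads=cfg.min_reads, anova_alpha=cfg.anova_alpha,
            )
            junctions = reg.select_junctions(
                md_by_ds, afe_by_ds, ds, role, min_dpsi=cfg.corr_min_dpsi
            )
            kept_regs[(ds, role)] = regulators
            rc = reg.correlate(expr_by_ds[ds], psi_by_ds[ds], regulators, junctions, role)
            rc = reg.cluster_patterns(rc, psi_by_ds[ds], expr_by_ds[ds], cfg.n_clusters)
            corr[(ds, role)] = rc
            rc.r.to_csv(outdir / f"{ds}_{role.lower()}_corr.tsv",
                        sep="\t", index_label="regulator", na_rep="NA")
            pd.DataFrame(
                {
                    "item": list(rc.regulator_clusters.index) + list(rc.junction_clusters.index),
                    "kind": ["regulator"] * len(rc.regulator_clusters)
                    + ["junction"] * len(rc.junction_clusters),
                    "cluster": list(rc.regulator_clusters) + list(rc.junction_clusters),
                }
            ).to_csv(outdir / f"{ds}_{role.lower()}_clusters.tsv", sep="\t", index=False)
            log.info("%s %s: %d regulators x %d junctions",
                     ds, role, len(regulators), len(junctions))
    rows = []
    for a, b in itertools.combinations(datasets, 2):
        for role in ("SF", "TF"):
            shared = sorted(set(kept_regs[(a, role)]) & set(kept_regs[(b, role)]))
            rs, frac = reg.cross_dataset_regulator_correlation(
                expr_by_ds[a], expr_by_ds[b], shared, r_cutoff=cfg.r_report_cutoff
            )
            rows.append(
                {
                    "dataset_a": a, "dataset_b": b, "role": role,
                    "shared_regulators": len(rs),
                    "pct_r_above_cutoff": frac,
                    "corr_of_corr": reg.correlation_of_correlations(
                        corr[(a, role)].r, corr[(b, role)].r
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "summary.tsv", sep="\t", index=False)


def stage_compare(cfg: PipelineConfig) -> None:
    outdir = Path(cfg.workdir) / "compare"
    outdir.mkdir(parents=True, exist_ok=True)
    datasets = _datasets(cfg)
    loaded = {}
    for ds in datasets:
        dsdir = Path(cfg.workdir) / "ds"
        tests = pd.read_csv(dsdir / f"{ds}_tests.tsv", sep="\t")
        dpsi = pd.read_csv(dsdir / f"{ds}_dpsi.tsv", sep="\t")
        calls = frame_to_calls(pd.read_csv(dsdir / f"{ds}_calls.tsv", sep="\t"))
        loaded[ds] = (frames_to_results(tests, dpsi), calls)
    rows = []
    for a, b in itertools.combinations(datasets, 2):
        summary = cross_dataset.concordance(
            loaded[a][0], loaded[a][1], loaded[b][0], loaded[b][1],
            dataset_pair=(a, b), alpha=cfg.alpha,
        )
        rows.append(summary.to_row())
    pd.DataFrame(rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    log.info("concordance written for %d dataset pairs", len(rows))


_STAGES = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "test": stage_test,
    "classify": stage_classify,
    "regulate": stage_regulate,
    "compare": stage_compare,
}


def run(subcommand: str, cfg: PipelineConfig) -> int:
    """Run one stage or, with ``all``, the whole pipeline in order."""
    if subcommand not in SUBCOMMANDS:
        raise ContractError(f"unknown subcommand {subcommand!r}; choose from {SUBCOMMANDS}")
    _write_config(cfg)
    stages = list(_STAGES) if subcommand == "all" else [subcommand]
    for name in stages:
        log.info("stage %s (seed=%d, hash=%s)", name, cfg.seed, cfg.config_hash)
        _STAGES[name](cfg)
    return 0
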