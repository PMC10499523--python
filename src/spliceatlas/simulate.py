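"""Synthetic worlds with planted truth for every pipeline stage.

The generator emulates the multi-dataset immune-cell design the pipeline is
built for: several independent RNA-seq datasets, each profiling B, CD4 T,
CD8 T, NK cells, monocytes and neutrophils with 2-5 replicates (defaults
mirror the real datasets' replicate structure {2, 4, 4, 5}).

Generative model per LC and sample: the LC's total JSR coverage is negative
binomial (mean ``depth_mean``, variance ``mu + dispersion * mu^2``); the split
of that total over the LC's junctions is Dirichlet-multinomial with
concentration ``concentration`` around group proportions. Null LCs share one
proportion vector across groups; differentially spliced LCs shift the
designated junction's proportion by ``delta`` in the affected groups (one cell
type for cell-type-specific patterns, the myeloid types for lineage-specific
ones). All datasets share the same truth and draw independent samples.

The annotation generator emits genes engineered so each target LC realizes
exactly one AS type (SE triad, MXE two-LC pair, A5SS/A3SS boundary pairs,
AFE/ALE first/last-exon junctions, plus unannotated "unknown" clusters), on
both strands. Regulator expression is a noisy linear function of a coupled
junction's realized PSI (splicing factors couple to non-AFE junctions,
transcription factors to AFE junctions); null regulators are cell-type-free
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .junction_data import (
    JunctionCountTable,
    junction_key,
    write_count_table,
    write_sample_sheet,
)
from .regulation_inference import ExpressionTable, write_expression

Interval = tuple[int, int]


@dataclass
class RegulatorConfig:
    n_true_sf: int = 30
    n_true_tf: int = 30
    n_null_sf: int = 20
    n_null_tf: int = 20
    n_background: int = 200
    noise_frac: float = 0.2  # noise sd as a fraction of the coupled signal sd


def _default_as_mix() -> dict[str, int]:
    # one instance per strand of each engineered type
    return {t: 2 for t in ("SE", "MXE", "A5SS", "A3SS", "AFE", "ALE", "unknown")}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_datasets: int = 4
    cell_types: tuple[str, ...] = ("B", "CD4 T", "CD8 T", "NK", "Monocytes", "Neutrophils")
    replicates: tuple[int, ...] = (2, 4, 4, 5)  # per dataset, per cell type
    conditions: tuple[str, ...] = ("healthy",)
    n_lcs: int = 100  # generic (annotation-free) LCs
    junctions_per_lc: int = 3
    frac_ds: float = 0.25
    delta: float = 0.3
    concentration: float = 30.0
    depth_mean: float = 80.0
    depth_dispersion: float = 0.3
    as_type_mix: dict[str, int] = field(default_factory=_default_as_mix)
    regulators: RegulatorConfig = field(default_factory=RegulatorConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.frac_ds <= 1):
            raise ValueError("frac_ds must be in [0, 1]")
        if not (0 < self.delta < 1):
            raise ValueError("delta must be in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class LCBlueprint:
    index: int
    gene_id: str | None
    chrom: str
    strand: str
    junctions: list[Interval]
    as_type: str  # SE/MXE/A5SS/A3SS/AFE/ALE/unknown/generic
    ds_junction: int | None = None  # index into ``junctions`` of the shifted one
    is_ds: bool = False
    pattern: str = "null"  # "cell:<type>" | "lineage" | "condition" | "null"

    @property
    def lc_key(self) -> str:
        return f"bp{self.index}"

    @property
    def junction_keys(self) -> list[str]:
        return [junction_key(self.chrom, s, e, self.strand) for s, e in self.junctions]


@dataclass
class GeneBlueprint:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[list[Interval]]


@dataclass
class GroundTruth:
    lcs: list[dict]
    regulators: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps({"lcs": self.lcs, "regulators": self.regulators}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(d["lcs"], d["regulators"])


# ---------------------------------------------------------------------------
# geometry templates (coordinates relative to a gene offset; '+' strand sense)
# ---------------------------------------------------------------------------

def _tpl_se():
    tx = [
        [(600, 699), (1000, 1099), (1200, 1299), (1400, 1499), (1700, 1799)],
        [(600, 699), (1000, 1099), (1400, 1499), (1700, 1799)],
    ]
    return tx, [([(1100, 1199), (1300, 1399), (1100, 1399)], 2)]


def _tpl_mxe():
    tx = [
        [(600, 699), (1000, 1099), (1200, 1299), (1700, 1799), (2000, 2099)],
        [(600, 699), (1000, 1099), (1400, 1499), (1700, 1799), (2000, 2099)],
    ]
    return tx, [([(1100, 1199), (1100, 1399)], 1), ([(1300, 1699), (1500, 1699)], 1)]


def _tpl_a5ss_plus():
    tx = [
        [(600, 699), (1000, 1149), (1400, 1499), (1700, 1799)],
        [(600, 699), (1000, 1199), (1400, 1499), (1700, 1799)],
    ]
    return tx, [([(1150, 1399), (1200, 1399)], 0)]


def _tpl_a3ss_plus():
    tx = [
        [(600, 699), (1000, 1099), (1300, 1499), (1700, 1799)],
        [(600, 699), (1000, 1099), (1350, 1499), (1700, 1799)],
    ]
    return tx, [([(1100, 1299), (1100, 1349)], 0)]


def _tpl_afe_plus():
    tx = [
        [(1000, 1099), (2000, 2099), (2400, 2499)],
        [(1400, 1499), (2000, 2099), (2400, 2499)],
    ]
    return tx, [([(1100, 1999), (1500, 1999)], 0)]


def _tpl_ale_plus():
    tx = [
        [(600, 699), (1000, 1099), (1200, 1299)],
        [(600, 699), (1000, 1099), (1600, 1699)],
    ]
    return tx, [([(1100, 1199), (1100, 1599)], 0)]


def _tpl_unknown():
    tx = [[(600, 699), (1000, 1099), (2000, 2099)]]
    return tx, [([(1300, 1599), (1300, 1699)], 0)]


def _template_for(as_type: str, strand: str):
    """On '-', donor/acceptor and first/last exons swap, so the geometry that
    realizes a type is the mirror type's '+' geometry."""
    if as_type == "SE":
        return _tpl_se()
    if as_type == "MXE":
        return _tpl_mxe()
    if as_type == "unknown":
        return _tpl_unknown()
    plus_tpl = {
        "A5SS": _tpl_a5ss_plus,
        "A3SS": _tpl_a3ss_plus,
        "AFE": _tpl_afe_plus,
        "ALE": _tpl_ale_plus,
    }
    mirror = {"A5SS": "A3SS", "A3SS": "A5SS", "AFE": "ALE", "ALE": "AFE"}
    return plus_tpl[as_type if strand == "+" else mirror[as_type]]()


@dataclass
class Blueprint:
    genes: list[GeneBlueprint]
    lcs: list[LCBlueprint]
    gff3: str


def generate_annotation(config: SimulationConfig) -> Blueprint:
    """Engineered genes and clusters realizing the configured AS-type mix,
    plus annotation-free generic clusters. Deterministic given the config."""
    genes: list[GeneBlueprint] = []
    lcs: list[LCBlueprint] = []
    offset = 0
    gi = 0
    for as_type in sorted(config.as_type_mix):
        for inst in range(config.as_type_mix[as_type]):
            strand = "+" if inst % 2 == 0 else "-"
            tx, lc_defs = _template_for(as_type, strand)
            gene_id = f"G_{as_type}_{inst}"
            genes.append(
                GeneBlueprint(
                    gene_id,
                    "chrA",
                    strand,
                    [[(s + offset, e + offset) for s, e in t] for t in tx],
                )
            )
            for junctions, ds_j in lc_defs:
                lcs.append(
                    LCBlueprint(
                        index=len(lcs),
                        gene_id=gene_id,
                        chrom="chrA",
                        strand=strand,
                        junctions=[(s + offset, e + offset) for s, e in junctions],
                        as_type=as_type,
                        ds_junction=ds_j,
                        is_ds=True,
                        pattern="cell:placeholder",
                    )
                )
            offset += 10_000
            gi += 1
    for i in range(config.n_lcs):
        start = 1_000 + 5_000 * i * max(1, config.junctions_per_lc)
        junctions = [
            (start, start + 200 + 400 * k) for k in range(config.junctions_per_lc)
        ]
        lcs.append(
            LCBlueprint(
                index=len(lcs),
                gene_id=None,
                chrom="chrG",
                strand="+",
                junctions=junctions,
                as_type="generic",
            )
        )
    return Blueprint(genes=genes, lcs=lcs, gff3=_emit_gff3(genes))


def _emit_gff3(genes: Sequence[GeneBlueprint]) -> str:
    lines = ["##gff-version 3"]
    for g in genes:
        lo = min(s for t in g.transcripts for s, _ in t)
        hi = max(e for t in g.transcripts for _, e in t)
        attrs = f"ID={g.gene_id};Name={g.gene_id}"
        lines.append(
            f"{g.chrom}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{attrs}"
        )
        for ti, exons in enumerate(g.transcripts):
            tid = f"{g.gene_id}.t{ti + 1}"
            tlo = min(s for s, _ in exons)
            thi = max(e for _, e in exons)
            lines.append(
                f"{g.chrom}\tsynthetic\tmRNA\t{tlo}\t{thi}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}"
            )
            for ei, (s, e) in enumerate(sorted(exons)):
                lines.append(
                    f"{g.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.e{ei + 1};Parent={tid}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

_PATTERN_CYCLE = (
    "cell:B", "cell:T", "cell:NK", "cell:Monocytes", "cell:Neutrophils", "lineage",
)


def _shift(p: np.ndarray, j: int, delta: float) -> np.ndarray:
    delta = min(delta, 0.92 - p[j])
    out = p.copy()
    out[j] = p[j] + delta
    rest = 1.0 - p[j]
    scale = (1.0 - out[j]) / rest if rest > 0 else 0.0
    for k in range(len(p)):
        if k != j:
            out[k] = p[k] * scale
    return out / out.sum()


def _nb_total(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def _dm_draw(rng: np.random.Generator, total: int, alpha: float, p: np.ndarray) -> np.ndarray:
    if total == 0:
        return np.zeros(len(p), dtype=np.int64)
    w = rng.gamma(np.maximum(alpha * p, 1e-12))
    if not np.isfinite(w).all() or w.sum() <= 0:
        w = p
    return rng.multinomial(total, w / w.sum()).astype(np.int64)


def _group_of(cell_type: str, condition: str) -> str:
    from .ds_test import harmonize_cell_type

    return harmonize_cell_type(cell_type) if condition == "healthy" else condition


def generate_counts(
    config: SimulationConfig, blueprint: Blueprint
) -> tuple[dict[str, JunctionCountTable], GroundTruth]:
    """Per-dataset junction count tables plus the planted truth.

    Patterns for DS LCs cycle deterministically through the five cell-type-
    specific patterns and lineage-specific, so every pattern is exercised.
    With >1 configured condition, DS LCs instead shift the designated junction
    in the non-healthy conditions across all cell types.
    """
    rng = np.random.default_rng(config.seed)
    condition_mode = len(config.conditions) > 1

    # planted usage proportions
    ds_counter = 0
    for lc in blueprint.lcs:
        J = len(lc.junctions)
        if lc.as_type == "generic":
            raw = rng.dirichlet(np.full(J, 4.0))
            base = (raw + 0.15) / (1.0 + 0.15 * J)
            lc_is_ds = ds_counter < round(config.frac_ds * config.n_lcs)
            lc.is_ds = bool(lc_is_ds)
            ds_counter += 1
            lc.ds_junction = int(np.argmin(base)) if lc.is_ds else None
        else:
            base = np.full(J, 1.0 / J)
        lc.base_props = base  # type: ignore[attr-defined]
        if lc.is_ds:
            if condition_mode:
                lc.pattern = "condition"
            else:
                lc.pattern = _PATTERN_CYCLE[lc.index % len(_PATTERN_CYCLE)]
            lc.shift_props = _shift(base, lc.ds_junction, config.delta)  # type: ignore[attr-defined]
        else:
            lc.pattern = "null"
            lc.shift_props = base  # type: ignore[attr-defined]

    def props_for(lc: LCBlueprint, cell_type: str, condition: str) -> np.ndarray:
        if not lc.is_ds:
            return lc.base_props
        if condition_mode:
            return lc.shift_props if condition != "healthy" else lc.base_props
        harmonized = _group_of(cell_type, "healthy")
        if lc.pattern == "lineage":
            shifted = harmonized in ("Monocytes", "Neutrophils")
        else:
            shifted = harmonized == lc.pattern.split(":", 1)[1]
        return lc.shift_props if shifted else lc.base_props

    all_keys = [k for lc in blueprint.lcs for k in lc.junction_keys]
    tables: dict[str, JunctionCountTable] = {}
    for d in range(config.n_datasets):
        ds_name = f"DS{d + 1}"
        n_rep = config.replicates[d % len(config.replicates)]
        sample_rows = []
        cols: dict[str, np.ndarray] = {}
        for condition in config.conditions:
            for ct in config.cell_types:
                for rep in range(1, n_rep + 1):
                    tag = ct.replace(" ", "")
                    sid = f"{ds_name}_{condition}_{tag}_{rep}"
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "dataset": ds_name,
                            "cell_type": ct,
                            "condition": condition,
                            "donor": f"{ds_name}_donor{rep}",
                        }
                    )
                    col = np.empty(len(all_keys), dtype=np.int64)
                    pos = 0
                    for lc in blueprint.lcs:
                        J = len(lc.junctions)
                        total = _nb_total(rng, config.depth_mean, config.depth_dispersion)
                        p = props_for(lc, ct, condition)
                        col[pos:pos + J] = _dm_draw(rng, total, config.concentration, p)
                        pos += J
                    cols[sid] = col
        counts = pd.DataFrame(cols, index=pd.Index(all_keys, name="junction"))
        tables[ds_name] = JunctionCountTable(counts, pd.DataFrame(sample_rows))

    truth = GroundTruth(
        lcs=[
            {
                "index": lc.index,
                "gene_id": lc.gene_id,
                "junctions": lc.junction_keys,
                "as_type": lc.as_type,
                "is_ds": lc.is_ds,
                "pattern": lc.pattern,
                "ds_junction": (
                    lc.junction_keys[lc.ds_junction] if lc.ds_junction is not None else None
                ),
                "delta": config.delta if lc.is_ds else 0.0,
                "base_props": [float(x) for x in lc.base_props],
                "shift_props": [float(x) for x in lc.shift_props],
            }
            for lc in blueprint.lcs
        ],
        regulators={},
    )
    return tables, truth


# ---------------------------------------------------------------------------
# regulators
# ---------------------------------------------------------------------------

def generate_regulators(
    config: SimulationConfig,
    tables: Mapping[str, JunctionCountTable],
    truth: GroundTruth,
) -> tuple[dict[str, ExpressionTable], list[str], list[str]]:
    """Regulator + background expression per dataset, coupled to realized PSI.

    True regulators read ``round(a + b * PSI + noise)`` with |noise| sd =
    ``noise_frac`` of the coupled signal sd; the coupling (junction and sign)
    is shared across datasets. Updates ``truth.regulators`` in place and
    returns (expression tables, SF gene ids, TF gene ids).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    reg = config.regulators

    afe_lcs = {t["index"] for t in truth.lcs if t["as_type"] == "AFE"}
    sf_pool = [
        t["ds_junction"] for t in truth.lcs
        if t["is_ds"] and t["ds_junction"] and t["index"] not in afe_lcs
    ]
    tf_pool = [t["ds_junction"] for t in truth.lcs if t["index"] in afe_lcs and t["ds_junction"]]
    if not sf_pool or not tf_pool:
        raise ValueError("blueprint lacks DS junctions to couple regulators to")

    # realized PSI per dataset under the planted cluster assignment
    from .junction_data import compute_psi

    cluster_of = {}
    for t in truth.lcs:
        for k in t["junctions"]:
            cluster_of[k] = f"bp{t['index']}"
    psi_by_ds = {d: compute_psi(tab, cluster_of).psi for d, tab in tables.items()}

    def make_gene_ids(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i + 1:03d}" for i in range(n)]

    sf_true = make_gene_ids("SF_T", reg.n_true_sf)
    sf_null = make_gene_ids("SF_N", reg.n_null_sf)
    tf_true = make_gene_ids("TF_T", reg.n_true_tf)
    tf_null = make_gene_ids("TF_N", reg.n_null_tf)
    background = make_gene_ids("BG", reg.n_background)

    couplings: dict[str, dict] = {}
    for i, g in enumerate(sf_true):
        couplings[g] = {
            "role": "SF", "is_true": True,
            "coupled_junction": sf_pool[i % len(sf_pool)],
            "sign": 1 if rng.random() < 0.5 else -1,
        }
    for i, g in enumerate(tf_true):
        couplings[g] = {
            "role": "TF", "is_true": True,
            "coupled_junction": tf_pool[i % len(tf_pool)],
            "sign": 1 if rng.random() < 0.5 else -1,
        }
    for g in sf_null:
        couplings[g] = {"role": "SF", "is_true": False, "coupled_junction": None, "sign": 0}
    for g in tf_null:
        couplings[g] = {"role": "TF", "is_true": False, "coupled_junction": None, "sign": 0}
    truth.regulators = couplings

    null_mu = {g: float(rng.uniform(80, 400)) for g in sf_null + tf_null}
    bg_mu = {g: float(rng.uniform(20, 2000)) for g in background}
    all_genes = sf_true + sf_null + tf_true + tf_null + background

    expr_by_ds: dict[str, ExpressionTable] = {}
    b_mag = 250.0
    for ds_name, table in tables.items():
        psi = psi_by_ds[ds_name]
        samples = list(table.counts.columns)
        mat = np.zeros((len(all_genes), len(samples)))
        for gi, g in enumerate(all_genes):
            info = couplings.get(g)
            if info and info["is_true"]:
                j = info["coupled_junction"]
                pv = psi.loc[j, samples].to_numpy(dtype=float)
                pv = np.where(np.isfinite(pv), pv, np.nanmean(pv))
                sd = float(np.std(pv))
                b = b_mag * info["sign"]
                a = 100.0 if info["sign"] > 0 else 350.0
                noise = rng.normal(0.0, reg.noise_frac * b_mag * max(sd, 1e-9), len(samples))
                vals = a + b * pv + noise
            elif info:  # null regulator: cell-type-independent noise
                mu = null_mu[g]
                vals = rng.normal(mu, 0.15 * mu, len(samples))
            else:
                mu = bg_mu[g]
                vals = rng.normal(mu, 0.1 * mu, len(samples))
            mat[gi] = np.clip(np.round(vals), 0, None)
        counts = pd.DataFrame(
            mat.astype(np.int64), index=pd.Index(all_genes, name="gene_id"), columns=samples
        )
        expr_by_ds[ds_name] = ExpressionTable(counts, table.samples.reset_index())
    return expr_by_ds, sf_true + sf_null, tf_true + tf_null


# ---------------------------------------------------------------------------
# orchestration + emission
# ---------------------------------------------------------------------------

@dataclass
class World:
    config: SimulationConfig
    blueprint: Blueprint
    tables: dict[str, JunctionCountTable]
    expression: dict[str, ExpressionTable]
    sf_ids: list[str]
    tf_ids: list[str]
    truth: GroundTruth

    @property
    def sample_sheet(self) -> pd.DataFrame:
        return pd.concat(
            [t.samples.reset_index() for t in self.tables.values()], ignore_index=True
        )


def simulate(config: SimulationConfig) -> World:
    blueprint = generate_annotation(config)
    tables, truth = generate_counts(config, blueprint)
    expression, sf_ids, tf_ids = generate_regulators(config, tables, truth)
    return World(config, blueprint, tables, expression, sf_ids, tf_ids, truth)


def write_world(world: World, outdir: str | Path, junc_files: bool = False) -> None:
    """Emit the world as the plain-text files every upstream reader accepts."""
    out = Path(outdir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    (out / "expression").mkdir(exist_ok=True)
    (out / "annotation.gff3").write_text(world.blueprint.gff3)
    write_sample_sheet(world.sample_sheet, out / "samples.tsv")
    for ds, table in world.tables.items():
        write_count_table(table, out / "counts" / f"{ds}.tsv")
    for ds, expr in world.expression.items():
        write_expression(expr, out / "expression" / f"{ds}.tsv")
    (out / "regulators_sf.txt").write_text("\n".join(world.sf_ids) + "\n")
    (out / "regulators_tf.txt").write_text("\n".join(world.tf_ids) + "\n")
    (out / "truth.json").write_text(world.truth.to_json())
    if junc_files:
        jdir = out / "junc"
        jdir.mkdir(exist_ok=True)
        for ds, table in world.tables.items():
            juncs = table.junctions
            for sid in table.counts.columns:
                lines = []
                col = table.counts[sid]
                for key, row in juncs.iterrows():
                    c = int(col[key])
                    if c > 0:
                        lines.append(
                            f"{row.chrom}\t{row.start - 1}\t{row.end}\t{key}\t{c}\t{row.strand}"
                        )
                (jdir / f"{sid}.junc").write_text("\n".join(lines) + "\n")
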