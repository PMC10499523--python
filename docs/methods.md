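# Methods

This note documents the statistical model, the fixed numerical choices, the
synthetic-data generator, and the design decisions taken where the procedure
was genuinely open. It states no empirical result that the test suite does
not itself compute.

## Junction and cluster model

A junction is an intron interval `chrom:start:end:strand` with `start`/`end`
the first and last intronic bases, 1-based inclusive. On-disk `.junc` files
are read as BED-dialect 0-based half-open intervals and converted on input;
the conversion is its own inverse, and round-trip identity is property-tested.
Strand is part of junction identity (identical intervals on opposite strands
are distinct junctions) and `.` (unknown) is allowed; unknown-strand junctions
cluster only with each other to avoid chimeric clusters across antisense gene
pairs. The flanking exonic positions of a junction are `start−1` and `end+1`;
all annotation queries anchor on them.

Clusters (LCs) are connected components of the shared-start-or-shared-end
graph, per chromosome and strand. The refinement pass before testing is:

1. drop junctions with more than 10 JSR in fewer than 2 samples (strictly
   more than 10 — a count of exactly 10 does not support a sample);
2. build clusters;
3. drop junctions whose count is below 10% of the per-sample mean JSR count
   of their LC in **every** sample. The mean is per sample over the LC's
   members (the tested junction included), and one clearing sample rescues
   the junction — the literal reading of "in all samples". The pooled-count
   alternative was considered and rejected as a looser reading; this choice
   is flagged for sensitivity analysis;
4. split LCs that lost internal connectivity into connected sub-LCs and prune
   LCs with fewer than 2 junctions, removing their count rows. One pass, no
   iteration of step 3 afterwards.

The pass is idempotent (tested) and cluster construction is cross-checked
against an independent connected-components oracle.

## The Dirichlet-multinomial test

Counts of one LC in sample `s` are modeled as `x_s ~ DM(n_s, α p)` with
junction proportions `p` on the simplex and concentration `α` shared across
groups. The likelihood (multinomial coefficient included, so values are
comparable across hypotheses and with other count models) is

    ℓ = Σ_s [ ln n_s!/(Π_j x_js!) + lnΓ(α) − lnΓ(n_s+α)
              + Σ_j ( lnΓ(x_js + α p_j) − lnΓ(α p_j) ) ].

Fitting maximizes ℓ by L-BFGS-B on per-group logits (reference category 0)
plus log α, with analytic gradients. Fixed numerical choices: initialization
at pseudocount-smoothed empirical proportions (+0.5 per junction) and α₀ = 30;
bounds |logit| ≤ 30, log α ∈ [−8, 16]; at most 500 iterations; likelihood
tolerance 1e-8; reported proportions floored at 1e-8 and renormalized.
All-zero input is a degenerate-input error.

The LRT compares group-specific against pooled proportions,
`Λ = 2(ℓ_alt − ℓ_null)` clipped at 0, referred to χ² with `(G−1)(J−1)` df.

### Concentration moderation

How the nuisance concentration is handled decides whether the χ² reference is
usable at realistic replicate counts (2–5 per cell type):

* re-fitting α freely under the alternative lets group means absorb
  between-sample dispersion — the acceptance calibration test measures ~2.5×
  the nominal size at 4 replicates/group;
* profiling α under each test's own pooled null is calibrated but soaks real
  signal into the dispersion estimate, costing enough pairwise power to
  miss a third of planted DS clusters.

`run_ds_analysis` therefore shares dispersion across clusters, as
expression tools (edgeR, limma) share it across genes: each eligible LC's α
is estimated under its pooled null; the analysis-wide median of log α is
bias-corrected by a one-round parametric bootstrap at the operating point
(300 resamples, fixed internal seed 0 — the pooled MLE runs ~10–15% high at
~20 samples); and every multi-group and pairwise test runs at that fixed
global concentration. At the global null this reproduces the calibration of
the oracle-concentration test (verified by the acceptance suite). The
limitation is deliberate: real clusters vary in α, and a single moderated
value trades per-cluster adaptivity for calibration; the median is robust to
the minority of signal-carrying clusters. The standalone `lrt()` (no
ensemble available) maximizes α freely under both hypotheses — the plain,
powerful, small-sample-anticonservative LRT; analyses should go through
`run_ds_analysis`.

### Eligibility

Mirroring the upstream tool's support flags: a junction enters a test with
≥ 10 reads in ≥ 2 of the compared samples; the multi-group screen requires no
per-group support (`-i 2 -g 0`), pairwise tests require 2 samples per group
whose LC total reaches 10 reads (`-M 10 -i 2 -g 2`). Ineligible tests carry a
"not tested" marker, never a p-value.

### Hierarchical FDR and DS calls

Stage 1: BH across the multi-group p-values of all tested LCs; selection at
adjusted p ≤ 0.05. Stage 2: pairwise tests only within selected LCs, BH
within LC at level `q·R/m` (R selected of m tested) — the
Benjamini-Bogomolov selective-inference scaling; stored adjusted p-values are
pre-scaled by `m/R` so the significance rule is uniformly `p_adj ≤ q`.
The hierarchical reference the analysis follows gives no formulas; this
scaling is the package's concrete choice.

`max(ΔPSI)` per junction is the maximal |ΔPSI| over *significant* pairwise
comparisons. A DS-LC requires: (1) multi-group adjusted p ≤ 0.05 — healthy
analysis only; (2) ≥ 1 significant pairwise comparison (any one; requiring a
specific one was the stricter unstated alternative); (3) ≥ 2 junctions with
max|ΔPSI| ≥ 0.1; (4) ≥ 1 junction with max|ΔPSI| ≥ 0.2. Two-condition
contrasts skip the multi-group stage and condition 1 and BH-adjust the single
comparison across LCs.

Patterns over the five harmonized cell types (CD4/CD8 folded into T; a
comparison significant with either subtype counts for T): cell-type-specific
for `t` iff every comparison involving `t` is significant — non-significance
among the remaining types is *not* additionally required (open question,
resolved permissively); lineage-specific iff all six lymphoid×myeloid
comparisons are significant with one ΔPSI sign on the LC's strongest junction
(ties broken by junction key order); cell-type-specific takes precedence.

## ΔPSI

PSI is undefined (NaN), never 0, where the LC total is 0 in a sample; group
means ignore undefined entries, and a group with no defined entries yields an
undefined ΔPSI. For planted-recovery scoring, the estimator matched to a
cell-type-specific truth is (mean PSI of the shifted type) − (mean PSI pooled
over the remaining types): pooling the complement is what the planted
contrast defines, and at 4 replicates/group the per-pair estimator's sampling
error alone (~0.05–0.056 mean absolute deviation by the DM variance formula)
would swamp the recovery signal.

## AS-type classification

Pure function of (junction geometry, max|ΔPSI|, annotation); junctions below
|ΔPSI| 0.1 are invisible to the classifier (for SE, via the 2-of-3 rule).

* **SE** — exact triad around an annotated exon `(s, e)`: inclusion junctions
  ending at `s−1` and starting at `e+1`, and a skip junction sharing both
  outer endpoints (`j0.start = j1.start`, `j0.end = j2.end`); a relaxed
  containment-only skip is not accepted, matching cluster connectivity.
* **MXE** — ordered pairs of one gene's LCs (upstream/downstream by genomic
  coordinate, not strand): upstream needs ≥ 2 qualifying junctions sharing a
  start with distinct ends, downstream ≥ 2 sharing an end with distinct
  starts. Genes with more than two LCs are handled by testing all coordinate-
  ordered pairs (the stricter exactly-two reading is noted).
* **A5SS/A3SS** — strand-resolved (donor = start on `+`, end on `−`): ≥ 2
  qualifying junctions sharing one splice site, differing on the other, with
  all alternate-side flanking positions inside a single merged-exon interval.
  The published wording is annotation-level; this coordinate rule is the
  package's operationalization. Unknown strand falls through unclassified.
* **AFE/ALE** — a qualifying junction whose flanking position lies in a
  first-exon (resp. last-exon) interval of some transcript, strand-aware.
  The sets may overlap (an exon can be first in one transcript, last in
  another); an LC may carry several labels or none ("unknown").

Gene assignment does not require exon-boundary matches (real junction sets
contain unannotated introns): a junction belongs to a gene iff both flanking
positions lie within the gene's span with compatible strand; ties go to the
larger exon-union overlap, then the smaller gene id. An LC takes its
junctions' majority gene.

## Regulation inference

Regulator lists (splicing factors: GO:0008380; transcription factors:
GO:0009299) are plain text files, one gene per line — frozen inputs, no live
GO queries. Expression is normalized to reads per million before the ANOVA
and all correlations; the source analysis states no normalization, and
unnormalized counts would correlate with depth rather than biology. A
regulator is kept with ≥ 10 raw reads in ≥ 1 sample in ≥ 2 datasets and
one-way ANOVA (RPM ~ cell type, `scipy.stats.f_oneway`) p ≤ 0.05.

Junctions for correlation: in DS-LCs shared by ≥ 2 datasets, max|ΔPSI| ≥ 0.2;
SF analysis excludes AFE-classified LCs, TF analysis keeps only them
("unknown" counts as non-AFE). Pearson correlations across samples use
pairwise deletion of undefined PSI, need ≥ 3 defined pairs, and record
zero-variance cases as missing — never 0. Clustering: junction PSI profiles
with standardized-Euclidean distance and complete linkage; regulator
expression with correlation distance and average linkage; trees cut to 10
flat clusters (lowered with a warning when fewer items exist). Undefined PSI
entries are filled with the junction's own mean for distance computation
only. Cross-dataset regulator agreement uses the five harmonized cell-type
means (T subtypes averaged) per dataset and reports the fraction of shared
regulators with r > 0.7, plus the Pearson correlation between flattened
regulator-by-junction correlation matrices over entries defined in both.

## Cross-dataset concordance

Datasets are compared at the junction level (clusters are dataset-specific):
junctions shared by exact key between DS-LCs of both datasets. For each, the
ten harmonized cell-type comparisons are categorized as non-significant in
both, significant in one, or significant in both with same/opposite ΔPSI
sign; comparisons untested or ineligible in either dataset are excluded from
the denominator (the alternative — counting them as non-significant — would
deflate every percentage and is noted as the open reading). The summary also
reports the fraction of shared junctions with ≥ 1 same-direction significant
comparison and the Pearson correlation of max|ΔPSI| vectors. All fields are
symmetric under swapping the datasets (tested).

## Synthetic worlds

The generator emulates the four-dataset immune design: datasets with
2/4/4/5 replicates of B, CD4 T, CD8 T, NK, monocytes, neutrophils sharing one
truth and drawing independent samples. Per LC and sample, total coverage is
negative binomial (mean 80, dispersion 0.3 — variance `μ + 0.3μ²`,
overdispersion typical of bulk junction coverage) and the junction split is
DM with α = 30. Null LCs share one proportion vector (Dirichlet(4) smoothed
toward uniform so every junction clears the 10% filter by construction); DS
LCs shift the designated junction by ΔPSI = 0.3 (renormalizing the rest) in
the affected groups. Planted patterns cycle deterministically through the
five cell-type-specific patterns and lineage-specific so every pattern is
exercised. A quarter of generic LCs are DS by default.

Engineered annotation: one gene per AS type per strand whose junction set
realizes exactly that type — SE triads, two-LC MXE pairs, A5SS/A3SS boundary
pairs, AFE/ALE first/last-exon junctions — padded with flanking exons so no
fixture accidentally touches a first or last exon; on the minus strand the
mirror geometry is used so the label is realized under strand-aware rules.
"Unknown" fixtures are junctions inside a gene matching no rule, plus
annotation-free generic clusters.

Regulators: expression = `a + b·PSI + ε` with |b| = 250, sign planted,
intercept keeping counts positive, and ε Gaussian with sd = 20% of the
coupled signal's sd; SFs couple to non-AFE DS junctions, TFs to AFE
junctions, the coupling shared across datasets. Null regulators are
cell-type-independent noise; ~200 background genes set the sequencing depth.
Everything is deterministic per seed, and emitted files are valid inputs to
every reader (schema round-trips are tested).

### What a green test does not establish

The generator matches the test's own distributional family (NB totals, DM
splits, one shared α, linear regulator couplings). Green acceptance tests
therefore establish internal correctness and calibration under the stated
world — not robustness to real-data pathologies: per-cluster dispersion
heterogeneity, GC/length biases, unannotated strand errors, batch effects
within a dataset, or regulators with nonlinear or combinatorial effects.
Cross-dataset concordance in the synthetic world shares the exact truth;
real datasets differ in populations and protocols, so observed concordance
there is expected to be lower.

## Known limitations

* Intron retention is invisible to junction-count analysis and out of scope.
* A single moderated concentration per analysis (see above).
* The 10%-abundance filter uses per-sample averages; the pooled reading
  would remove slightly more junctions.
* Pattern labels require every relevant comparison to be significant, so
  they are conservative at low replication.
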