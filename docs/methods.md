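# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical conventions and the deliberate design choices in
`membranebench`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

Quantification tables are proteins × samples matrices of MaxLFQ-style
intensities with explicit missingness (NaN). Three conventions are fixed
at the I/O boundary:

- an intensity of exactly **0 means "not quantified"** and becomes missing
  on read (the upstream quantification tool writes 0 for absent values;
  coercion prevents log2(0) downstream);
- a protein is **"identified" in a replicate** iff it has a present
  intensity in that replicate's column;
- the log2 transform is recorded in a scale flag so it can be applied at
  most once.

## Localization classification

Each protein carries a GO cellular-component keyword string, a predicted
α-helical TM-segment count, a gene symbol and a molecular weight. The
decision procedure is a fixed partition:

1. no "membrane" keyword → **SP** (soluble);
2. membrane keyword, TM count 0 → **MAP** (membrane-associated);
3. membrane keyword, ≥ 1 TM, "plasma membrane" keyword → **pIMP**;
4. otherwise → **oIMP**.

Matching is case-insensitive substring matching against configurable
keyword lists. Rule 4 is intentionally a catch-all: the IMP split is
binary, so pIMP + oIMP = IMP holds as an arithmetic identity for any
input (the organellar keyword list is retained for diagnostics and
configurability, not as a gate). Curated GO keyword sets are open-ended;
the defaults (ER, Golgi, endosome, exosome, peroxisome, lysosome, vesicle,
mitochond-, nucle-) are a practical superset of the usual organellar
terms, and users can supply their own.

SLC (solute carrier) transporters are flagged by the gene-symbol rule
`Slc<digit>…` (case-insensitive), optionally extended by user keyword
lists over the annotation string. This is a deliberate stand-in for a
curated molecular-function vocabulary, which no desk-side rule can fully
reproduce.

TM counts are taken from the annotation table whenever provided, so output
from a real topology predictor can be used directly. When absent, a
deterministic hydropathy sliding-window stand-in is available: windows of
19 residues with mean Kyte–Doolittle hydropathy ≥ 1.6 are merged into
maximal runs; a run counts one segment, or ⌈run/19⌉ segments when it
exceeds twice the window. This is a crude surrogate for an HMM topology
predictor — adequate for synthetic sequences with planted hydrophobic
stretches, not a replacement on real proteins.

## Hydropathy profiling

GRAVY is the mean Kyte–Doolittle (1982) hydropathy over a sequence's
residues; the scale table is defined once and shared with the TM stand-in.
Per workflow, peptide GRAVY scores are summarized as an intensity-weighted
distribution: duplicate sequences collapse to one entry whose weight is
the summed present intensity over the pooled samples, and the weighted
median is the smallest score whose cumulative weight reaches half the
total (invariant to weight rescaling). Because published per-method
medians rarely state whether they are intensity-weighted, the unweighted
per-sequence median is reported alongside.

Pairwise workflow comparisons use the two-sided Wilcoxon rank-sum test
(scipy's `mannwhitneyu`) on the **unweighted** per-sequence scores — a
rank test is weight-free by construction, so intensity weights shape only
the displayed distribution — with Bonferroni correction by the number of
pairs, C(k, 2).

## Global structure analyses

- **Correlation**: Pearson r over pairwise-complete observations on the
  log2 scale; pairs sharing fewer than 3 proteins are reported as
  undefined rather than dropped. Between-method correlation represents
  each workflow by its highest-identification replicate (ties to the
  lowest replicate index); the same "best replicate" rule is reused for
  abundance ranking, where the choice is otherwise arbitrary.
- **PCA**: complete-case proteins only (no imputation — the least-
  assumption default), each protein row centered and unit-scaled
  (sample SD), samples projected on the first two components. Signs are
  fixed by forcing each component's first nonzero protein loading
  non-negative, making coordinates deterministic up to that convention.
- **Compositions**: top-200 (ties broken by accession, deterministic) and
  abundance quartiles. Quartiles are formed on the descending sort; when
  the protein count is not divisible by 4 the higher quartiles take the
  extra proteins — an explicit tie-break where no convention is standard.
- **Molecular-weight recovery**: per MW bin (default edges 40/70/100 kDa),
  the number of IMPs identified by workflow A as a percentage of workflow
  B — the diagnostic for filter-based loss of small proteins.
- **Overlaps**: exclusive (UpSet-style) intersection sizes; each protein
  belongs to exactly one membership pattern, so sizes sum to the union.
  Results are emitted as a pattern/size table consumable by any UpSet
  plotting tool.
- **Heatmap preparation**: missing → constant −4 (far below any observed
  log2 intensity), then per-row centering and unit-scaling; zero-variance
  rows become all-zero.

## Differential abundance

The two-group model (condition vs condition within a workflow, or
workflow vs workflow within a condition) chains four steps:

1. **Valid-value filter.** Default: ≥ 3 present values among the 6
   samples of the comparison. The stricter alternative — present in all
   replicates of at least one group — is selectable (`valid_rule`). Both
   rules circulate in practice; where they conflict, the 3-of-6 rule is
   the default because it describes what volcano plots typically show.
2. **MNAR imputation.** Per sample (column) with observed mean μ and SD σ
   (ddof = 1), each missing cell draws independently from
   Normal(μ − 1.8σ, (0.3σ)²). Per-column imputation matches the
   per-sample detection-limit mechanism the downshift models. Seeded and
   reproducible; present values untouched; a column needs ≥ 2 present
   values.
3. **Moderated statistic.** t = (mean_B − mean_A)/(SE + s0) with the
   pooled-variance SE and s0 = 0.1 by default. At s0 = 0 this is exactly
   the classical pooled t test. Two-sided p-values are read from the t
   distribution with n_A + n_B − 2 df at the moderated statistic; for
   s0 > 0 this is a deliberately conservative convention (the statistic is
   shrunk but the reference distribution is unchanged), which is why both
   the analytic p (driving volcano thresholds) and the permutation q
   (driving FDR cuts) are reported.
4. **Permutation FDR.** Balanced relabelings of the group assignment; for
   a 3-vs-3 design all C(6,3)/2 = 10 distinct relabelings minus the
   identity are enumerated exactly, eliminating Monte-Carlo noise at small
   n (a subsample is drawn only when `n_perm` is smaller). At each
   observed |t| threshold, FDR = (mean permuted count ≥ threshold)/
   (observed count ≥ threshold); the per-protein q is the monotone
   envelope (minimum over all thresholds at or below the protein's own
   |t|), capped at 1. No π0 correction is applied, so q is conservative
   when many true effects exist.

Volcano calls: up if log2FC ≥ 1 **and** −log10 p ≥ 1.3 (both inclusive),
symmetrically down; thresholds configurable. Per-category summaries report
up/down/total and proportions for pIMP, oIMP, IMP (= pIMP + oIMP) and
"Sols" (= SP + MAP). An optional additional q-gate
(`results.significant(q_threshold=0.05)`) applies the FDR < 0.05 cut; the
default call set uses the volcano thresholds only, since conventions
differ on whether both gates combine.

## Replicate precision

For each protein present in every paired replicate of both conditions,
log2 fold changes are computed by matched replicate index (replicate i vs
replicate i — three values from 3 + 3; an all-pairs variant exists for
sensitivity analysis) and their sample SD taken. The workflow-level metric
is the mean per-protein SD within IMPs and within soluble proteins. It is
computed on **unimputed** data: imputed values would fabricate precision,
so incompletely observed proteins are excluded and the exclusion count
reported. The metric is invariant to adding a constant to all samples of
one condition.

## Synthetic-data generator

The generator emulates the structure of a seven-workflow, two-condition,
three-replicate benchmark (42 sample columns) with full ground truth. It
is first-class, tested code — the basis of all recovery properties — not a
fixture.

**Proteome.** Categories are drawn from configurable proportions (default
SP 0.49, MAP 0.34, pIMP 0.07, oIMP 0.10, matching the category shares a
deep liver-membrane dataset shows). IMPs draw a TM count from a per-class
distribution over the five TM bins (pIMPs skewed to multi-pass); each TM
is a 19-residue stretch from {I, L, V, F, A, M} embedded in a hydrophilic
background (mean hydropathy ≈ −2.4, K/R frequent enough for tryptic
digestion), separated by ≥ 20-residue spacers so the window stand-in
resolves the planted count exactly. Keyword strings are constructed to
satisfy the classification rules; molecular weight is the (monoisotopic)
sequence mass; ~15% of pIMPs receive SLC-style gene symbols. Base
abundances are log-normal: log2 intensity ~ Normal(23, 2), the typical
MaxLFQ range. A fraction (default 10%) of proteins carries a planted
condition effect of |log2FC| = 2 with random sign.

**Workflow capture.** Expected captured abundance =
base × logistic(slope · (GRAVY − midpoint)) × category factor
(imp_enrichment ≥ 1 for IMPs, sp_depletion ≤ 1 for SPs) × optional
logistic molecular-weight retention below a cutoff (modelling
centrifugal-filter loss of small proteins). The seven presets are
*qualitative* parameterizations mirroring the benchmark's ordering, not
fits to any measured data: mimetics (Peptidisc, spNW30) with positive
GRAVY slope, strong IMP enrichment (5×/4×), SP depletion and low replicate
CV (0.12/0.15); solid-phase presets with negative slope and high CV
(0.40–0.50); FASP additionally with a 40 kDa loss cutoff; SMA2000
intermediate (2.5×, CV 0.20). The CV ordering encodes the observation that
mimetic workflows measure membrane-protein fold changes far more
reproducibly.

**Replicates and missingness.** Each replicate value is
expected × exp(ε), ε ~ Normal(0, CV²); the second condition's expectation
is scaled by 2^(true log2FC). Missingness is intensity-dependent
(missing-not-at-random): each cell is masked with probability
logistic(26 − 1.5 · log2 intensity), i.e. a detection-limit transition of
~1.5 log2 units centered near log2 I ≈ 17.3 — the steep MNAR shape that
downshifted-normal imputation models. A shallow transition would instead
produce near-random missingness at mid abundance, which the downshift
imputation handles badly (a single stray missing cell then explodes a
protein's within-group variance); the steep default keeps the generator
consistent with the imputation model the analysis chain assumes.

**Peptides.** Each protein is digested once with the strict-trypsin rule
(cleave after every K/R including before proline), all fully tryptic
peptides with ≤ 2 missed cleavages retained, then filtered to length 7–50
and monoisotopic mass 500–5000 Da (pyteomics residue masses + water).
Protein intensities are split across peptides by a fixed, seeded Dirichlet
draw per protein, preserving protein totals; peptide missingness follows
the protein's.

**Seeding.** One global seed expands into per-stage child seeds via
`numpy.random.SeedSequence.spawn` (proteome, peptide allocation, then one
replicate-noise and one missingness stream per workflow), so every stage
is individually reproducible and full runs are byte-identical.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: no peptide-to-protein inference or shared
peptides, no match-between-runs correlation structure (cells are masked
independently), no batch effects or label-specific biases, replicate noise
that is homoscedastic in the log domain (real solid-phase noise is
intensity- and category-dependent), GRAVY compositions more extreme than
real proteomes (backgrounds ≈ −2.4 vs real medians ≈ −0.2 to −0.6), and no
search-engine FDR structure. Recovery results demonstrate that the
analysis chain is correct and calibrated under its own assumptions, not
that any real workflow attains these numbers.

## Problem sizes and numerical choices

Simulation-based checks use 800 proteins (400–500 for the multi-preset and
peptide-level checks) with 20 seeds per property — sizes chosen so that
Monte-Carlo error is small relative to the margins being asserted while
the whole suite stays quick to run. Other conventions: sample SD
(ddof = 1) throughout; ranking ties broken by accession; report floats
written at fixed precision ("%.6g") and no timestamps in metadata, so
reruns are byte-comparable; p-values floored at the smallest positive
float to keep −log10 p finite.

## Known limitations

- The p-value convention under s0 > 0 (t reference at the shrunk
  statistic) is conservative; tools differ here, and no single convention
  is canonical.
- The permutation FDR has only 9 informative relabelings at n = 3 + 3;
  q-values are correspondingly granular and conservative without a π0
  estimate.
- The TM stand-in and the SLC gene-prefix rule are deliberate surrogates
  for an external topology predictor and a curated function vocabulary.
- MNAR imputation fabricates signal when one group is entirely below the
  detection limit; such proteins legitimately appear significant and
  inflate empirical FDR slightly — a property of the downshift method
  itself, visible in the recovery simulations.
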