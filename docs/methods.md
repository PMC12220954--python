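# Methods

## Temporal model

Expression is modelled on the `log2(CPM + 1)` scale of per-(tissue,
timepoint) pseudobulk profiles (cells summed, columns CPM-normalized).
For each gene within a tissue, ordinary least squares regresses the
pseudobulk value on encoded time; the slope's two-sided p-value uses the
t-distribution with n−2 degrees of freedom and is Benjamini–Hochberg
corrected per tissue across all genes detected in at least one cell.
Genes with numerically zero residual variance (exact lines, constants)
are flagged degenerate, keep their exact slope, and are excluded from the
q-value ranking.

**Time encoding.** The default `scaled01` maps days affinely onto [0, 1],
making the slope threshold independent of the span of the course (0.15 per
scaled-time unit is a 0.15-log2 total change; the same threshold per day
would imply an implausible ~9-log2 change over 60 days). `days` and
`index` encodings are provided for sensitivity analyses.

**Selection thresholds.** Defaults are `q < 0.1`, `slope > 0.15` and
`% cells > 5` (`direction="down"` selects `slope < −0.15` for decreasing
programs). Thresholds are recorded in each signature's provenance.

**Pattern classification.** Among top-variance genes, a trajectory is
*transient* when its maximum sits at an interior timepoint and exceeds both
endpoints by at least 0.5 log2 units (a value chosen so that sampling noise
at default conditions, ~0.04 log2 per pseudobulk point, cannot produce it);
otherwise the sign of its Pearson correlation with time labels it
increasing or decreasing.

**Normalization conventions.** Log base 2 and pseudocount 1 are declared
defaults, configurable per run and recorded in the run summary.

## Signature algebra and validation

The consensus resident program is the exact-string intersection of
per-tissue selections; the temporal T_RM signature removes genes also in
the circulating consensus. Overlap accounting uses exclusive-intersection
(UpSet) semantics over ≤ 10 sets. A symbol-uppercasing mode supports
mouse-to-human comparisons and is symbol matching only, not orthology.

Validation statistics and their fixed conventions:

* **Scoring** — mean over signature genes of row-z-scored values
  (sample sd, ddof 1); zero-variance rows are skipped with a warning.
* **Segregation** — signature rows z-scored, column distance 1−Pearson,
  average linkage, 2-cluster cut; purity is the best label agreement of the
  cut. The pipeline segregates memory-phase columns (day ≥ 30): Pearson
  column distance is invariant to additive shifts, so early-course resident
  columns (which sit at circulating-like baselines) carry no class signal
  by construction — the comparison is between mature memory states.
* **Two-group ranking** — signed −log10 p of a two-sided Mann–Whitney test
  with midranks, sign from the mean difference; ties broken by gene id.
* **Preranked GSEA** — running sum with hit increments ∝ |stat|^w
  (normalized to 1, w = 1 by default) and miss decrements 1/(N−n); ES is
  the extremum; the null draws seeded random same-size gene sets (all of
  them, exactly, when the universe is small enough); NES divides ES by the
  mean |null| of matching sign; the two-sided empirical p uses an add-one
  correction, so p ≥ 1/(n_perm+1).
* **AUC markers** — one-vs-rest U/(n1·n2) with midranks; clusters with
  fewer than 2 cells on a side are skipped.
* **One-vs-all pseudobulk DE** — log2 fold-change of mean CPM (+1) between
  cluster and rest pseudobulk replicates, p from a two-sample t-test on the
  replicate log2 CPM values, BH per cluster. When no biological replicates
  exist, seeded pseudo-replicates split cells at random. A
  negative-binomial Wald model on pseudobulk counts is a heavier
  alternative with the same fold-change definition; the t-test keeps the
  dependency surface small and is exact under the replicate-level
  normality that pooled counts approach.
* **Growth score** — proliferation-score minus apoptosis-score per cell
  (z-score units, antisymmetric under swapping the sets). The bundled
  proliferation/apoptosis GMT lists are editable defaults of canonical
  cell-cycle and apoptosis genes.

## The synthetic generator

`trmtime.synth` emulates a droplet scRNA-seq time course of FACS-sorted
antigen-specific CD8+ T cells: by default 10 timepoints at days
0, 2, 5, 10, 15, 20, 25, 30, 45, 60; two resident (skin, siIEL) and two
circulating (dLN, spleen) compartments; 200 cells per sample; 1,000 genes;
log-normal library sizes (log-mean 9.2 ≈ 10k counts per cell, log-sd 0.3).

Each gene's log2 intensity is linear in scaled time (increasing/decreasing
classes), a Gaussian bump peaking at an interior timepoint (transient), or
constant (flat). Per-cell counts are negative binomial with mean
proportional to the gene's exp-scale intensity times the cell's library
factor. The NB uses the linear-variance (NB1/quasi-Poisson) form
`var = (1 + α)·mean` with α = 0.5: UMI counts are close to Poisson
conditional on relative abundance, and the NB2 form (`var = mean + mean²/θ`)
would add a gamma-mixing term that does not average out across cells,
leaving pseudobulk trajectories far noisier than real per-timepoint
profiles of this depth.

Further realism choices, each of which maps to a feature the analysis
depends on in real data:

* **Baselines** — log2 baselines ~ Normal(log2(1e6/n_genes), sd 0.6). The
  simulated panel is the moderately expressed signature-candidate stratum
  (roughly CPM 250–4,000), consistent with the `% cells > 5` screen; the
  full transcriptome dynamic range is out of scope.
* **Slope heterogeneity** — per-gene effect sizes uniform in
  nominal×(1 ± 1/3), shared across tissues. Real temporal programs span a
  range of slopes; with identical slopes, row-z-scored signature profiles
  are constant across genes and correlation-based sample clustering is
  degenerate.
* **Residence offsets** — gene-specific baseline shifts with a component
  shared by tissues of the same residence class (sd 0.15 log2) plus a
  tissue-idiosyncratic term (sd 0.05). Epithelial residence and lymphoid
  circulation impose shared programs beyond the temporal ramp; these
  offsets are what make mature resident and circulating profiles
  separable by clustering, as they are in real memory-subset data.

The two-compartment constructor plants: genes increasing in all resident
tissues (a fraction of which also increase in the circulating
compartments — general memory genes), disjoint tissue-specific genes per
resident tissue, and circulating-only genes. The expected temporal
signature is the shared-resident set minus its circulating overlap, and
is emitted alongside the data (`truth.tsv`) so tests never reconstruct it
implicitly.

**What the generator does not emulate** — doublets, ambient RNA, batch
effects, gene–gene correlation beyond the class-level offsets, zero
inflation beyond NB sampling, and the full transcriptome's expression
range. Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of temporal structure under realistic noise,
not robustness to every artifact of real droplet data.

## Known numerical properties

* **Compositional drift.** CPM closure means that when ~5% of the library
  ramps up, nominally flat genes drift slightly negative (~−0.017 log2
  across the course at default conditions), inflating their two-sided
  rejection rate at α = 0.05 to ~0.066. The regression's intrinsic size is
  measured on an all-flat simulation (~0.05). This mirrors real data,
  where library normalization imposes the same closure.
* **Recovery at default conditions** (measured by `trmtime.evaluation`
  over 5 seeds; these sizes keep the full suite under a minute):
  selection sensitivity ≈ 0.93 with empirical FDR < 0.01; end-to-end
  signature Jaccard ≈ 0.86 against truth; memory-phase segregation purity
  1.0; GSEA NES ≈ 2 with empirical p = 1/1001 at 1,000 permutations.
* **Determinism.** All stochastic steps (simulation, pseudo-replicate
  splitting, GSEA null, cell subsampling) take explicit seeds; pipeline
  outputs are sorted and hashed, and identical configs reproduce identical
  manifests.
* **Degenerate inputs.** Exact-line fits get p = 0 and a degenerate flag
  rather than dividing by a zero standard error; zero-variance vectors in
  correlations return flagged results rather than silent NaNs; empty QC
  results, zero-total pseudobulk columns and missing markers raise errors
  naming the offending item.

## Open design points resolved here

* The slope unit behind the 0.15 threshold is not tied to days; `scaled01`
  is the default encoding (rationale above).
* All timepoints present for a tissue enter its regression; no phase
  exclusion.
* "Expression" for QC means raw count > 0; the minimum-genes cutoff
  (default 200 for real data, 0 in the synthetic pipeline where no
  low-quality cells are simulated) is explicit and logged.
* BH correction is applied per tissue across genes passing the minimal
  expression screen (pct > 0), recorded in provenance.
* The GSEA flavor (sign-matched NES normalization, add-one two-sided
  empirical p) and the two-group ranking statistic are declared
  conventions; reported NES values are implementation-dependent.
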