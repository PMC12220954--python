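# trmtime

Temporal derivation and validation of tissue-resident memory T cell (T_RM)
gene signatures from single-cell RNA-seq time courses.

## The problem

Memory T cells that take up long-term residence in barrier tissues (skin,
gut epithelium) differ transcriptionally from circulating memory subsets
(T_CM, T_EM), but signatures built by contrasting fully differentiated
end states miss the genes whose defining feature is a *gradual* rise as
effector cells transition to residence over weeks. Given antigen-specific
CD8+ T cells profiled at ~10 timepoints spanning days 0–60 after infection
in several compartments, `trmtime` derives a temporal T_RM signature:

1. **Pseudobulk.** Cells are summed per (tissue, timepoint) and normalized
   to `log2(CPM + 1)`.
2. **Temporal linear model.** For each gene *g* in tissue *t*, ordinary
   least squares fits

   `log2 CPM_g(τ) = β0 + β1 τ + ε`,

   with τ the day mapped affinely onto [0, 1]. Two-sided p-values come from
   the t-distribution on n−2 df and are Benjamini–Hochberg corrected per
   tissue. A gene is temporally associated when `q < 0.1`, `β1 > 0.15` and
   it is detected in more than 5% of the tissue's cells.
3. **Consensus and subtraction.** The consensus resident program is the
   intersection of the per-tissue temporal sets for resident compartments;
   subtracting the analogous circulating-memory (T_CIRC) consensus yields
   the temporal T_RM signature.
4. **Validation.** Signature scoring (mean of row-z-scored expression),
   hierarchical segregation of labelled samples (1−Pearson distance,
   average linkage, 2-way cut purity), preranked GSEA with a seeded
   permutation null (running-sum ES, sign-matched NES, add-one empirical p,
   leading edge), one-vs-rest AUC markers, one-vs-all pseudobulk DE,
   profile correlations and a proliferation-vs-apoptosis growth score.

A negative-binomial simulator (`trmtime.synth`) generates full time courses
with known per-gene temporal classes (increasing / decreasing / transient /
flat), so every stage is testable against ground truth without any
downloads.

## Worked example

Simulate a four-compartment time course (two resident, two circulating
tissues; 1,000 genes; 200 cells per sample) and run the whole pipeline:

```sh
cat > run.yaml <<EOF
outdir: trm_run
seed: 1
simulate:
  n_genes: 1000
  cells_per_sample: 200
EOF
trmtime run --config run.yaml
```

which prints the gene counts at each derivation stage:

```json
{"consensus": 43, "final_signature": 36, "removed_by_tcirc": 7,
 "selected_dLN": 37, "selected_siIEL": 72, "selected_skin": 76,
 "selected_spleen": 36}
```

Read: 76 and 72 genes pass the temporal thresholds in the two resident
tissues, 43 of them in both (the consensus); 7 of those are also part of
the circulating-memory program and are removed, leaving a 36-gene temporal
T_RM signature (the simulation's ground truth plants 40 such genes).
`trm_run/validation.json` holds the downstream checks on the same run:

```json
{"gsea_nes": 2.088, "gsea_p": 0.000999, "segregation_purity": 1.0,
 "truth_jaccard": 0.854, "n_leading_edge": 18, ...}
```

The signature separates resident from circulating memory-phase pseudobulk
samples perfectly (purity 1.0), is strongly enriched in resident over
circulating cells (NES 2.09, empirical p = 1/1001 at 1,000 permutations),
and matches the planted ground-truth set with Jaccard 0.85. All stage
outputs (pseudobulk tables, per-gene fits, signature TSV/GMT) are written
under `trm_run/` together with a SHA-256 manifest; re-running the same
config reproduces identical hashes.

Every stage is also available on its own (`trmtime simulate|qc|pseudobulk|
fit|signature|gsea|markers|segregate|growth`) and as library functions.

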