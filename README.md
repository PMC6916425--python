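# microgliaseq

Comparative bulk RNA-seq analysis of developing microglia — the
brain-resident macrophages — across larval timepoints and across species.

Microglia colonize the zebrafish brain around 3 days post fertilization
(dpf) and differentiate rapidly over the following days.  Sorted-cell
RNA-seq of microglia at 3, 5 and 7 dpf, contrasted against other brain
cells and against microglia profiles from other datasets and species, asks
two questions this package answers quantitatively:

1. **Which genes change during larval development, and how?**  Pairwise
   differential expression between the three timepoints, followed by
   classification of the significant genes into six temporal expression
   groups (higher early, higher late, transient peaks and dips).
2. **Is the microglia gene signature conserved?**  Ortholog-mapped
   comparison of the larval microglia profile to a reference microglia
   dataset: Pearson correlation of mean expression per timepoint, a formal
   test of which timepoint correlates best, and hypergeometric enrichment
   of the overlap between the two datasets' microglia-specific gene lists.

## Methods at a glance

* **Normalization** — median-of-ratios size factors
  `sf_j = median_g counts[g,j] / (prod_j' counts[g,j'])^(1/m)` over genes
  detected in every sample, then a pseudocount log transform
  `log2(count/sf + 1)` (an explicit stand-in for a regularized log
  transform).
* **Differential expression** — per-gene negative-binomial model
  (Var = μ + αμ²) with method-of-moments dispersions shrunk toward a
  fitted `α(μ) = a₀ + a₁/μ` trend; Wald test of the log2 fold change
  between group means, Benjamini–Hochberg correction; genes selected at
  FDR ≤ 0.05 and fold change ≥ |2|.
* **Temporal groups** — each selected gene's sign triple over the 3v5,
  3v7 and 5v7 contrasts is mapped through a priority-ordered decision
  table to one of six groups (G1 high-at-3 … G6 high-at-3-and-7).
* **Cross-species** — ortholog pairing (1:1 / 1:many policies), joint
  renormalization of both datasets on the shared ortholog rows, Pearson r
  of log-scale replicate means, and the Hotelling–Williams t-test
  (df = n − 3) for whether two correlations sharing the reference differ.
* **Overlap enrichment** — upper-tail hypergeometric p for the overlap k
  of lists of sizes K and n in a universe of N, with fold enrichment
  `k·N/(K·n)`.
* **qPCR** — comparative-Ct quantification, fold = 2^(−ΔΔCt).
* **Synthetic data** — seeded negative-binomial generators that plant DE
  genes, pure temporal patterns and a cross-species conserved signature,
  with truth tables for end-to-end validation.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a two-species experiment with a planted microglia signature that
is 80% conserved, then run the full pipeline:

```sh
microgliaseq simulate dual --seed 11 --n-genes 1500 --conservation 0.8 \
    --signature-size 100 --outdir demo
cat > demo/pipeline.yaml <<EOF
counts_a: counts_a.tsv
design_a: design_a.tsv
counts_b: counts_b.tsv
design_b: design_b.tsv
orthologs: orthologs.tsv
outdir: run
seed: 11
EOF
microgliaseq run-all --config demo/pipeline.yaml
```

`run/xspecies_correlations.tsv` then holds the per-timepoint correlation
with the reference microglia profile:

```
group        r  n_pairs   policy
 3dpf 0.871653     1350 max_mean
 5dpf 0.872633     1350 max_mean
 7dpf 0.873945     1350 max_mean
```

All three timepoints correlate strongly with the reference (the generator
makes ortholog baselines covary), and the Williams tests in
`run/xspecies_williams.tsv` correctly find no significant difference
between them (p ≥ 0.22).  `run/overlap_enrichment.tsv` shows the planted
conservation:

```
timepoint    N   K   n  k      fold            p  shared_percent
     7dpf 1336 101 103 81 10.402384 3.175624e-89       78.640777
```

Of N = 1336 ortholog pairs detected in both species, the 7 dpf microglia
list (K = 101) and the reference microglia list (n = 103) share k = 81
genes — a 10.4-fold enrichment over the ≈ 7.8 pairs expected by chance,
recovering ~79% of the reference list, in line with the 80% planted
conservation.

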