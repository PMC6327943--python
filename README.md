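# tadreg

Statistical analysis of diet-responsive gene expression organized by
topologically associated domains (TADs).

In paired brain-region expression studies (the same mice assayed in frontal
cortex, striatum and hypothalamus under a control vs. an energy-dense
free-choice diet), transcriptional responses come in two regimes: a
switch-like regime of differentially expressed (DE) genes with |fold change|
≥ 1.5–2, and a "fine-tuned" regime of genes with subtle changes (|log2FC|
≈ 0.2–0.4) that correlate tightly (|ρ| > 0.9) with body-weight and
behavioral phenotypes.  `tadreg` asks whether these per-gene scores are
organized by the chromatin domain structure: do log2 fold changes and
phenotype correlations distribute across TADs non-randomly, are responsive
genes concentrated in a small set of *regulated* TADs, and are they
sign-coherent (coregulated) within those TADs?

The package is aimed at computational biologists who want these domain-level
permutation tests as tested, reusable components, together with a synthetic
data generator that plants all of the above structure with known ground
truth, so every stage can be validated end to end at desk scale.

## The statistics at the core

* **Moderated-t differential expression.**  Within a region, per-gene
  log2FC = mean(CM) − mean(SC); variances are shrunk by empirical Bayes
  (scaled inverse-chi-square prior; d₀ and s₀² by method of moments on
  log s²_g), giving t = log2FC / (s̃_g √(1/n₁+1/n₂)) with d₀ + d_g degrees
  of freedom and Benjamini–Hochberg adjustment per region.
* **Phenotype correlation.**  PCA composites (body weight, compulsivity)
  plus three raw variables are correlated with every gene by Spearman ρ;
  p-values via the Fisher z transform, z = atanh(ρ), SD 1/√(n−3); selection
  requires BH-adjusted p < 0.05 *and* a ≥ 10% group change on the linear
  intensity scale.
* **TAD conformance.**  Kruskal–Wallis H of per-gene scores grouped by TAD
  (TADs with ≥ 5 genes), compared against B permutations under two null
  schemes: re-dealing genes into TADs with fixed per-TAD counts, or
  re-shuffling (TAD length, downstream gap) pairs per chromosome with gene
  positions fixed.  Empirical p = (#{H_perm ≥ H_obs} + 1)/(B + 1).
* **Regulated TADs.**  Counts of responsive genes (DE ∪ correlating, union
  over regions) per TAD are fitted with Poisson / power-law / geometric /
  log-normal families (AIC-ranked); a TAD is regulated when the fitted
  log-normal survival probability P(X > n_t) < 0.05.
* **Intra-TAD coregulation.**  Per regulated TAD, D_t = |#up − #down| over
  responsive genes; the mean D̄ is tested by re-dealing the signed genes
  across the TADs' slots, p = (#{D̄_perm ≥ D̄_obs} + 1)/(B + 1).
* **Set statistics.**  Szymkiewicz–Simpson coefficient |A∩B|/min(|A|,|B|),
  exclusive Venn counts, Fisher's exact overlap tests, and a generic
  hypergeometric over-representation engine for user-supplied GMT
  collections.

## Worked example

Simulate a full-scale study (3 chromosomes × 50 TADs, ~5000 genes, 4 mice
per diet assayed in 3 regions, 10 planted regulated TADs) and run the whole
pipeline:

```sh
tadreg simulate --seed 5 --out sim/
cat > cfg.yaml <<EOF
seed: 202
out_dir: run/
simulate: {}
B: 200
EOF
tadreg run --config cfg.yaml
```

Typical output for one region (from `run/` on such a study):

```
de_HT.csv                      190 DE genes (|FC| >= 1.5, q < 0.05)
conformance_HT_log2fc_gene_reassign.json
    observed_H = 241.6, mean permuted H = 149.4, empirical p = 0.004975
conformance_HT_log2fc_border_shuffle.json
    observed_H = 241.6, mean permuted H = 185.2, empirical p = 0.004975
regulated_tads.json            9 regulated TADs (log-normal tail, alpha 0.05)
coregulation_HT.json           mean deviation 6.89, p = 0.004975
```

Read: the observed H sits far above both permutation nulls — the empirical
p equals the 1/(B+1) floor at B = 200 — so the fold-change profile conforms
to the domain segmentation; shuffling borders (which keeps gene positions
and hence partial domain overlap) weakens the null less than re-dealing
genes, as expected.  Nine of the ten planted regulated TADs are recovered,
and their responsive genes are strongly sign-coherent (a mean deviation of
6.9 over ~10-gene TADs means most genes in a TAD move the same way).

Each stage is also exposed as a library function
(`tadreg.fit_de`, `tadreg.conformance_test`, `tadreg.select_regulated`,
`tadreg.coregulation_test`, ...) and as individual subcommands
(`tadreg diffexpr|correlate|map-tads|conformance|regulated-tads|coregulation|overlaps|enrich`).

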