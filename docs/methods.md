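# Methods

This note documents the statistical models implemented in `tadreg`, the
design of the synthetic-data generator, the numerical choices that matter,
and what the test suite does and does not establish about real data.

## Study design being modelled

A paired two-diet design: N mice per diet (default 4; standard chow SC vs
energy-dense chocolate-mixture CM), each assayed in three brain regions
(frontal cortex FC, striatum ST, hypothalamus HT), with per-mouse phenotype
measurements (body weight, grooming, nesting, limited-access intake,
quinine-adulteration intake, total energy intake, eating rate).  Expression
values are background-corrected log2 intensities; probe-level input is
supported (negative-control filtering, replicate averaging to a
one-value-one-gene matrix) but the synthetic generator emits gene-level
matrices directly.

## Differential expression

Within one region the contrast is CM − SC on log2 intensities, so the
effect is a log2 fold change.  Because mouse and diet are confounded within
a region, the per-region two-group contrast is unbiased and a joint
multi-region fit with a shared within-mouse correlation is deliberately out
of scope; the mouse pairing matters only across regions, which no
within-region contrast touches.

Variance moderation follows the standard empirical-Bayes scheme: a scaled
inverse-chi-square prior on the true residual variances, hyperparameters
(d0, s0²) estimated by the method of moments on log s²_g using
digamma/trigamma identities, and the trigamma inverted by Newton iteration.
Two boundary conventions were adopted after cross-checking against the
Bioconductor reference implementation of the same estimator on a shared
fixture (the test suite keeps that cross-check): when the observed spread
of log-variances is below the pure chi-square noise level the prior df is
infinite and the prior variance is the arithmetic mean of the sample
variances; and the total df d0 + d_g is capped at the pooled residual df,
since the prior cannot carry more information than the genes that built it.
Forcing d0 = 0 recovers the ordinary two-sample t exactly; d0 = ∞ uses s0²
for every gene.  All-constant genes get t = 0, p = 1 (logged, not an
error).

DE selection uses per-region thresholds on the linear fold-change scale
(|FC| ≥ 1.5 with q < 0.05 for hypothalamus; |FC| ≥ 2 with q < 0.01 for
frontal cortex and striatum) — the pipeline defaults.

Multidimensional scaling uses the leading-log2FC distance: for each sample
pair, the RMS of the 500 largest absolute per-gene log2 differences
(selected per pair, ties broken by gene order), followed by classical
metric MDS (double centering + eigendecomposition).

## Phenotype correlation

Five analysis variables: a body-weight composite (PC1 of final weight and
% gain), a compulsivity composite (PC1 of grooming, nesting, three
limited-access intake days and quinine intake), inflexibility (quinine
intake), total energy intake and eating rate.  Composites are PC1 scores of
z-scored variables; the first listed variable's loading is constrained
non-negative; mice with missing values are dropped (not imputed), with the
dropped ids logged.

Per gene: Spearman ρ (average-tie midranks, pooled across both diet groups
within a region), two-sided p from the Fisher z approximation
2(1 − Φ(|atanh ρ|·√(n−3))), BH-adjusted across genes within one
(region, variable) family.  At n = 8 the z approximation is compared in the
test suite against the exact 8!-permutation null and agrees within a factor
of two.  Selection additionally requires the linear-scale group change
|mean_lin(CM)/mean_lin(SC) − 1| ≥ 0.10, computed on antilogged values;
"percent change" reads most naturally on the linear intensity scale.

## Gene-to-TAD assignment

Intervals are 0-based half-open throughout; a gene whose anchor equals a
TAD's end lies outside it.  The anchor is the TSS (start on '+', end − 1 on
'−'), with the gene-body midpoint available as an alternative; genes
spanning borders are resolved purely by anchor.  TAD-level statistics use
only TADs holding ≥ k genes (default 5).

## TAD conformance test

Observed statistic: Kruskal–Wallis H of per-gene scores grouped by eligible
TAD, with midrank ties and the tie-correction divisor; the chi-square
p-value (df = #TADs − 1) is reported alongside.  Two permutation nulls:

* **gene_reassign** — a uniformly random re-partition of the in-TAD genes
  into the same TADs with identical per-TAD counts;
* **border_shuffle** — per chromosome, the sequence of (TAD length,
  downstream gap) pairs is re-ordered uniformly at random and laid down
  from the first original TAD start, so the spanned interval and the
  length/gap multisets are conserved exactly; genes keep their coordinates
  and are re-assigned, and the ≥ k filter is re-applied inside every round
  (disable with `refilter=False`).

Empirical p = (#{H_perm ≥ H_obs} + 1)/(B + 1); the raw descending rank of
H_obs is also reported.  Border shuffling is per chromosome because
length+gap pairs cannot move across chromosomes without changing spans; the
leading gap before the first TAD is kept fixed.

Two properties of this comparison deserve emphasis, both established while
calibrating the test:

1. *Scores must cover all genes.*  The border scheme re-groups every scored
   gene; restricting scores to the genes eligible under the observed
   segmentation starves the permuted groupings (fewer groups, fewer genes)
   and inflates H_obs relative to the null.  The pipeline always scores
   every gene, and `conformance_test` restricts the annotation to scored
   genes symmetrically.
2. *Raw H is only comparable across groupings when gene placement is
   exchangeable with the border process.*  If gene density itself is
   organized by the true domains (dense domains, empty gaps), shuffled
   borders systematically capture fewer eligible TADs, and the comparison
   partially detects that organization even when scores are independent of
   domains.  The generator therefore places genes as an inhomogeneous
   Poisson process whose rate is length-proportional, which makes the null
   exchangeable; under it, both schemes reject at 0.04–0.06 at the nominal
   0.05 over 200 fresh null datasets (B = 200).  Type-I error is assessed
   over fresh genomes per replicate because p-values conditional on a
   single fixed genome are not uniform even under exchangeability.

## Regulated TADs

Responsive genes (DE ∪ correlating, union over regions and variables,
counted once per TAD) give per-TAD counts; TADs with zero responsive genes
are excluded, so the fit sample is zero-truncated.  Four families are
fitted by maximum likelihood on the positive counts: zero-truncated
Poisson (Newton solve of λ/(1−e^{−λ}) = mean), discrete power law with
x_min = 1 (zeta normalization, bounded scalar optimization), geometric on
{1, 2, ...} as the discrete exponential, and log-normal fitted on log
counts (continuous approximation; a zero-truncated discretized likelihood
over bins [k−½, k+½] is available behind `discrete_lognormal=True`).
Families are ranked by AIC; on 2000-count samples the generating family
(Poisson vs log-normal) is identified in ≥ 95% of seeds.

Selection: TAD t is regulated iff the fitted survival function P(X > n_t)
< α (default 0.05), which formalizes "the probability of another TAD
exceeding this count by chance".  Selection is monotone in the count and
nested in α.  The log-normal family is forced for selection (configurable)
regardless of the AIC winner, mirroring the analysis this package
re-implements.

## Intra-TAD coregulation

For one region, each regulated TAD containing ≥ 1 responsive gene
contributes D_t = |#up − #down|; the statistic is the mean over those TADs.
The null re-deals the pooled signed genes uniformly across the same TADs'
slots (slot counts fixed), so a globally unbalanced sign pool (e.g. mostly
upregulated genes) does not masquerade as coherence.  p = (#{D̄_perm ≥
D̄_obs} + 1)/(B + 1), with ties counting against rejection.  The default
pool is the responsive genes already inside regulated TADs; `pool="all"`
draws from the region's whole responsive set instead.  Cross-region sign
reversal is reported descriptively (`sign_balance_table`), not tested.

## Synthetic data generator

`make_genome` lays down, per chromosome, log-normal TAD lengths (median
800 kb, σ = 0.45) separated by log-normal gaps (median 100 kb, σ = 0.6),
defaults 3 chromosomes × 50 TADs.  Genes are placed by an inhomogeneous
Poisson process: base density = mean genes per TAD (default 33, giving
~5000 genes) divided by the mean TAD length, modulated by a per-TAD
log-normal multiplier (σ = 0.3).  Realized counts are a Poisson-log-normal
mixture — heavy-tailed, and scaling with TAD length, which real genomes do
and the border-shuffle null requires (see above).  A configurable 5% of
genes sit in inter-TAD gaps.

`make_study` builds expression as

    y_{g,m,r} = baseline_g + region_offset_{g,r} + mouse_offset_{g,m}
              + δ_{g,r}·1[diet(m)=CM] + β_g·s_{g,r}·score_{v(g),m}
              + N(0, noise_sd)

with the mouse offset (SD = noise_sd/2) shared across regions, reproducing
the within-mouse correlation that the paired design blocks on.  Planted
structure: `n_regulated_tads` TADs (default 10) receive
`responsive_per_tad` responsive genes (default 10), split between
switch-like DE effects (|log2FC| uniform on [0.6, 2.0]) and subtle
correlating effects; signs follow a per-TAD base sign with probability
`within_tad_sign_coherence`, and the hypothalamus flips sign relative to
cortex/striatum when `cross_region_sign_flip` is on.  A further
`n_scattered_responsive` genes (default 300) are planted uniformly across
the genome; they provide the heavy-tailed background of the per-TAD
responsive counts.

Phenotypes: two latent factors per mouse (body-weight and compulsivity
families, loading 0.9) shifted by ~2 SD in CM mice, plus two standalone
variables with the same effect size; the strong shift keeps the realized
diet contrast of every planted score positive at n = 4 per group, so
planted signs are the up/down direction in CM.  Correlating slopes are
sized so the realized CM−SC expression contrast equals the drawn magnitude;
magnitudes are triangular(0.2, 0.3, 0.4) rather than uniform — the subtle
regime is a unimodal pile-up inside the band, and an edge-loaded uniform
would smear half its mass below 0.2 once the ~0.08 estimation SE (4v4 mice,
noise 0.1) is added.

`noise_sd` defaults to 0.1 log2 units: the value at which planted subtle
effects (|log2FC| ≈ 0.3) reach |ρ| > 0.9 at 8 mice, i.e. the regime the
fine-tuned genes are reported to occupy.  At n = 8, |ρ| > 0.9 also occurs
by chance at the fixed combinatorial rate of 0.46% of null genes (~23 per
5000 genes per region×variable); these chance genes inherit a noise-driven
|log2FC| ≈ 0.14 because a high sample correlation with a diet-separated
score implies alignment with the diet gap.  The effect-regime experiment
therefore plants only correlating effects (`de_fraction=0`) and aggregates
the high-|ρ| histogram across all regions and variables, which is how the
original figure is constructed.

What the generator does *not* emulate: probe-level array chemistry and
normalization artefacts, cell-type mixture within regions, correlated
expression between neighboring genes beyond the planted TAD effects,
missing phenotype data patterns, and any real Hi-C contact structure.
Passing tests show the statistics behave correctly under the stated
generative model, not that real data satisfies that model.

## Problem sizes and runtime choices

Full-scale synthetic studies use ~5000 genes, 150 TADs, 24 samples;
permutation counts are B = 200 in tests and the acceptance script (B = 1000
is the pipeline default for real use).  Calibration sweeps use a reduced
genome (2 × 15 TADs, ~240 genes) with 200 replicates; recovery sweeps use
20–50 seeds.  These sizes were chosen so the complete suite runs in a few
minutes on one CPU while keeping every Monte-Carlo margin comfortably wide.

## Numerical details

* BH adjustment: step-up with reverse cumulative minimum, capped at 1;
  ties and ordering are stable (mergesort).
* Empirical p-values always use the (k+1)/(B+1) convention and therefore
  never return 0; permutation streams derive from `numpy` PCG64 with
  per-stage seeds hashed from the master seed (SHA-256, < 2³¹), so adding a
  stage never perturbs another stage's stream.
* Fisher z p-values underflow to 0 at |ρ| = 1 (atanh clipped at 1 − 1e−15);
  this is reported as-is and documented as an underflow floor.
* Zero-variance genes: ρ = 0 with p = 1 (logged); all-constant genes in DE:
  t = 0, p = 1 (logged).
* Expression TSVs are parsed with round-trip float precision so write→read
  is the identity.
* MDS keeps only non-negative eigenvalues; duplicated samples land on
  identical coordinates.

## Known limitations

* The border-shuffle comparison of raw H values is exchangeable only when
  gene placement carries no domain organization; on real genomes (gene
  deserts, domain-clustered genes) it partially detects that organization,
  so its p-values there should be read as measuring "domain structure"
  broadly, not expression conformance alone.
* The Fisher z approximation is anti-conservative at very small n; at the
  design's n = 8 it stays within a factor of two of the exact permutation
  p, but exact permutation p-values would be preferable for n < 6.
* The continuous log-normal likelihood on discrete counts slightly favors
  the log-normal for small, heavily tied samples; the discretized
  alternative exists but is slower and was not made the default.
* Per-region contrasts ignore cross-region variance sharing; a joint
  mixed-model fit could gain power for small effects.
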