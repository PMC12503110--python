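# Methods

This note documents the statistical procedures `pleiolink` implements, the
defaults and why, what the synthetic-data generator emulates, and the
numerical choices made where the design was genuinely open. Every number
quoted here is produced by the test suite or `scripts/acceptance.py`;
nothing is asserted that the code does not compute.

## Structural metrics

**Distance procedure.** For each mutation site, the minimum Euclidean
distance is taken from the site's Cα on the β chain to one representative
point per residue of every chain annotated with the partner role. Amino
acids contribute their Cα. Nucleotides have no Cα; the default
representative atom is C1′ (one point per residue, mirroring the Cα
convention), configurable to P or to all heavy atoms, because the
convention actually used for nucleic acids in comparable analyses is
ambiguous. Ties in the minimum are broken by (chain_id, residue_seq)
ascending; insertion codes sort after their base residue number. Alternate
locations: altloc 'A' or blank is used for distance work; both altlocs are
retained by the parser. Only model 1 of multi-model files is read.

The implementation is checked against an exhaustive all-pairs scan
(agreement to 1e-9 Å) and is invariant under rigid rotation + translation
to 1e-6 Å (the residual is float accumulation in the transformed
coordinates).

**Ensemble aggregation.** One observation per structure; structures lacking
a role shrink that role's n rather than being imputed, so per-role ANOVA
denominators vary. The per-role comparison across mutants is a one-way
fixed-effects ANOVA treating each structure's minimum distance as one
observation. Groups with a single observation are an error; identical
values everywhere are flagged degenerate rather than returning F = 0/0.

**Stability.** ΔΔG tables (kcal/mol, positive = destabilizing) are
ingested, never computed. Classification uses the genotype mean against a
configurable negligible band, default ±0.5 kcal/mol: the band exists
because a mean "very close to 0" should not be forced into either class,
and 0.5 kcal/mol is comparable to the per-structure spread of typical
predictors. The band is echoed in the output metadata.

## Differential expression

The estimator is a per-contrast two-group negative-binomial Wald test,
deliberately simpler and fully explicit rather than a DESeq2 re-wrap. With
a full factorial genotype × temperature design, the contrast "mutant at 42
vs 37 °C" estimates the same quantity as the releveled interaction
coefficient of a joint GLM, while keeping every ingredient inspectable:

- **Size factors**: median-of-ratios over reference genes (positive counts
  in all samples), reported unnormalized. Recovery of planted factors on
  synthetic data: Spearman ≥ 0.95.
- **Fold change**: log2 of normalized group means with a ½ pseudocount for
  stability near zero.
- **Dispersion**: per-gene method of moments, (s² − x̄)/x̄², pooled across
  the two groups by degrees of freedom, then floored at the across-gene
  median of these estimates. The adaptive floor is the load-bearing
  numerical choice: at 2–4 replicates the per-gene moment estimate
  routinely collapses to zero, which understates the standard error and
  drives null p-values to ~1e-15. Flooring at the median is the simplest
  form of across-gene information sharing (no trend fitting, no shrinkage
  toward a fitted curve); it is conservative for genes whose true
  dispersion is below the median. Measured consequences: on fully null
  simulations (2,000 genes, 7 genotypes × 2 temperatures × 3 replicates)
  the fraction of genes at padj < 0.05 is ≤ 0.1% per seed; with planted
  |log2FC| = 2 at dispersion 0.05 and n = 4 the DEG gate recovers ≥ 95% of
  planted genes at an observed false-discovery proportion ≤ 0.02.
- **Test**: Wald z = log2FC / SE with the delta-method SE from the NB
  mean-variance relation evaluated on the normalized scale (μ + αμ²), so
  DE calls are an exact function of the normalized matrix — rescaling any
  single sample is absorbed entirely by its size factor. Two-sided normal
  p; BH adjustment per contrast over its tested genes.
- **DEG rule**: |log2FC| > 1 (log2 scale, strictly) and padj < 0.05. Both
  thresholds configurable.

Genes with row sum below 10 across all samples are removed before
everything else. All-zero genes within a contrast are excluded and counted.
Batch correction of counts is out of scope; batch ("experiment") enters the
PERMANOVA design instead.

## PERMANOVA

Bray–Curtis dissimilarity d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) on
normalized counts (validated against scikit-bio to 1e-12). The variance
partition follows the projection form: Gower-center −½D², then sequential
(Type-I) sums of squares for the ordered terms temperature, genotype,
temperature:genotype, experiment, replicate, each SS the trace increment of
the cumulative hat-matrix projection. Pseudo-F tests each term against the
residual; p-values come from free permutation of sample labels with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), default 9,999 permutations.
Restricted/blocked permutation is not used (nothing in the target design
requires it). Terms that add no rank (e.g. a replicate factor aliased by
experiment) are dropped and recorded, never silently absorbed. Term r²
values plus residual sum to 1 by construction (checked to 1e-10). Output
matches vegan's `adonis2(..., by = "terms")` on a fixed fixture to the
printed precision, and the type-I error rate per term on pure-noise data is
within [0.02, 0.08] at α = 0.05 over 400 simulations.

## Preranked GSEA

Genes are ranked by log2 fold change, descending, ties broken by gene id so
the ranking is deterministic. The enrichment score is the classic weighted
Kolmogorov–Smirnov running sum: hits step up by |score|^w (w = 1 default,
configurable 0/1/2) normalized over the set's hits, misses step down by
1/(N − set size); ES is the extremum of largest magnitude (positive wins an
exact tie), and the leading edge is the hits at or before a positive
extremum (after, for negative). Sets are intersected with the ranked
universe before size filtering (default 5–500) so size semantics match the
tested statistic.

Because the input is a preranked list, the null resamples random gene sets
of equal size from the universe (sample-label permutation has no meaning
here). NES divides ES by the mean |null ES| of matching sign; the nominal p
is one-sided within the matching-sign null with (1 + b)/(1 + n_same_sign)
smoothing — the denominator is the matching-sign count, not the total
permutation count, which keeps null p-values uniform (KS test against
uniform passes at p > 0.01 on 50 random sets) and never exactly zero. BH
FDR runs across all retained sets. Given a seed, output is bit-identical
across runs.

## Organismal traits

Fitness is the empirical AUC of the OD600 growth curve over 0–24 h:
trapezoid on the observed 10-minute grid, no smoothing, no extrapolation
past the last observed point, in OD·hour units. Blank subtraction is not
applied unless a blank is supplied (whether source curves were
blank-corrected is an acquisition detail, not an analysis one). The
trapezoid at 10-minute sampling is within 0.5% of the closed-form logistic
integral.

Between-temperature deltas use σ_f = √(SEM₃₇² + SEM₄₂²); the interval
delta ± 1.96 σ_f covers the true delta in ~94–95% of simulated draws at
n = 12 (slight undercoverage vs 95% is the usual normal-quantile-for-t
effect). Scalar phenotypes (biofilm OD550, nickel ppb) get a one-way ANOVA
across genotypes on raw values and per-genotype Welch t-tests (42 vs 37 °C)
with BH across genotypes — Welch rather than pooled because equal variances
across temperatures is not worth assuming.

## Cross-level screen

Each link is an OLS fit Var1 ~ Var2 with intercept across per-genotype
values; p is the model F-test (identical to the slope t-test with a single
predictor); adjusted r² = 1 − (1 − r²)(n − 1)/(n − 2). A link is
significant iff adjusted r² > 0.3 and BH FDR < 0.05. The FDR family is all
pairs tested in one screen invocation — the default family crosses the DEG
counts (total/up/down at 42 vs 37 °C) with every structural metric
(per-role ensemble-mean distance, per-role per-structure distance, mean
ΔΔG) and adds ΔAUC × total DEG count: 124 pairs for six mutants over seven
structures and five roles. Correcting across the full family is the most
conservative of the defensible choices (across structures only, across DEG
categories only, full family); the family membership is printed with the
output. With n = 6 genotypes the adjusted-r² gate is volatile (adjusted
r² = 1 − (1 − r²)·5/4); the code warns when n < 6.

## Synthetic data

The generator's defaults are the study conditions: six *rpoB* mutants
(V146F, Q513L, Q513R, S522F, H526Y, S531F) plus wild type; temperatures 37
and 42 °C; two experiment batches; 3 RNA-seq replicates per genotype ×
temperature; 2,000 genes with log-normal baselines (median ≈ 55 counts);
NB dispersion 0.05; size factors uniform in [0.7, 1.4]; planted
temperature-response DEG sets per genotype spanning ~45–380 genes with
|log2FC| = 2 (more up than down in all genotypes except Q513L); 12
replicates of logistic growth per genotype × temperature, sampled every
10 minutes for 24 h with Gaussian noise (σ = 0.01 OD); biofilm (n = 6) and
nickel (n = 3) traits as Gaussian draws; a 7-structure ensemble with 0.3 Å
distance jitter.

Structures are geometric scaffolds, not proteins: mutation-site Cαs sit
150 Å apart; each partner chain carries one short rigidly placed contact
segment per site whose nearest representative atom is at the planted
distance plus N(0, jitter) radial noise, with all other atoms strictly
farther, plus a distant filler helix. A single rigid placement of one
helix cannot satisfy several exact per-site minima at once, so each contact
segment is placed independently; only inter-chain minima matter downstream.
Mutants at the same residue (Q513L/Q513R) necessarily share distances, and
contradictory planted values for one residue are rejected, as are distances
that collide with the site spacing. Written PDB files carry three-decimal
coordinates, so file round trips reproduce distances to ~5e-4 Å; in-memory
ensembles with zero jitter reproduce planted distances exactly.

Batch enters counts as a per-(gene, experiment) multiplicative log-normal
factor (σ = 0.1). A scalar per-sample batch factor would be absorbed by
size-factor normalization and leave the PERMANOVA experiment term with
nothing to detect; gene-specific batch effects are also what real batch
effects look like.

The linked scenario plants the cross-level relation: per mutant, the
nontemplate-DNA distance d (10–35 Å across the five mutated residues) and
the temperature-response DEG count n satisfy n = 50 + 8·d + ε, with ε
scaled so the truth-level R² is 0.9 (slope 0 gives the null calibration
scenario). Draws that would leave a genotype with too few planted genes to
feed the enriched gene-set specs are resampled element-wise, which cannot
induce a spurious distance dependence because the floor is identical for
every genotype. ΔΔG means are fixed independently of DEG counts, planting
the stability↔DEG non-correlation that the screen must not flag.

**What passing does and does not show.** The generator matches the
analysis' own assumptions (NB counts with shared dispersion, Gaussian
traits, exact minimum-distance geometry). Passing therefore demonstrates
correctness of the estimators, their calibration under the stated null,
and end-to-end recovery of planted effects at realistic sizes — not
robustness to dispersion trends, outlier replicates, unbalanced designs,
compositional artifacts, or annotation error in real data. With six
genotypes, a truth-level R² planted at 0.9 realizes anywhere from ~0.8 to
~0.99 in a given draw; end-to-end detection through the 124-pair FDR gate
succeeds in ≥90% of seeds, and the failures are draws whose realized truth
R² is low, not pipeline degradation (measured adjusted r² tracks the
realized truth value closely).

## Reproducibility

A single master seed derives one 31-bit seed per stage via CRC-keyed
`SeedSequence`, so stages can be rerun in isolation and two full runs with
the same seed produce byte-identical tables (asserted in the test suite).
All tables are TSV with a commented metadata header echoing the thresholds
that produced them; each stage writes a JSON manifest with input checksums,
its seed, and row counts. Default problem sizes (2,000 genes, 7 structures,
9,999 PERMANOVA and 1,000 GSEA permutations) complete a full run in well
under a minute on one CPU; the calibration simulations in the test suite
use 199–1,000 permutations and 400 replicates, which is where the
simulated operating characteristics above stabilize.

## Known limitations

- The NB Wald contrast is not DESeq2: no dispersion trend/shrinkage, no LFC
  shrinkage, no independent filtering, no outlier (Cook's) handling. No
  numerical equivalence with DESeq2 is claimed, and none should be
  expected.
- The median dispersion floor is conservative for genuinely low-dispersion
  genes and assumes dispersions are exchangeable across genes.
- PERMANOVA uses free permutation; with strong within-replicate
  correlation a restricted scheme would be more appropriate.
- GSEA p-values are bounded below by the permutation count; deeply
  significant sets saturate rather than separate.
- The screen is univariate OLS per pair; it makes no multivariate or causal
  claims, and with n = 6 the r² gate has high variance by construction.
- ΔΔG values are taken as given; computing them, temperature effects on
  structures, and read-level RNA-seq processing are out of scope.
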