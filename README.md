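# pleiolink

Multi-level analysis of RNA polymerase point mutations: from structure to
transcriptome to organismal fitness.

Rifampicin-resistance mutations in the β subunit of bacterial RNA polymerase
(*rpoB*) are pleiotropic: a single substitution shifts the protein's
stability and its contacts with transcription partners, dysregulates
hundreds of genes, and changes growth, biofilm formation, and transporter
activity — all in a temperature-dependent, genotype-specific way.
`pleiolink` implements the full analysis chain that connects those levels
for a panel of *rpoB* mutants (V146F, Q513L, Q513R, S522F, H526Y, S531F)
measured against a wild type at 37 °C and 42 °C:

- **Structural metrics** — minimum Euclidean distance from each mutated
  residue's Cα to every partner role in a PDB structure ensemble (β′
  subunit, σ factor, template/nontemplate DNA, nascent RNA; nucleotides
  represented by C1′ by default), ensemble aggregation, per-role one-way
  ANOVA across mutants, and ΔΔG ingestion/classification (positive ΔΔG =
  destabilizing).
- **Differential expression** — median-of-ratios normalization, per-contrast
  negative-binomial Wald tests (a mutant's 42 vs 37 °C response, or mutant
  vs wild type within one temperature), DEG calling at |log2FC| > 1 and
  BH-adjusted p < 0.05, UpSet-style exclusive intersections, Bray–Curtis
  distances, and a sequential multi-term PERMANOVA
  (`distance ~ temperature × genotype + experiment + replicate`).
- **Preranked GSEA** — weighted running-sum enrichment scores over gene sets
  (GMT), a gene-set resampling null, sign-matched NES, and BH FDR.
- **Organismal traits** — empirical growth-curve AUC (OD600, trapezoid over
  0–24 h) as fitness, between-temperature deltas with propagated error
  σ_f = √(σ²₃₇ + σ²₄₂) on SEMs, one-way phenotype ANOVA, and per-genotype
  Welch tests.
- **Cross-level screen** — OLS (Var1 ~ Var2) between per-genotype metrics of
  different levels, gated at adjusted r² > 0.3 and BH FDR < 0.05 within the
  declared pair family, emitted as a level-to-level link graph.
- **Synthetic data** — a first-class generator that emulates every input
  with planted ground truth: controlled minimum distances, NB counts with
  genotype-specific temperature-response DEG sets, enriched gene sets,
  logistic growth with closed-form AUC, and a planted linear relation
  between structural distance and DEG count.

## Worked example

Run the whole pipeline on a simulated linked scenario (planted slope of
8 DEGs per Å between nontemplate-DNA distance and temperature-response DEG
count, truth R² = 0.9):

```sh
pleiolink run-all --seed 11 --out run
# run complete: run (24 significant cross-level links)
```

`run/` then contains one directory per stage with TSV tables and JSON
manifests. Highlights from this run:

- `run/de/deg_summary.tsv` — DEG counts per genotype at 42 vs 37 °C; the
  paired test of up- vs down-counts gives t(6) = 6.46, p = 6.5e-4
  (`run/de/updown_t.tsv`): more genes up- than downregulated at 42 °C.
- `run/de/permanova.tsv` — variance partition of the Bray–Curtis matrix:
  r² = 0.33 for genotype, 0.33 for genotype×temperature, 0.026 for
  temperature (each p = 1e-4 with 9,999 permutations): mutant identity, not
  temperature, dominates the transcriptomic response.
- `run/correlate/links.tsv` — the screen recovers the planted
  structural→transcriptomic link: DEG count vs mean distance to nontemplate
  DNA, slope +6.8 genes/Å, adjusted r² = 0.96, FDR = 0.004, while the
  planted-null ΔΔG↔DEG pair is (correctly) not significant
  (adjusted r² = −0.24, FDR = 0.86).

Each stage is also exposed separately (`pleiolink simulate | structure |
de | gsea | organismal | correlate`) and as library functions
(`pleiolink.structures.min_distance`, `pleiolink.transcriptome.permanova`,
`pleiolink.gsea.gsea_preranked`, ...).

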