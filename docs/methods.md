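# Methods

## Model and procedure

Variant Enrichment Analysis treats a patient group's shared exome variants
as draws over genes and asks whether their allocation to a pathway's gene
set departs from an ancestry-matched population reference. The procedure:

1. **Common variants.** A group's case set is the exact intersection of its
   members' variant sets. Variant identity is (chromosome, 1-based
   position, ref, alt) after normalization: `chr`-prefix stripped, alleles
   uppercased, shared suffix then prefix trimmed (the prefix trim advances
   the position). Multi-allelic records are split before normalization.
   Zygosity is ignored: carrying the alternate allele, het or hom, counts
   as "present". Full left-alignment against a reference FASTA is *not*
   performed — within one cohort annotated by one pipeline, minimal
   trimming suffices for key equality, and it keeps the package free of
   reference-genome downloads.
2. **Universe restriction.** The test universe is the union of all pathway
   gene sets. Case variants and background counts outside it are removed
   from both margins, so case and background share one denominator frame.
3. **Per-pathway test.** `case_in` counts *distinct* common variants whose
   gene set intersects the pathway (a variant hitting two genes of one
   pathway counts once there, but may count in several pathways); `bg_in`
   sums per-gene background counts over the pathway's genes. A two-sided
   Fisher's exact test is applied to each 2×2 table; the two-sided p is the
   sum of hypergeometric point probabilities ≤ the observed one within
   relative tolerance 1e-7 (the R tie convention). Enrichment direction is
   read from OR > 1.
4. **Multiplicity.** Benjamini–Hochberg adjustment over all pathways of one
   group's run; the FDR family is per group, because group EP lists are
   formed first and compared afterwards. Enriched ⇔ adjusted p < α
   (default 0.05).
5. **Post-processing.** Venn partition of per-group EP sets (exclusive =
   present in exactly one group's list); ranking by ImportantVar count, by
   OR (> 1.5 and ≥ 1 ImportantVar), or by EPR; optional hypergeometric
   over-representation of a DEG list with a final Venn overlay.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | adjusted-p threshold for the enriched flag |
| `or_threshold` | 1.5 | OR filter in odds-ratio ranking |
| `min_damaging` (k) | 1 | damaging predictor verdicts needed for the score clause of ImportantVar |
| CADD cutoff | 20 (phred) | numeric score counted as a damaging verdict |
| functional-impact classes | nonsynonymous, stopgain, stoploss, startloss | classes that make a variant important regardless of scores |
| `rna_threshold` | 1.0 | RNA evidence level counted as expressed |
| `protein_levels` | Low/Medium/High | protein evidence counted as expressed |
| background `af_threshold` | 0.01 (metadata) | allele-frequency cutoff used offline to call a reference variant "common" |

ImportantVar combines its two clauses by **union** (damaging evidence OR
functional impact), since both independently argue for impact; `k` is
exposed because "multiple algorithm" evidence can reasonably be read as
requiring consensus. Missing predictor data never counts as damaging, so
adding evidence can only move a variant toward importance (monotonicity,
property-tested).

The population background enters **only** as a pre-aggregated per-gene
count table with its ancestry and AF threshold recorded as metadata. An
all-individuals intersection is not computable from a population sites
table; gene-level counts of common variants (AF ≥ 0.01, the standard
population-genetics convention) are the closest well-defined surrogate,
and pinning the threshold into the file's metadata makes the choice data
provenance rather than code behaviour.

"Expressed" for EPR is the OR of RNA and protein evidence: the ratio counts
genes, not evidence channels, so a gene detected on both channels counts
once. EPR is computed for every pathway of a run (not only eEPs) so all
ranking modes operate on one uniform table.

## Numerical choices

- Fisher p is computed by summing hypergeometric pmf values over the
  conditional support; tables with an empty row or column margin are
  undefined and reported as p = 1.
- The odds ratio is the sample OR; when any cell is zero the
  Haldane–Anscombe +0.5 correction is applied to all four cells (for the
  OR only, never the p), keeping OR ranking total instead of producing
  0/∞.
- All result orderings (report rows, rankings, Venn regions, generated
  files) break ties by pathway ID, making every output byte-deterministic
  for fixed inputs.
- Degenerate inputs fail loudly: empty groups, empty pathway databases,
  zero-total backgrounds and case/background sets disjoint from the
  universe are errors, not silent empties.
- VCF records with FILTER other than PASS/`.` are excluded by default
  (configurable); gene symbols are matched after uppercase folding with no
  alias/HGNC resolution (documented limitation); coordinates are taken as
  given, with genome-build agreement across inputs the user's
  responsibility.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *statistical design* of a small-cohort exome
study: a few groups of ~3 individuals, per-gene background variant counts
Poisson(λ = 2), within-group sharing probability s = 0.8 (shared variants
written to every member, private noise at rate λ(1−s) per member), pathway
sizes uniform on 5–30 over a 1000-gene pool with overlap, Bernoulli(0.7)
tissue expression, and annotation calls drawn from a fixed mixture.
Enrichment is planted multiplicatively on the **case** shared-variant rate
of a pathway's genes (background stays at λ) — exactly the alternative the
Fisher table tests; planting can be global or group-specific (a globally
planted pathway can never be Venn-exclusive). Simulated variants are
synthetic keys on a pseudo-chromosome with sequential positions.

It does **not** emulate linkage disequilibrium, mutation spectra,
gene-length variation, annotation errors, population stratification or
batch effects. Passing tests therefore demonstrate correctness of the
statistics and plumbing under the stated sampling model, calibration of the
FDR under independent-gene nulls, and power against multiplicative
planting — not robustness to the correlation structure of real exomes.

Test and acceptance problem sizes (200 pathways × 1000 genes, 200 null
replicates, 50 planted replicates) were chosen as the smallest scale at
which the binomial error bars on the measured rates are meaningfully tight.

## Known limitations

- Gene-level background counts discard within-gene position information;
  pathways dominated by long genes inherit their background load.
- Per-group FDR families mean cross-group comparisons (the Venn stage) are
  descriptive, not jointly error-controlled.
- The DEG list is a user input; no differential-expression computation is
  performed, and the DEG-ORA universe defaults to the pathway universe
  (configurable) rather than an expression-platform universe.
- No permutation or gene-length-corrected null, no covariate adjustment,
  no burden-style rare-variant tests.
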