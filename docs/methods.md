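# Methods

## The problem

Genotype imputation infers untyped SNPs from a sequenced reference panel,
leaving per-SNP, per-individual genotype-probability triplets
`(p0, p1, p2)`. Downstream association tests collapse the triplet into the
dosage `e = p1 + 2·p2` or the best-guess genotype `argmax(p)`. Both lose
calibration information, and the resulting P-values diverge from what the
true genotypes would have given — in both directions. Post-imputation
quality control filters SNPs on an imputation-quality score, classically
IMPUTE info with thresholds 0.3 (permissive) or 0.8 (stringent). Inside
the *midrange* (0.3, 0.8) neither threshold separates true from false
associations at SNP level: a high cut discards real signals, a low cut
keeps spurious ones.

## Spikes

Because of linkage disequilibrium, a real association appears as a spike
of low P-values at neighbouring SNPs, not as an isolated hit. We chain the
positions of suggestive SNPs (P < 5e-7; the genome-wide threshold 5e-8
defines significance, the looser set stabilises spike boundaries) by
single linkage: SNPs fewer than 2 Mb apart, or connected through a chain
of such gaps, share a spike. The algorithm sees only positions, never
P-values. "Fewer than" is strict: two SNPs exactly 2,000,000 bp apart
start separate spikes. Spikes never span chromosomes. Equality with a
brute-force transitive closure is property-tested.

## The Midrange Filter

Each spike is annotated with: format presence (a format is present if at
least one member is suggestive in it), a typed anchor flag (some directly
genotyped member reaches significance), and the extremes `q_min`/`q_max`
of the combined imputation quality over its suggestive imputed members
(members of any present format; typed members carry no imputation
quality). Decision rules, in order:

1. **Typed anchor → keep.** A significant typed SNP secures the signal.
2. **`q_min` < lower threshold → discard.** One badly imputed significant
   member discredits the whole spike.
3. **Best-guess-specific and `q_max` < upper threshold → discard.** A
   signal visible only after flattening the probabilities must show at
   least one high-confidence member, because dosage has more power.
4. Otherwise keep.

Thresholds are compared strictly ("does not meet" = below); a value
exactly at a threshold passes. Raising either threshold can only turn
keeps into discards (monotonicity, property-tested), and the filter
dominates the single-threshold rules: all-below-lower spikes are always
discarded, all-above-upper spikes always kept.

In the practical workflow (`MidrangeFilter(study).fit()` or `run_filter`)
the initial association scan covers typed SNPs plus imputed SNPs at or
above the lower threshold. If significant SNPs emerge, SNPs that the
quality restriction skipped within 2 Mb of a spike are association-tested
in dosage format (follow-up), join the membership when suggestive, and can
drag `q_min` down — this is how an apparently clean spike acquires its
disqualifying low-quality member. Membership only grows. When cases and
controls were imputed jointly, quality must be recalculated per group
first; the per-SNP table entry point (`MidrangeFilter.from_snp_table`)
accepts such recalculated summaries directly.

## Quality measures

All measures are computed per group (cases, controls) and combined with a
rule in {min (default), mean, max}. The minimum is the operative choice: a
SNP imputed well in controls but poorly in cases still produces a biased
test.

- **IMPUTE info**: with `e_i = p_i1 + 2 p_i2`, `f_i = p_i1 + 4 p_i2`,
  `θ = Σe_i / 2N`: `info = 1 − Σ(f_i − e_i²) / (2N·θ(1−θ))`; monomorphic
  columns score 1 by convention; raw negatives (badly calibrated
  triplets) are clipped to 0 and logged.
- **MaCH R²**: population variance of the dosage over `2θ(1−θ)`; may
  exceed 1.
- **Beagle dosage R²**: squared Pearson correlation between dosage and
  best-guess dosage; 0 when either vector is constant.
- **Iam (chance / HWE) and hiQ — surrogates.** The published definitions
  live outside this package; we implement documented surrogates that
  reproduce the stated behaviour: `iam_chance` is the mean normalised
  total-variation distance of the triplets from the uniform triplet (low =
  random imputation); `iam_hwe` the mean normalised TV distance from the
  Hardy-Weinberg triplet at θ̂, clamped to never exceed `iam_chance`;
  `iam_combined = iam_hwe − iam_chance + 1 ∈ [0, 1]`. `hiq` is the
  normalised Gini impurity of the mean triplet (0 for monomorphic
  imputation, 1 for a uniform mean). Surrogate values are *not*
  numerically comparable to published Iam/hiQ thresholds.

No MAF-based exclusion is applied anywhere.

## Association

Per-SNP logistic regression of case status on genotype (dosage or best
guess) plus optional covariates (sex, age, principal components), fitted
by Newton–Raphson (≤100 iterations, score tolerance 1e-8), Wald P-value
on the genotype coefficient. Separation is flagged when the per-SD scaled
coefficient `|β|·sd(x)` exceeds 15 — the scaling matters because
frequency-imputed dosage columns have tiny variance, so genuinely
spurious-but-finite effects have numerically huge raw coefficients;
flagging those would silently delete exactly the false positives the
filter exists to catch. Constant genotypes are marked untestable. The fit
is verified against the statsmodels Logit MLE to 1e-6 relative in the
tests. The Wald statistic was chosen as the common GWAS default; no
genomic control or multiplicity correction beyond the fixed thresholds.

## Synthetic cohorts

The simulator generates the statistical structure the filter needs at
desk scale; it does not attempt population-genetic realism.

- **Haplotype pool**: `2·(panel_size + n_cases + n_controls)` haplotypes.
  Per-SNP allele frequencies are uniform on (0.05, 0.95) with two
  subpopulations perturbed by N(0, 0.04). LD comes from a first-order
  copying process: each allele is carried from the previous SNP with
  probability `1 − ld_decay`, else redrawn at the population frequency.
  `ld_decay=0` gives constant haplotypes, `ld_decay=1` independence.
- **Case–control sampling**: individuals are haplotype pairs resampled
  from one pool half; status follows a logistic disease model with
  per-locus log-odds `log(OR)` under additive/dominant/recessive coding
  and an intercept solved numerically for population prevalence 0.1
  (configurable; chosen to keep rejection sampling cheap). Disease-locus
  MAFs are constrained to [0.05, 0.4]; pools violating it are regenerated
  (capped, logged). Default sizes mirror a small clinical study: 1,000
  per group, panels of 10,000 per group (alternatives 333 cases / 5,000
  panel members).
- **Deletion**: scaffold mode keeps a quasi-regular, frequency-biased
  subset (within each window of `1/fraction` SNPs the most common SNP is
  typed), emulating an array manifest without shipping one; uniform mode
  deletes each SNP with probability 0.8. Disease loci get no protection.
- **Surrogate imputation**: for each individual and untyped SNP, every
  reference individual (haplotype pair from the group's own panel — cases
  and controls use disjoint panels) is weighted `α^mismatches` against
  the individual's typed genotypes over the `k = 8` nearest scaffold
  SNPs; the triplet is the weight-normalised reference genotype
  distribution. α = 0.3: soft enough that a poorly tagged SNP collapses
  toward the panel's genotype frequencies — the low-quality,
  frequency-driven regime in which spurious dosage associations arise
  (small panels then shift group means apart) — while well-tagged SNPs
  still go degenerate. A sharper α pins every SNP to one reference
  individual and that regime never occurs.
- **Truth**: a SNP is truly associated iff the complete (pre-deletion)
  data reach 5e-8; since complete-data triplets are degenerate, one gold
  scan covers both formats. A spike is true iff it contains at least one
  truly significant member — spikes mixing false-positive and
  false-negative members count as true signals.

What the generator does *not* emulate: recombination-map structure,
realistic MAF spectra, phasing error, spatially varying array coverage,
chromosome-specific features (MHC, X/Y). Passing benchmarks therefore
demonstrate that the filter's logic responds correctly to quality
gradients and format asymmetries of this mechanism, not performance on
any particular real array/panel combination.

## Benchmark

`benchmark.run_benchmark` runs 20 replicates (800 SNPs at 25 kb spacing,
300 cases / 300 controls) cycling three regimes: *good* (LD decay 0.02,
panel 600, scaffold 25%), *mid* (0.03, 300, 18%), *bad* (0.08, 50, 12%,
mismatched panel, weak OR 1.5 locus only — with 300 cases the locus is
undiscoverable, so spikes arising there are imputation artefacts,
mirroring the observation that false signals concentrate in
small/mismatched-panel, low-power settings). Filters compared per spike:
per-SNP thresholding at 0.3 and at 0.8 (a spike survives if any
significant member survives; partial survival tracked), and the Midrange
Filter. Replicate sizes were fixed once as the smallest grid that
produces multi-SNP spikes and a usable number of false signals.

## Numerical and degenerate-input choices

- Best-guess ties break to the lowest genotype index (argmax convention).
- Dosage-only VCFs are read by splitting dosage mass between the two
  nearest integer genotypes (documented lossy); multi-allelic records are
  skipped with a warning; coordinates are 1-based throughout; GP values
  round-trip VCFs at 4 decimals (1e-4).
- ROC: thresholds sweep the observed values plus ±∞; discard rule is
  `quality < t`, consistent with the filter; AUC is the trapezoid over
  (1 − specificity, sensitivity), equal to the tie-corrected
  pair-ordering probability. `threshold_at_specificity` returns the
  largest threshold meeting the target, flagging unreachable targets.
- False % is rounded half-up to 2 decimals (printed-table convention).
- Empty imputation windows emit the uniform triplet and are counted.
- The packaged hit list stores P-values on the 1e-6 scale exactly as
  published; a censored `>100` entry parses to +∞. Its loader verifies a
  SHA-256 checksum and the list's invariants (80 rows, 3 typed SNPs,
  every row below 5e-6 in some format). That analysis ran at a 5e-6
  reporting threshold, so the fixture workflow uses 5e-6 as both the
  presence and the operative significance threshold.

## Known limitations

- The Iam/hiQ surrogates support qualitative statements only.
- Spike truth requires gold-standard labels, available only in
  simulation; on real data the filter reports verdicts and reasons so
  discarded spikes can be reviewed rather than silently dropped.
- A spike present in both formats is treated as dosage-detectable; the
  edge case where its best-guess support vanishes after filtering is not
  re-classified.
- Chaining the published 80-SNP list by position alone yields 16 spikes;
  the original per-format bookkeeping that reports 17 is not fully
  specified, and no result here depends on that count.
- Continuous phenotypes, mixed models, meta-analysis, and low-pass
  sequencing adaptations are out of scope.
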