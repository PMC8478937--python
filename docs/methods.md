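# Methods

## Model and procedure

The pipeline treats a cohort variant table as a set of independent
bi-allelic records, each carrying a variant allele frequency (VAF)
estimated over the whole cohort, a single consequence category from a
closed ten-term vocabulary (intronic, upstream, downstream, UTR, missense,
synonymous, splice acceptor, splice donor, start lost, stop gained), and
up to three categorical deleteriousness calls (SIFT, PolyPhen2, PROVEAN).
No linkage, haplotype or transcript-isoform structure is modelled: every
statement the pipeline makes is a marginal statement about single sites.

Classification is a deterministic cascade:

1. **VQSR filter.** Records with a Phred-scaled variant-quality score
   below the threshold (default 35) are dropped. Records without a score
   pass and are counted in the manifest, because frequency-only data
   releases usually do not carry per-variant quality; silently dropping
   them would empty real inputs.
2. **Rarity.** Rare ⇔ VAF < 0.01. The boundary VAF = 0.01 is assigned to
   the common class so that "rare" matches a strict inequality.
3. **Missense consensus.** With k non-missing predictor calls of which d
   are damaging: deleterious iff k > 0 and d/k ≥ 1/2; neutral otherwise;
   with k = 0 the variant is *unclassified* and excluded from both the
   deleterious and neutral tallies. The shrinking denominator is a
   deliberate choice: treating a missing call as tolerated would make
   missingness informative, which it is not.
4. **Loss of function.** Splice acceptor/donor, start-lost and stop-gained
   are putative LoF. An optional CADD PHRED threshold (default: off; 20
   when enabled) can demote splice variants whose score is present and
   below it — off by default because splice deleteriousness assessment in
   the target use case confirmed all splice variants, and no numeric
   cutoff is canonical.

**Aggregated functional-variant frequency.** For gene *g*,
AFF(g) = 100 · Σ VAF over functional (deleterious missense + LoF)
variants, in percent. The sum was chosen over the union-probability form
1 − Π(1 − VAF) because it is additive (adding a functional variant of
frequency v raises AFF by exactly 100·v), exactly zero for genes without
functional variation, and the two forms differ only at second order for
the small frequencies involved; the union form remains available via
`aggregation="union"`. The max/min fold across a panel excludes genes at
exactly zero, otherwise the fold is undefined.

The rare/common split of a gene's functional variation is computed by
variant count; a VAF-weighted alternative exists behind the same API for
sensitivity analysis, since either convention is defensible.

**Percent reporting.** Every reported percentage is
round-half-up(100·x, 1), implemented in decimal arithmetic to avoid
binary-float midpoint surprises. Full-precision fractions are retained
alongside in all outputs.

## Statistics

- **Population comparison.** Published per-population VAFs are converted
  back to allele counts via alt = round-half-up(VAF × AN) where AN is the
  population's total allele number, giving the 2×2 table
  [[alt₁, ref₁], [alt₂, ref₂]]. Pearson chi-square without continuity
  correction is used unless any expected cell count is below 5 (the
  conventional reading of "Fisher's exact test when needed"), in which
  case the two-sided exact test applies. Yates correction is available as
  an option but defaults to off. Tables with a zero marginal (for
  instance an allele absent from both populations) are flagged degenerate
  and reported with p = 1 rather than raising: they occur routinely in
  cross-population tables and carry no evidence either way.
- **Multiple testing.** Bonferroni thresholds α/m at full precision; the
  defaults m = 18 (6 families × 3 regression responses) and m = 72
  (8 variants × 9 comparison populations) reflect the canonical analysis
  design and are overridable.
- **Family comparison.** Tie-corrected Kruskal–Wallis with the chi-square
  approximation on (groups − 1) degrees of freedom. When every
  observation across all groups is identical there is no rank variation
  and H is defined as 0 with p = 1 (the underlying scipy routine refuses
  this case).
- **Length regression.** Ordinary least squares of per-gene counts
  (total, missense, deleterious missense) on gene length in kb, two-sided
  t-test of zero slope; requires ≥ 3 genes and non-degenerate lengths. A
  constant response is reported as slope 0, R² = 0, p = 1.

Family summary dispersion uses the sample (n − 1) standard deviation and
is reported as not-applicable for single-gene families.

## Synthetic cohorts

The generator produces study-condition inputs with known ground truth:

| parameter | default | meaning |
| --- | --- | --- |
| genes_per_family | 16/50/17/26/9/7 | ABC/SLC/phase1/phase2/nuclear-receptor/other — a 125-gene panel |
| length_kb_lognormal | median 35–80 kb, σ = 0.7 | per-family gene lengths; ABC longest |
| variants_per_kb | 5.0 | Poisson density of variants per gene, ≈ 35–40k variants per cohort |
| rare_target | 0.374 | intended fraction of VAF < 1% |
| n_cohort_alleles | 282,862 | 2 × 141,431 diploid genomes; sets the minimum VAF 1/(2N) |
| consequence_probs | ≈ 93.3% non-coding | exonic slice split 41.6/31.3/25.0% missense/UTR/synonymous with a thin LoF tail |
| substitution_probs | C>T 0.253, G>A 0.248 | Ti/Tv ≈ 2.2 |
| p_deleterious_latent | 617/1063 | probability a missense variant is truly deleterious |
| predictor_accuracy / p_missing_call | 0.95 / 0.05 | per-tool observation noise of the latent state |
| p_novel | 0.027 | probability of a missing rs identifier |
| p_low_quality | 0.02 | fraction receiving a VQSR score below threshold |
| fst | 0.1 | Balding–Nichols divergence of population tables |

VAF is a two-bin uniform mixture — Uniform(1/(2N), 0.01) with probability
`rare_target`, else Uniform(0.01, 0.5) — rather than a coalescent site
frequency spectrum: the validation targets only need a controllable rare
fraction, not population-genetic realism. Population tables draw each
population's frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) around the
cohort frequency p, then discretize to allele counts, so every reported
VAF is an achievable count ratio; F = 0 returns p exactly. Consequences
are drawn independently of position and VAF, and predictor errors are
independent across tools given the latent state.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium and haplotype
structure, a realistic site frequency spectrum, correlated predictor
errors (real SIFT/PolyPhen2/PROVEAN disagreements are not independent
coin flips), mutation-rate heterogeneity along genes, VAF–consequence
dependence (real functional variants skew rare through selection; here
rarity and function are independent by construction), and indels (the
generator emits SNVs only, though the pipeline handles indels in real
inputs and excludes them from the substitution spectrum).

Determinism: every operation draws from a named substream of a single
integer seed (stable string-hashed spawn keys), so identical
configurations yield byte-identical files on any platform; the truth
table is written separately and never read by the analysis path.

## Numerical and interface choices

- Coordinates are 1-based inclusive (VCF convention); BED panels are
  converted on read, with the dialect declared by file extension.
- The annotation join key is (chrom, pos, ref, alt) after uppercasing and
  left-trimming the alleles' shared prefix; no other normalization.
- A variant ID of "." or empty marks a novel variant; any non-empty ID
  marks it known.
- Score-valued predictor annotations convert at each tool's published
  default: SIFT < 0.05, PolyPhen2 ≥ 0.446, PROVEAN ≤ −2.5 ⇒ damaging.
- The VCF reader is a purpose-built minimal parser (CHROM, POS, ID, REF,
  ALT, INFO:AF; multi-allelic rows split per ALT) so that allele
  frequencies survive a write/read cycle at 10 significant digits;
  general-purpose htslib bindings store INFO floats at single precision.
  Tests cross-check it against pysam on the bundled fixture.
- UTR variants count as exonic in the overview despite being non-coding,
  matching the usual region taxonomy for panel summaries.
- The run manifest contains the config snapshot, seed, input digests and
  stage counts but no wall-clock timestamps, keeping full-run outputs
  byte-identical across reruns.
- Report floats serialize at 10 significant digits; JSON keys are sorted.

## Validation design and problem sizes

The test suite validates against independent oracles rather than
round-tripping the implementation: the consensus vote against exhaustive
enumeration of all 27 call triples; Fisher p-values against full
hypergeometric enumeration over every 2×2 table with total ≤ 40; the
Kruskal–Wallis statistic against direct rank-sum arithmetic; the
percentage-rounding layer against a set of published numerator/
denominator/percentage triples from a large cohort study of 125
pharmacogenes. Calibration checks run at cohort scale: the rare fraction
at ≈ 40,000 generated variants against 99% binomial bounds; the type-I
error of the population comparison over 2,000 null replicates; recovery
of the latent deleterious state (sensitivity and specificity ≥ 0.85 at
predictor accuracy 0.95, > 1,000 missense variants); recovery of a
planted 5 variants/kb density over 50 genes within the fit's 95%
confidence interval; and Hudson-estimator recovery of the generating
F<sub>ST</sub> within 20% over ≈ 2,000 variants.

## Known limitations

- Star-allele/haplotype-level pharmacogene interpretation is out of
  scope; all results are single-site.
- Predictor scores are ingested, never computed; transcript selection is
  the annotator's responsibility upstream.
- gnomAD per-population allele numbers are not bundled with the
  clinically relevant variant table; contingency tests on it require the
  caller to supply real allele numbers, and the bundled default (50,000)
  is a documented placeholder for illustration.
- The chi-square/Fisher comparison assumes the reconstructed allele
  counts are independent binomial draws, which ignores any shared-sample
  or relatedness structure in the source cohorts.
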