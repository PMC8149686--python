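# Methods

This note documents the models, rules and numerical choices behind hcgkit:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely open.

## Methylation calling

**Conversion filter.**  Bisulfite leaves methylated cytosines unconverted, so
a read from a molecule that escaped conversion reads as methylated at every
cytosine.  In plants, genuine CHH methylation is sparse outside
heterochromatin, so a long run of methylated CHH calls within one read is the
canonical failure signature.  A read is removed when it carries a run of
**more than three** consecutive methylated CHH calls (a run of exactly three
survives).  "Consecutive" is interpreted within the read's subsequence of CHH
calls: intervening CG/CHG calls do not reset the run, because conversion
failure is a property of the whole molecule.  The stricter reading (any
non-CHH call breaks the run) is available as `span_other_contexts=False`.
With a fully-unconverted read fraction *f* and reads carrying ≥ 5 CHH calls,
the residual CHH signal after filtering is far below *f* (the acceptance
script measures it; the property test asserts < *f*/10).

**Per-cytosine levels.**  Counts are accumulated per (chromosome, position,
strand); the level of a site is m = #C/(#C + #T) and is undefined at zero
coverage.  Symmetric CG dyads are *not* merged across strands: accounting is
per-cytosine, matching per-cytosine callers; merging would halve positional
resolution and is left to the caller if wanted.

**Region levels.**  The pooled level of a region is count-weighted,
Σ#C / Σ(#C+#T), which keeps the #C/(#C+#T) semantics at region scale; the
unweighted mean of per-cytosine levels is reported alongside.  Two coverage
regimes exist: targeted-amplicon mode drops cytosines under 20 reads;
everywhere else the per-cytosine minimum is 4 reads, harmonised with the DMR
rule below.

## Bins, ranking, clusters

The genome is tiled with 200-bp bins anchored at position 0 (the grid origin
is a convention; nothing downstream depends on it).  Per bin and context the
table holds pooled counts over cytosines covered ≥ 4× and the number of
contributing cytosines.  Bins with no CG methylation in *any* genotype are
discarded; the rest are ranked by the reference (wild-type) CG level in
**descending** order — percentile 1 is the most-methylated, heterochromatic
end — and split into 100 groups whose sizes differ by at most one bin, with
ties broken by genomic order so reruns are identical.  The four clusters
default to percentiles 1–13, 14–25, 26–43 and 44–100: heterochromatic bins
(hypomethylating under the transgene), bins methylated in all three contexts,
CG-only bins, and previously unmethylated bins.  On other datasets these
boundaries are parameters, not constants.

Open choice: whether ranking should use the raw pooled level or some
coverage-weighted variant.  Pooled counts over ≥ 4× cytosines were chosen for
consistency with the DMR rule; likewise the zero-methylation filter is
evaluated *after* coverage filtering.

## Differential methylation

A bin is a hyper DMR when all three hold in both directions' mirror image:

* ≥ 4 cytosines covered (each ≥ 4 reads) in **both** samples,
* pooled level difference (test − reference) > 0.10,
* two-sided Fisher's exact p < 0.05 on [[m₁,u₁],[m₂,u₂]].

The test is computed by exact integer hypergeometric enumeration (the
point-probability definition), cached per margin triple, so it agrees with
brute-force enumeration to machine precision and is cheap even for the
hundreds-of-reads tables produced by pooled bins.  A two-proportion score
test is available (`method="score"`) for sensitivity analysis.

No multiple-testing correction is applied by default — the rule is an
uncorrected per-bin significance level combined with a hard effect-size
filter, which is what keeps the null rate low (measured ≈ 2% at 6 cytosines ×
20×; the difference filter, not the p-value, does most of the work).  An
optional Benjamini–Hochberg flag exists.

DMR identity across sets is bin identity (same chromosome, same grid start).
All sets live on one grid, so interval-overlap logic would add ambiguity
without adding information.

**Heritability chains.**  The heritable set of a target generation is the
target intersected with the chained intersection of its references
(e.g. heritable(T4−) = T4− ∩ T3+ ∩ T2+; heritable(T5−) = T5− ∩
heritable(T4−)).  Because "percentage heritable" admits two denominators,
both are reported: |heritable| / |∩ references| (primary — the fraction of
the earlier DMRs still present) and |heritable| / |target|.

## Matched controls

For every rank percentile holding k DMR bins, k control bins are drawn
uniformly **without replacement** from the retained, non-differential bins of
the same percentile (with replacement would duplicate genomic regions, which
is meaningless for a background set).  The eligible pool excludes both hyper
and hypo DMRs of the comparison: a control must be non-differential.  The
control histogram over percentiles therefore equals the DMR histogram exactly
for any seed.  A percentile whose pool is too small raises an error by
default; shortfall mode takes what exists and records the deficit — on very
small simulated genomes (few bins per percentile) shortfalls are expected and
say nothing about real-genome behaviour.

## Gene classification and annotation

Gene-body methylation is the pooled CG level over the full annotated gene
span (exon-restricted computation is a flag; the field uses both and the
difference is small for CG).  Classification uses strict inequalities: a
reference level exactly at 3% is in neither gbM-change class, and exactly 40%
or 1% in neither wild-type/epimutant class — the thresholds are printed
values, and the boundary behaviour is documented rather than smoothed.

Control genes are matched on the reference-gbM percentile (±5 percentiles by
default), excluding genes whose bodies overlap any hyper-CG DMR bin, drawn
seeded and without replacement.

Feature annotation assigns each region by its **midpoint** with precedence
promoter > TTS > exon > intron > TE > intergenic.  The promoter is the
strand-aware window [TSS − 1000, TSS + 100); the TTS window mirrors it,
[TTS − 100, TTS + 1000).  Midpoint assignment is deterministic and is the
common annotator behaviour for 200-bp bins; maximal-overlap assignment would
differ only for regions straddling feature boundaries.  Observed/expected
enrichment is the category-frequency ratio against a background set
(typically the matched controls); categories absent from the background get
an undefined (NaN) ratio.

## Profiles and comparisons

Metaplots rescale each region body to 20 relative bins with 2-kb flanks in 10
absolute bins (all configurable; the defaults are plotting conventions, not
results).  Minus-strand regions are reversed so profiles read 5′→3′; bins
with no data are skipped per region; the curve is the across-region mean with
SE = sd/√n.

The genotype comparison takes each region's mean signal over the full region
or its strand-aware 3′ half ("last 50% of the gene body"), averages replicate
tracks within a genotype per region, and applies an **unpaired** Welch
two-sample t-test across genotypes.  Averaging replicates before testing (and
not pooling them) keeps the unit of replication the region.  Degenerate
zero-variance input returns statistic 0 / p 1 with a warning instead of
raising.

## The synthetic generator

The generator produces the statistical structure the analyses assume, not
sequencing realism:

* **Genome**: uniform-random sequence; a central pericentromeric window
  (fraction 0.2 of each chromosome) holding TEs; genes placed without overlap
  on the arms by stick-breaking, 1–4 exons each.
* **Baseline methylome**: gbM genes (30% of genes) carry CG-only body
  methylation at level 0.6 shaped by a smooth dome x³(1−x)² (peak at 60% of
  gene length, within the 40–80% window typical of gene-body profiles); TEs
  carry CG/CHG/CHH at (0.9, 0.7, 0.1); all other sites are 0.
* **Accessibility**: a per-bin covariate in [0,1], high on arms and promoters
  (0.75/0.9), low over the pericentromere (0.15) and a random 30% of gene
  bodies (0.3).  It exists purely so "gains prefer less open chromatin" is a
  testable property of the sampler; it does not model any particular assay.
* **Ectopic gain**: gain regions are single 200-bp bins aligned to the
  analysis grid, so ground truth maps 1:1 onto bins and recovery tests are
  exact.  Eligible bins have ≥ 1 CG site below the saturation level 0.9
  (saturated sites never gain).  Sampling uses weights
  exp(−bias·accessibility) × 4 for gene-body bins, drawn by fixed-size
  systematic PPS so that inclusion probabilities are exactly proportional to
  the weights; `ectopic_gain_rate` is the expected fraction of eligible bins
  gaining.  Gained CG sites get +0.7 (clipped at 1); CHG/CHH are never
  touched.  `calibrated_gain_rate` inverts the sampler's expectation to hit a
  chosen genome-wide mean CG gain exactly, which is how the 3–4%-scale
  genome-wide gain condition is configured.  How strongly gains depend on
  accessibility is not an identified quantity; the bias weight (default 2.0)
  is a free parameter.
* **Inheritance**: retention is **region-level** — each still-retained gain
  region is kept with probability r (default 0.8) each generation and, when
  lost, all its CG sites revert together to baseline.  Heritability is
  tracked at DMR (region) granularity downstream, so per-cytosine retention
  would add unidentifiable noise.  Lost regions stay lost; baseline
  methylation always persists; propagation never creates regions.
* **Reads**: each read covers 10 consecutive cytosines of one strand with
  uniform-random starts (per-site depth ≈ Poisson(coverage, default 8×));
  calls are independent Bernoulli(true probability).  A fraction (default
  0.5%) of reads is emitted fully methylated — the conversion-failure
  signature.  There is no sequence-level read synthesis, alignment error,
  PCR duplication or context-dependent error model.

What passing tests therefore show: the pipeline's rules are implemented
exactly and recover the generative signal (gain location, magnitude,
retention) under binomial sampling noise.  What they cannot show: robustness
to mapping artefacts, coverage biases, chimeric epigenomes or real chromatin
covariates — those require real data.

**Problem sizes.**  The shipped tests and the acceptance script run on
2 × 300–500 kb genomes at 6–20× coverage with ~10³ gain regions.  These sizes
give binomial/ranking granularity fine enough for the stated tolerances
(e.g. a ±0.005 band on a 0.035 mean over ≳ 5·10⁴ shared sites) while keeping
a full run in minutes on one CPU; all pipeline code is vectorised and scales
linearly in genome size × coverage.

**Deterministic tables.**  `expected_counts_table` renders a ground-truth
methylome as a noise-free cytosine table (every site at fixed depth with
round(p·depth) methylated reads).  It is used where read-sampling noise is
not the quantity under study — e.g. isolating retention randomness in the
heritability measurement — and is labelled as such wherever it appears.

## Known limitations

* The bin test models counts pooled across cytosines and strands as
  exchangeable Bernoulli draws; within-bin heterogeneity is ignored, as in
  any pooled-count bin test.
* Percentile ties at level 0 are resolved by genomic order; on sparse genomes
  this concentrates zero-level bins into deterministic percentiles.
* The annotator is midpoint-based and single-isoform; UTRs are not separated
  from exons.
* The simulator's accessibility covariate is a stand-in, not an ATAC model,
  and its coupling strength to gains is a free parameter.
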