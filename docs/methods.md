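# Methods

`chronovar` implements the three analysis arms used to ask whether mouse
genotype shapes circadian gene expression: cosinor rhythmometry with
between-genotype comparison, strain-difference SNV annotation with Grantham
severity classes, and SNP-density analysis in clock-protein binding
regions. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## Cosinor rhythmometry

### Model

For a series y(t) sampled at circadian times t (hours), the
single-component cosinor with fixed period τ = 24 h is

    y(t) = M + A·cos(2π(t − φ)/τ) + ε,   ε ~ N(0, σ²)

with MESOR M (rhythm-adjusted mean), amplitude A ≥ 0 and acrophase
φ ∈ [0, τ) — the clock time of the fitted peak. The model is linear in
(M, β, γ) with β = A·cos(ωφ), γ = A·sin(ωφ), ω = 2π/τ, and is fit by
ordinary least squares; A = √(β² + γ²) and φ = atan2(γ, β)/ω wrapped into
[0, τ). The period is fixed at 24 h throughout; free-running period
estimation and multi-component cosinors are out of scope.

Rhythmicity is the zero-amplitude F test against the intercept-only model,

    F = ((RSS₀ − RSS)/2) / (RSS/(n − 3)) ~ F(2, n − 3) under A = 0,

with a raw-p cutoff of 0.01 by default. Benjamini–Hochberg adjusted values
are available downstream but the raw-p behaviour is the default because
the per-gene cutoff is part of the analysis definition being reproduced.

### Confidence intervals

Amplitude and acrophase intervals come from the delta method on the
(β, γ) least-squares covariance, using t(n − 3) quantiles. The acrophase
of a vanishing amplitude is undefined, so when the fitted A falls below
twice its standard error — or the delta-method half-width reaches half the
period — the phase interval is reported as the full circle and flagged
unreliable. Under a true zero amplitude the flag fires in the large
majority of replicates (the ratio A/se(A) is then roughly the root of a
χ²₂ variable, which falls below 2 about 86% of the time). Bingham-style
conditional-ellipse intervals were considered as an alternative
construction; the delta method was chosen as primary because it yields a
closed-form standard error that the between-genotype Wald tests reuse, and
its empirical 95% coverage at the study design (6 timepoints × 3
replicates, A/σ = 2) sits at 0.955 in the package's own simulation.

### Between-genotype comparison

For a gene rhythmic in both genotypes (non-rhythmic genes yield an
explicit not-comparable record), the phase difference is the circular
difference Δφ = φ_b − φ_a wrapped to [−12, 12) — positive means the second
genotype peaks later — and the amplitude difference is A_b − A_a. Both are
Wald tests with combined delta-method standard errors. The reference
distribution is t with min(n_a, n_b) − 3 degrees of freedom rather than a
normal: at this design's small n the combined Wald statistic is visibly
heavy-tailed (simulated null rejection at cutoff 0.01 was 0.017 with a
normal reference and 0.011 with the min-df t). CI-overlap flags are
reported alongside the tests, since either construction is a defensible
reading of a "95% confidence interval plus p < 0.01" comparison rule; the
Wald flags are primary. Values are assumed already normalized; an
optional log2 transform is deliberately not applied by default.

The sign convention places the reference genotype (129S2 in the default
synthetic cohort) first, so a positive class-mean delay reads "the second
genotype (C57BL/6J position) is phase delayed".

## Grantham scoring and SNV annotation

### Grantham distance

The Grantham distance combines atomic composition c, polarity p and
molecular volume v:

    D(i,j) = ρ·[α(c_i−c_j)² + β(p_i−p_j)² + γ(v_i−v_j)²]^½

with α = 1.833, β = 0.1018, γ = 0.000399 and ρ = 50.723 scaling the mean
over the 190 residue pairs to 100. The package ships the published integer
table as ground truth for annotation and keeps the formula as a
cross-check. The two agree to within one unit of integer rounding on 188
of 190 pairs; the exceptions are Asn–Glu (published 42, formula 40.86) and
Asp–Trp (published 181, formula 190.55), which trace to the original
publication and are preserved as printed because downstream tools and the
literature quote the printed integers.

Severity classes partition the score range at the conventional boundaries:
conservative 0–50, moderately conservative 51–100, moderately radical
101–150, radical ≥ 151. The boundaries are configurable in the sense that
`classify_gms` is a pure function of the score; the defaults are the
widely used four-class convention, since the class names alone do not pin
down the cut points.

### Location classes and coding consequences

Variants are SNVs only (multi-allelic records are decomposed; indels are
skipped with a logged count). VCF positions are 1-based at every
interface; all interval arithmetic is half-open 0-based with one
centralized conversion. Location classes use the vocabulary {exonic,
splicing, exonic;splicing, UTR5, UTR3, intronic, intergenic, ncRNA} with
precedence exonic;splicing > exonic > splicing > UTR5 > UTR3 > intronic >
ncRNA > intergenic across overlapping transcripts. The splice window is
±2 nt (configurable): intronic bases within the window of an interior
exon/intron junction are "splicing", and CDS bases within the window on
the exon side are "exonic;splicing", so a variant in the last CDS base
before an intron carries both labels in one class.

Coding consequences evaluate the substituted codon against the standard
genetic code, strand-aware, reporting the most severe call across
transcripts (stopgain > stoploss > nonsynonymous > synonymous) with
per-transcript detail retained. Notation follows the
`c.<ref><cdsPos><alt>:p.<refAA><aaPos><altAA>` style with ref/alt in
coding-strand orientation. A REF base that disagrees with the genome is a
hard data-integrity error, not a warning.

Category enrichment is a generic one-sided Fisher exact test per category
on the 2×2 membership table, with BH-adjusted values reported; it stands
in for web-service annotation tools, which are out of scope.

### Strain difference accounting

Shared variants (identical chrom/pos/ref/alt in both strains) are removed
before annotation and their count reported. The "difference between
strains" column counts the union of the two strain-unique sets; per-strain
columns count each strain's post-removal set. Both conventions are printed
because the source analysis's exact derivation of its difference total is
not recoverable from any simple set operation on its published per-strain
totals.

## Regulatory SNP density

Binding regions are half-open intervals with a summit (narrowPeak column
10; interval midpoint for plain BED). Per-region counts include a SNP in
every region covering it; aggregate densities de-duplicate by counting
unique positions over the merged region union, so overlapping inputs do
not inflate density. The summit-centered profile re-expresses each
in-region SNP as an offset from the summit (offset 0 = summit), clips the
window to the region extent, and reports per-bin counts, the number of
regions whose extent reaches each bin, and count/(regions × binsize) as
average per-base density; the count column sums to the total in-window SNP
count. Defaults: window ±1,000 nt, bin 50 nt.

Density is also reported in the reciprocal "one SNP per N nucleotides"
form (infinite when no SNPs are observed). The comparison against a
reference density is a two-sided single-sample t test whose sample unit is
the per-factor average density (df = k − 1 for k factors, default seven
clock proteins); a per-region-sample reading of the test is possible by
passing per-region densities instead, since the published description does
not determine the sample unit.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume, plus truth tables.

* **Expression**: values = M + A·cos(2π(t − φ)/24) + N(0, sd²) on the
  study's grid (every 4 h over 24 h, 3 replicates/timepoint). The default
  cohort has 10 core-clock and 15 metabolic genes across two tissues and
  two light conditions; the second genotype is delayed 2.8 h (core clock)
  or 6.1 h (metabolic) with amplitude ratio 0.7, mesor ~U(3, 8), A = 2,
  sd = 0.5 — an A/σ of 4, comfortably rhythmic, matching the regime in
  which the published comparisons operate. Noise is Gaussian on the
  expression scale; qPCR noise is plausibly multiplicative, so a
  log-normal option exists via log-transforming downstream, but the
  Gaussian default keeps planted parameters exactly recoverable.
* **Genome**: one ~100 kb toy chromosome, 16 coding + 4 noncoding genes on
  both strands; coding genes have 3 exons, 30 nt UTRs and a 600 nt CDS
  (200 codons). Variants of every location class and coding consequence
  are planted with generator-side bookkeeping (its own cDNA/codon
  arithmetic), then verified through the annotation module before files
  are written; a disagreement aborts generation. A Per2-like worked case
  (codon 172 = AGT, cDNA 515 G>C ⇒ c.G515C:p.S172T, Grantham 58) is
  planted by default. A configurable shared subset appears in both
  strains' VCFs.
* **Regions**: non-overlapping regions (default 7 factors × 200 × 1.5 kb)
  with jittered summits; SNP counts per region are Poisson at a planted
  per-base rate (default one per 219.6 nt), positions uniform, plus an
  optional Gaussian summit enrichment (sd 100 nt) for profile-shape tests.

What passing these tests shows: the estimators recover the parameters the
model family actually generates, at the study's design and noise scale,
and the interval machinery matches brute-force enumeration. What they do
not show: robustness to non-sinusoidal waveforms, heteroscedastic or
multiplicative qPCR noise, linkage structure or mutation-rate
heterogeneity in real exomes, or ChIP-Seq summit uncertainty. Real-data
headline quantities that depend on the unreleased expression tables and
external variant resources are out of reach by construction and are
covered instead by these planted-truth substitutes.

## Numerical and scale choices

* Least squares via `numpy.linalg.lstsq`; the 3×3 normal-equation inverse
  is well conditioned for any design with ≥ 4 distinct timepoints.
* Degenerate all-constant series return A = 0, p = 1 and a degenerate flag
  rather than raising, so batch runs over gene panels complete.
* A perfect (noise-free) fit has RSS ≈ 0; the F statistic is then treated
  as infinite and p as 0 (amplitude > 0) or 1 (constant input).
* Circular phase differences wrap to [−12, 12) with +12 mapping to −12;
  antisymmetry holds everywhere except that boundary.
* Monte-Carlo problem sizes in the test suite (10,000 null replicates for
  test size, 1,000 for CI coverage, 500 for comparison error rates,
  ~10 Mb for rate recovery) were chosen to make binomial/Poisson error
  small relative to the asserted bands while keeping the suite fast.
* Pipeline outputs contain no timestamps; re-running an identical
  configuration reproduces every file byte for byte.

## Known limitations

* The cosinor assumes sinusoidal waveform and homoscedastic noise;
  asymmetric waveforms bias the acrophase toward the dominant harmonic.
* Delta-method phase intervals degrade near A = 0 (flagged, not fixed);
  conditional-ellipse intervals would be the next refinement.
* The annotator handles SNVs only and one CDS reading per transcript; no
  splice-isoform re-weighting, no indels, no selenoproteins.
* The enrichment test treats genes as exchangeable units; gene length or
  SNV-count confounding is not modelled.
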