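# Methods

## The authentication model

A cell line's identity is treated as a genotype fingerprint over the
unique single-base substitutions curated for it in a reference database
(a COSMIC-style per-line mutation profile). RNA-seq observes that
fingerprint only partially — a variant is visible only if its transcript
is expressed and covered — so the method separates *how much* of the
fingerprint is observed (coverage) from *how well* the observed part
agrees (concordance). The underlying assumption is that concordance at
covered positions is insensitive to expression level: shallower
sequencing removes positions from the overlap but does not bias the
genotypes of the positions that remain. The subsampling module exists to
exercise exactly this assumption.

Genotype matching is allele-level by default: a covered position matches
when the reference's mutant allele is among the sample's called alleles.
Zygosity-strict matching is available (`mode="strict"`) but not the
default, for two reasons: database zygosity annotations are frequently
"unknown", and RNA-seq allelic imbalance (one allele transcribed more
than the other) distorts observed zygosity even in authentic samples.
A confident homozygous-reference call at a reference-mutation position
counts as an overlap and a mismatch — the sample was sequenced there and
demonstrably lacks the mutation. This can be disabled
(`count_hom_ref=False`) to reproduce an alternate-allele-only analysis.

## The filtering stack

`build_profile` applies, in order:

1. **Upstream flags + quality gates.** Calls flagged by the upstream
   caller's filters are dropped, as are calls with Fisher-strand
   FS > 30 (phred-scaled strand-bias evidence; high values indicate
   artefacts) or quality-by-depth QD < 2 (variant confidence per
   informative read). These directions and thresholds follow the GATK
   hard-filtering convention for RNA-seq calls; both are configurable.
   Absent FS/QD values pass in the default lenient mode (hom-ref calls
   legitimately lack both statistics) and fail when
   `fail_missing_stats=True` — absent evidence should not silently pass
   a gate when the input is expected to carry the statistics.
2. **Non-SNV removal.** Indels and MNVs are out of scope for profile
   comparison.
3. **Cluster removal.** Any SNV lying in a window of 35 consecutive
   bases containing ≥ 3 SNVs is removed (positions p, q are
   window-compatible iff |p − q| ≤ 34, i.e. the inclusive-span
   convention of GATK's `-window 35 -cluster 3`). Dense SNV clusters in
   RNA-seq are characteristically misalignment around splice junctions,
   not real variation. Hom-ref and non-SNV records neither count toward
   a window nor get removed.
4. **Depth floor.** Total allelic depth must be ≥ 10 (inclusive: 10
   kept, 9 removed).
5. **Highest-impact selection.** For each annotated transcript, only
   variants reaching that transcript's maximum putative impact
   (MODIFIER < LOW < MODERATE < HIGH) are kept; a variant survives via
   any one of its transcripts. Unannotated calls pass unconditionally.
   Selection happens at profile construction, before any comparison.

Quality gates run before structural filters so that cluster windows are
counted over calls that are at least individually credible. If two
surviving SNVs share a position, the deeper call wins (ties: higher QD,
then input order), and the collision is logged. Each stage logs its
removal count; kept + removed always equals the stage input.

## Comparison outputs and reporting conventions

Percentages are rounded half-up to one decimal at reporting only;
fractions are kept at full precision internally. Concordance over an
empty overlap is reported `NA`, never 0. A contaminant screen with zero
overlap is labelled *indeterminate* rather than clean — absence of
evidence is surfaced, not converted into a verdict; any match over an
overlap of ≥ 2 positions (configurable) raises a contamination warning.
The authentication verdict requires concordance ≥ 0.90 (the threshold
proposed for SNP-panel authentication) over ≥ 25 overlapping positions;
the floor is this package's own guard, set well below the smallest
reference overlap seen in practice for genuine samples but high enough
to reject coincidental perfect scores over a handful of shared
polymorphisms.

Pairwise transcriptome-wide comparisons match *called allele sets* at
shared positions by default (genotype-string equality available), so a
het/hom difference at the same alternate allele still matches under the
default, consistent with the allele-level philosophy above.

## Two-site haplotype classification

A read is informative for a site pair only if it carries an aligned base
at both positions (a spanning deletion makes it uninformative). Bases
matching neither the wild-type nor the mutant allele at either site put
the read in `other`, which is tracked but excluded from the total — the
total column is the sum of the four wt/mut combinations. Replicate
proportions are **pooled** (summed counts over summed totals), not
averaged: averaging per-replicate proportions weights a 70-read
replicate equally with a 163-read one and gives measurably different
numbers. Each alignment record is classified independently; overlapping
mates are not deduplicated (no deduplication rule is defined at this
stage).

## Depth subsampling as a surrogate

The robustness experiment thins every allelic depth d to
Binomial(d, fraction) — each original read surviving independently —
then re-runs filtering and comparison. Alleles whose thinned depth hits
zero are dropped from the genotype (the remaining allele is repeated;
all-zero collapses to hom-ref); genotypes are not re-called beyond this
drop rule, since calling internals are out of scope. This surrogate
preserves the mechanism under test (depth-driven SNV loss versus stable
concordance) but not absolute SNV counts, which for real data would also
depend on alignment and calling at reduced depth; only the curve's shape
and the concordance-stability property are comparable to read-level
subsampling. One seed drives a curve; per-fraction substreams are
derived by fixed offsets, so curves are reproducible point-by-point and
fraction 1.0 reproduces the base pipeline bit-for-bit.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs
with exact ground truth. Defaults are the regime the method targets:
reference profiles of 1000 unique substitutions (real profiles span a
few hundred to a few thousand), expressed fraction 0.4 (transcriptome
coverage of genomic variants observed in practice), discordance rate
0.02 at covered positions (authentic-sample territory; planted half as
wrong-allele calls, half as confident hom-ref calls, exercising both
mismatch paths), per-site depths 10 + NegativeBinomial(mean 40,
dispersion 2), heterozygous zygosity fraction 0.8, and two-site
haplotype ratios ≈ 1:1:1.

Two deliberate design choices keep parameter recovery exact rather than
confounded:

- **Expressed-site depths are floored at 10** (the depth distribution is
  a shifted negative binomial), so an expressed reference position
  always survives the depth gate and recovered coverage estimates the
  expression parameter alone. The depth gate itself is exercised by
  separately planted low-depth calls.
- **Filter fodder lives off the reference grid.** Planted clusters,
  indels, low-depth calls, impact-shadowed pairs and FS/QD gate failures
  are placed in their own regions of the toy chromosome, and reference
  variants sit on a 50-bp grid (wider than the cluster window), so no
  filter removes an expressed reference call and
  (1 − concordance) estimates the discordance rate alone.

The toy genome is a single synthetic chromosome with flat base
composition; no real reference sequence is needed because every
comparison is coordinate- and allele-based. Contaminant admixture is
modelled as each contaminant-profile variant independently generating a
call with probability expressed_fraction × contaminant_fraction, with
depth skewed toward the reference allele as expected of a minority
population. Generated reads have constant quality strings and no
sequencing errors beyond the planted `other`-base fraction.

What passing synthetic tests do **not** show: robustness to real
alignment artefacts (the cluster filter is tested against planted, not
emergent, clusters), to annotation disagreements between tools, to
multi-sample VCF quirks, or to reference profiles with shared ancestry.
The worked-example arithmetic on published benchmark counts complements
this by pinning the statistics' definitions to printed values from real
experiments.

## Numerical choices and problem sizes

Rounding is half-up (ties away from zero) to one decimal for
percentages and to integer for per-million rates, applied at reporting
only. All randomness flows through `numpy.random.Generator` seeded
explicitly; generators are deterministic to the byte under a fixed seed.
Test and acceptance runs use reference profiles of 200–1000 variants,
10–20 simulation seeds, oracle-equivalence sweeps of 1000 random
instances per operation (≤ 500 variants each), and read sets of a few
hundred alignments — sizes chosen so the statistical checks (3 binomial
standard errors) are sharp while the whole suite runs in well under a
minute.

## Known limitations

- Best-match search across a whole profile database is out of scope;
  the caller names the claimed cell line (and optionally a contaminant).
- SAM text only; BAM/CRAM, liftover between assemblies, and VCF writing
  of novel calls are not supported.
- Multi-sample VCFs are read one named sample at a time.
- The VCF reader reports record-level errors with coordinates rather
  than raw line numbers (the underlying htslib parser does not expose
  them).
- Strand normalisation of reference profiles relies on an explicit
  strand column; exports without one are assumed forward-strand.
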