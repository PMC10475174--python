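# Methods

## Scope and data model

`dnvqc` operates on de novo variant (DNV) callsets as flat tables of
records `(sample, chrom, pos, ref, alt)` with 1-based positions and
VCF-anchored alleles (the first REF base is the shared anchor for indels).
Records are validated on read: alleles non-empty, uppercase, over
{A,C,G,T}, `ref != alt`, `pos >= 1`. Chromosome names are normalized by
stripping any leading `chr` prefix case-insensitively and upper-casing
sex/mitochondrial names; the original spelling is preserved and written
back out. Duplicated records are retained — a QC tool should not silently
rewrite a callset — but counted and reported. Strict parsing (first bad
row aborts, with its line number) is the default; a permissive mode skips
bad rows and reports how many, so `records + rejected == data lines`
always holds.

## Variant classification

Class is a pure function of allele lengths: equal length 1 → SNV, equal
length > 1 → MNV, REF longer → deletion, ALT longer → insertion. Indel
length is the net difference `|len(ref) - len(alt)|` (a 1-bp insertion has
length 1); MNV length is the shared allele length. Transitions are the
purine↔purine and pyrimidine↔pyrimidine changes (A↔G, C↔T); the other
eight ordered single-base changes are transversions.

Complex substitutions with unequal lengths both > 1 (e.g. `ATT→GC`) have
no canonical class; the length rule classifies them deterministically
(here: deletion of length 1) and a per-table diagnostic counts indel rows
whose REF and ALT do not share a first base, so non-normalized callsets
are surfaced rather than silently misread. Left-alignment and MNV
splitting are out of scope.

## Summary statistics

Ti/Tv and deletion/insertion summaries internally restrict to SNVs and
indels respectively, so they can be called on mixed tables. Conservation
invariants are enforced by construction: transitions + transversions
equals the SNV count, deletions + insertions equals the indel count, the
12-change spectrum sums to the SNV count. Ratios are stored at full
precision and formatted to one decimal for display; a zero denominator
yields an undefined (None) ratio with a warning rather than an exception
or an infinity. The change spectrum is kept as 12 ordered changes, with
an optional strand-collapsed 6-type view (pyrimidine-reference
convention, A>G folded onto T>C, etc.) for display.

Per-individual counts use the sample standard deviation (n−1). Only
samples present in the table are counted — a variant table cannot attest
samples with zero DNVs — but a roster argument can add them. The density
curve is a Gaussian KDE (scipy) with Scott's-rule bandwidth by default;
bandwidth is a parameter because no single choice suits every cohort
size.

## CpG maps and annotation

A CpG site is defined as **either base** of a `CG` dinucleotide on the
reference forward strand. Both-bases is the standard mutational-hypermutability
reading (the methylated C deaminates, producing C>T on one strand and G>A
on the other); the constant `_CPG_OFFSETS` isolates the rule so a
C-position-only map is a one-line change. The scan is case-insensitive
(soft-masked references work) and characters outside A/C/G/T never
participate, so `N` runs break pairs. Maps are exchanged as BED3
(0-based, half-open, one line per position); merged intervals are
accepted on read and expanded per base. Annotation restricts to SNVs,
marks `at_cpg` by sorted-array membership, and reports
`100 · n_at_cpg / n_snvs`. Chromosomes missing from the map annotate as
False with a warning rather than failing, since references and callsets
routinely disagree about decoy contigs. No CpG-island logic, no strand
resolution, no methylation data.

## Parental-age models

The modelling table has fields `sample, dnm_counts, fatherAge, motherAge`
(ages in years at the child's birth), produced by an inner join of a
count table with an age table; samples on only one side are named in a
warning, and an empty intersection is an error. Two classical forms are
fitted by OLS (statsmodels):

- linear: `dnm_counts ~ fatherAge + motherAge`
- exponential: `log(dnm_counts) ~ fatherAge + motherAge`
  (requires every count ≥ 1, checked at fit time with offenders named)

each with `both`, `father_only`, or `mother_only` predictors. Single-parent
fits re-run the full procedure on the reduced design — they are not
coefficients read off the joint fit. Reported: coefficients, SEs from the
unbiased residual variance, 95% CIs as `estimate ± t(0.975, df)·SE` (95%
is the conventional default; the level is a module constant), plain and
adjusted r², and Pearson correlations of each included age with the
response. Rows with missing ages are dropped (complete-case) with a
warning; rank-deficient designs (constant or collinear ages) are rejected
with a clear error rather than handed to a pseudo-inverse. For plotting,
the exponential fit is drawn as `exp(linear predictor)` with no smearing
correction. Counts are modelled as Gaussian; Poisson/negative-binomial
GLMs and parent-of-origin phasing are out of scope.

## Synthetic data: what it emulates

`SimConfig` defaults are fixed study conditions emulating a human
trio-WGS de novo callset: 139 children at ~70 DNVs each (Poisson), class
weights 8558:643:540:0 over SNV/insertion/deletion/MNV (≈87.9% SNV — the
composition of a published trio callset of that scale), Ti/Tv target 2.0
(transition probability `titv/(1+titv)` per SNV), 20% of SNVs placed on
CpG sites, and counts rising 1.0 per father-year and 0.7 per mother-year
around intercept 20 with Gaussian noise sd 20, ages uniform on 20–45
(father) and 20–40 (mother) years. The noise level is chosen so the
joint-fit 95% CI half-width is ≈0.5 at n=139, matching the precision a
simulated demonstration cohort of this size typically shows. Counts are
rounded and floored at 1 so exponential-model fixtures are always valid;
indel alleles are generated VCF-anchored and copied from the reference,
so every simulated record validates against it.

What the generator does **not** emulate: mutation-rate heterogeneity
along the genome, clustered DNVs, trio genotypes or sequencing error,
indel length distributions beyond a capped geometric (p=0.5, max 10 bp),
or correlation between parental ages. Passing tests therefore demonstrate
that the *computations* are correct and self-consistent under controlled
conditions, not that any particular real callset is clean.

A second generator, `simulate_fixed_composition`, draws alleles and
positions randomly but takes exact class/transition counts, giving a
by-construction oracle for end-to-end summary checks.

All generators use `numpy.random.default_rng(seed)` and are bitwise
reproducible; no global random state is touched.

## Problem sizes and numerical choices

Tests and the acceptance script run on toy references (2 chromosomes ×
20 kb) and callsets of ~10⁴ records; the CI-coverage check uses 200
replicates of n=200 fits. These sizes make every distributional check
well-powered (binomial/SE bounds are stated in each test) while the whole
suite runs in seconds. OLS is compared against an independent
normal-equations solve at 1e-8; exact-interpolation fixtures must return
r² = 1 to machine precision up to integer rounding of counts. BED and TSV
round-trips are exact identities, not approximate comparisons.

## Known limitations

- Only TSV ingestion; VCF/BCF and pedigree files are out of scope by
  design (callers' TSV exports and a column map cover the common cases).
- The CpG map is per-position and forward-strand; island detection and
  methylation-aware annotation are not attempted.
- X/Y handling is purely name-based; pseudo-autosomal regions are not
  distinguished.
- The parental-age models are descriptive OLS fits, not calibrated
  mutation-rate models.
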