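# Methods

This note documents the models, defaults, and numerical choices behind
`tmpop`, and what its simulation-based tests do and do not establish.

## Population model

The pedigree simulator models a backcross–selfing design: a single F₁
between a homozygous recurrent parent (MO17) and a homozygous donor (MEX)
is backcrossed `n_backcrosses` times (default 2) to the recurrent parent
and then selfed.  Every simulated individual descends from the same F₁;
backcross and selfing meioses are drawn independently per line.  The
default selfing depth is chosen so that the total number of
mutation-accumulating generations — F₁ formation, each backcross, each
selfing round — is **g = 10**, matching the "ten continuous generations"
accounting a BC₂F₇ design implies; `g` is configurable.

Meiosis draws a Poisson number of crossovers on genetic distance
(`GeneticMap`, piecewise-linear cM(bp)), with an obligate crossover per
chromosome by default when the map length is positive.  Crossover
interference is not modeled: the downstream statistics (donor fractions,
segment lengths at the 10–100 kb resolution of the analyses) are
insensitive to it.  The expected diploid donor fraction after `b`
backcrosses is 0.5^(b+1) independent of the map — 12.5% for b = 2 — and the
simulator is checked against this analytically and against a single-locus
transmission enumeration in the no-crossover limit.

## Mutation planting and the estimator it justifies

`plant_mutations` places, per line and per generation, Poisson(μ · G)
mutations uniformly over the genome of the lineage reaching the final
individual (G = haploid genome length).  Fixation and loss during selfing
are deliberately not simulated: a mutation is attached to the final
genome, homozygous outside residual-heterozygosity regions.  This is the
standard mutation-accumulation idealization and is exactly the model under
which the estimator

  rate = n / (callable bp × lines × g)

is unbiased; the test suite verifies recovery of the planted rate within
two Poisson standard errors under realistic read noise.  Preexisting
parental variants (the "recurrent" confounder removed by the caller) can
be planted in two or more lines via `recurrent_fraction`.
Residual heterozygosity is modeled as ancestral heterozygous blocks
(exponential lengths, default mean 50 kb) present in a configurable subset
of lines; they emit clustered heterozygous sites, the signature the
cluster mask is designed to catch.

## Read-evidence model

Per site and line, total depth is Poisson (optionally fixed or
negative-binomial with variance m(1 + φm)); mutant-allele read counts are
binomial with success 1−e (homozygous carrier), 0.5 (heterozygous), or
e/3 (non-carrier), with per-read error e (default 10⁻³).  High-quality
unique-read counts (the MQ ≥ 50 support the caller requires) are binomial
thinning of allele depths.  Genotypes are called at 0.2/0.8 allele-fraction
cutoffs, so error-free fixed-depth emission reproduces truth exactly.  The
generator does not simulate reads, alignment, mapping-bias artifacts, or
linkage between sites; passing recovery tests therefore demonstrates the
correctness of the interval logic and filter cascade, not robustness to
alignment pathologies in real data.

## Segment calling and line selection

Parental origin is called per line with a three-state (MO17/MEX/HET)
maximum-score changepoint model: +1 per concordant marker, −1 per
discordant marker, and a switch penalty (default 1.5) per origin change,
solved exactly by dynamic programming and verified against full path
enumeration on toys.  Boundaries are placed at midpoints between flanking
discordant markers (the genotyping array localizes a crossover only to an
inter-marker interval; the midpoint is the symmetric choice), terminal
segments extend to chromosome ends, and internal segments supported by
fewer than `min_markers` markers are absorbed into the better-supported
neighbor.  Line selection for assembly-style designs is greedy maximum
coverage of donor bases (ties to the lowest line id, for determinism);
shared-origin regions are computed by an event sweep at carrier-set
granularity so each region lists exactly its carriers.  HET bases are
excluded from shared regions and from callable length, since heterozygous
material cannot support homozygous mutation calls.

## Mutation filter cascade

Site prefilter, mirroring standard short-read SNP hygiene: site MQ ≥ 30;
per-line depth within [5, 40] for every genotyped line (a summed-depth
reading would reject all sites in a 10-line design at ~20× each); no
neighboring retained site within 5 bp; minor-allele depth ≥ 5.  Candidates
are one-vs-rest sites in shared regions: exactly one carrier homozygous
for a private allele, all other carriers concordantly homozygous.
Validation requires ≥ 5 uniquely-mapped MQ ≥ 50 reads on the mutant allele
in the carrier **and** on the shared allele in every other carrier ("each
of the two alleles" is read as one threshold per allele, both
configurable), a proper-pair flag, exclusion of clustered-heterozygosity
masks, and exclusion of alleles seen as candidates in two or more lines
(recurrent, i.e. preexisting).  The cluster mask flags any stretch with
≥ 3 flagged sites within 10 kb (both parameters exposed; no published
values exist for them) and extends to the enclosing segment boundaries.
Rules are evaluated on the full candidate set, so the surviving set is
order-independent; every stage emits a ledger with
input = output + Σ rejections.

Masked intervals are subtracted from the callable denominator as well as
from the call set, which keeps the estimator consistent; because masks are
*defined by* clustered calls, extremely dense mutation regimes (far beyond
the ~4 × 10⁻⁶/bp site density of real mutation-accumulation data) would
bias the rate downward — the recovery tests run at realistic densities.

## Rates, spectrum, clustering

Rates carry exact Poisson 95% intervals (χ² form).  Stratification schemes
partition the genome; overlapping annotations are resolved by the
precedence exon > UTR > intron > up5kb > down5kb > intergenic (a base
upstream of one gene and intronic in another counts as intronic), and
pericentromere = annotated centromere ± configurable flank (default 0).
Strata conserve counts and denominators by construction.  Transitions are
A↔G and C↔T; triplet contexts are strand-collapsed into 32 classes and
enrichment is observed share over genomic share, so the genomic-weighted
mean enrichment is 1.  The "ASA/CSG excess" is the mean enrichment of the
collapsed {ACA, AGA, CCG} classes over the unweighted mean of the rest.
Coding effects come from the standard codon table with minus-strand genes
complemented.  Deleterious flags are an input column (effect prediction is
out of scope); the generator can plant them with compartment bias.

The clustering test compares adjacent-mutation distances, mapped into
concatenated callable space, against pooled uniform null draws of the same
size.  Distances within one draw are negatively correlated, which makes
the naive two-sample KS p conservative (empirically ~3× at n = 60); the
default p-value is therefore Monte-Carlo — the observed KS D ranked among
the per-replicate null D values — which restores nominal type-I error
(verified at α = 0.05 over seeded null runs).  The asymptotic p is exposed
for cases needing resolution below 1/(n_null + 1).

## rIBD scan

Windows tile from position 0; a final partial window is kept when ≥ 50% of
the window size, else merged into its predecessor.  Per line, panel and
window, nIBD is the fraction of panel members sharing any overlapping
tract; window-level nIBD is the mean over lines, and per-line values drive
per-line introgression proportions (a line is credited with a flagged
window when its own rIBD there is positive).  Windows below mean SNP
density are removed *before* μ and σ are computed (following the stated
order of operations).  The default flag rule is the z-score
(rIBD − μ)/σ > 2; the printed form (rIBD − μ)/(σ·rIBD) > 2 is implemented
verbatim as `as-printed` because its scale-odd normalization is most
plausibly a typeset z-score — both modes are reported and agree on strong
positive outliers.  A 500-kb window preset suits low-marker-density
(landrace) panels.  σ ≤ 10⁻¹² (all retained rIBD equal up to rounding) is
treated as a degenerate scan and raises.

## PAV calling

"Regions (≤ 50 bp) with coverage depth ≤ 2 were merged" is read as: maximal
depth ≤ 2 runs whose separating gaps are ≤ 50 bp are bridged — the only
reading that yields merging.  Length > 100 bp is strict; TE-related
(≥ 80% TE) is inclusive; intervals containing N are dropped.  The
unaligned-segment variant takes alignment and gap intervals as input files
(aligners are external) and subtracts a second-pass rescue-alignment mask.
The coverage caller is idempotent on its own output.

## Reproducibility and problem sizes

All randomness flows from one root seed through named per-stage
`SeedSequence` children (logged in the run manifest); reruns are
bit-for-bit identical, and manifests record sha256 checksums of every
artifact.  The test suite and acceptance script use desk-scale problem
sizes chosen to make Monte-Carlo error small relative to the tested
effects: 2,000 individuals on a 10 × 5-Mb, 1,500-cM genome for the donor
expectation; 50 replicates of a 6-line, 2-Mb genome at μ = 2 × 10⁻⁷ for
rate recovery; 100 replicates of a 10-Mb, 20-line scan for introgression
sensitivity; 200 null runs for KS calibration.

## Known limitations

No read-level simulation (FASTQ/alignment), no linkage disequilibrium
structure within the teosinte panels, no crossover interference, no
fixation dynamics during selfing, and no attempt to reproduce
data-dependent published figures (total mutation counts, genome-wide
introgression fractions, PAV totals, ts/tv, clustering p-values), which
depend on the original reads and on denominators that were never printed.
The callable-genome denominator is always exposed explicitly rather than
inferred from published rate/count pairs.
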