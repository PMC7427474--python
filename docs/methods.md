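# Methods

## Frequency estimation from phased panels

The estimator is a direct haplotype census. For each marker (an ordered
set of ≥2 component variants on one chromosome) and each individual, the
alleles on the same phase strand across the component variants, taken in
position order and joined with commas, form one haplotype; diploid
individuals contribute two, and males contribute the single haplotype
observed at X-chromosome markers. Haplotypes are tallied within each
population sample and divided by the population's allele total, so
per-population frequencies sum to exactly 1 before any file rounding and
every record carries its raw count.

Assumptions and their consequences:

- **Input is phased.** No statistical phasing is attempted. An individual
  is excluded from a marker — and removed from its denominator — if any
  component call is missing or is an *unphased heterozygote*; a partial
  haplotype is not a haplotype. Unphased homozygotes are retained, since
  their phase is determined. Exclusion counts are kept on the tally and
  logged.
- **Ploidy is read from the genotype, not metadata.** A haploid call marks
  a male X genotype; sex metadata, when supplied, is only cross-checked
  (mismatches are logged, the genotype wins). X-marker allele totals are
  therefore 2·(included females) + (included males).
- **Variants are matched by rsID first**, with a (chromosome, position)
  fallback; if both resolve and disagree, the rsID match wins with a
  warning. A marker with any component variant absent from the panel is
  excluded whole and listed in the exclusion report — frequencies over a
  subset of the defining SNPs would describe a different marker.
- **Alleles are taken verbatim** from the variant's REF/ALT strings;
  multiallelic SNPs and indel alleles pass through untouched (deletion
  haplotype tokens use `del` in the flat files; insertions spell out the
  inserted sequence).

## Variation statistics

**Ae** (effective number of alleles) is `1/Σp²`, computed per population on
that population's own conditional distribution — haplotypes unobserved in
a population are dropped before renormalizing, so a population fixed for
one haplotype scores exactly 1 regardless of what other populations carry.
The marker-level summary is the unweighted arithmetic mean over
populations (a per-population value is available at query time via
`population_ae` / `--ae-pop`; the flat file stores only the mean).

**In** (informativeness for assignment) follows Rosenberg's definition
with natural logarithms and the unweighted mean frequency `p̄ⱼ` across the
K populations (the defining sum divides by K, not by sample sizes).
`0·ln 0 ≡ 0` throughout, so fixed alleles are handled exactly and the
bounds `0 ≤ In ≤ ln K` are attained: 0 for identical rows, `ln K` for
population-private alleles. Residuals below 1e-12 in magnitude are snapped
to 0 — identical rows cancel only approximately in floating point.

**F_ST** uses the Weir–Cockerham (1984) variance components. Each
individual's two marker haplotypes form one diploid genotype at a
multiallelic locus; for each haplotype allele *j*, the components
*a* (among-population), *b* (among individuals within populations) and
*c* (within individuals) are computed from the per-population allele
frequencies and observed heterozygote proportions, and
`F_ST(j) = a/(a+b+c)`. The marker value is the unweighted mean over
alleles with a nonzero denominator; negative per-allele estimates are
retained and nothing is clamped to [0, 1], so the estimator stays unbiased
near zero differentiation. The alternative pooling `Σa / Σ(a+b+c)` is
available (`average="ratio_of_means"`); the default is the mean of ratios,
the simplest reading of "averaged across all alleles". A marker
monomorphic everywhere has no defined component ratio and reports missing.
Haploid individuals are excluded from this (intrinsically genotypic)
estimator; X-marker F_ST therefore describes the female/diploid subset.

## Database model

The database is a directory of UTF-8, LF, tab-delimited tables with header
rows: three core tables (`marker.tsv`, `population.tsv`, `frequency.tsv`)
and four ancillary ones (`idmap.tsv` third-party cross-references,
`variantmap.tsv` rsID→marker, `sequence.tsv` flanking sequence windows,
`altcoords.tsv` alternate-assembly coordinates). Coordinates are 1-based
inclusive everywhere a user sees them; interval arithmetic is 0-based
half-open internally. Chromosome labels accept both `1` and `chr1` on
input and are emitted `chr`-prefixed. Loading validates every invariant
(arity, ordering, referential integrity) and tolerates per-group frequency
sums within ±0.005 of 1 — published tables are rounded to three decimals —
without silently renormalizing; `renormalize=True` rescales explicitly.
Frequencies are written at full float precision so load∘write is the
identity; the Ae/In/Fst columns are stored at 4 decimals, and
`annotate_stats` rounds to the same resolution so annotated databases
round-trip exactly too.

Merging sorts markers by (chromosome, start, name) and frequencies by
(marker, population, haplotype), collapses fully identical records (same
definition under different source labels collapses with the labels
joined by `;`), and keeps both sides of a name collision with differing
definitions, renaming later arrivals with a numeric suffix and reporting
the name — mirroring how independently curated marker collections overlap
(exact duplicates versus adjusted redefinitions under a reused name).

## Amplicon arithmetic

The candidate amplicon starts as the marker span extended by `delta` bases
per side; if still shorter than `min_length`, both sides grow as evenly as
possible with the odd base going right; clipping at either end of the
available sequence shifts the deficit to the other side while room
remains. The resulting length is `max(span + 2·delta, min_length)`
whenever the chromosome (or stored sequence window) allows it — a property
the tests verify by brute force against a base-by-base oracle. Defaults
`delta=25`, `min_length=0` give a compact context view; assay designers
will typically set `--min-length` to their platform's amplicon size.

## The synthetic cohort generator

The generator emulates the *shape* of a phased multi-population reference
panel, not its population genetics. Markers are placed non-overlapping
with 200–1500 bp gaps on the requested chromosomes (round-robin), each
drawing 2–5 SNPs and a core span of 8–150 bp by default, inside a random
reference with planted REF alleles and ≥500 bp flanks. Per marker, 2–8 of
the allelically possible haplotypes receive a base distribution drawn
Dirichlet(1), and each population's distribution is a Dirichlet
perturbation of the base with a per-marker concentration drawn
log-uniformly from [5, 200] — spanning near-panmixia to strong structure
(differentiation roughly 1/(1+θ)), which is what makes In and F_ST vary
together across random markers. Default cohort: 26 populations × 96
individuals (≈2,500 genomes, the scale of the global reference panels
such frequencies are estimated from), sex ratio 0.5.

Individual haplotypes are drawn i.i.d. from the population distribution
and written to phased VCF with a consistent strand assignment, so
haplotype extraction inverts the simulation *exactly* — the round-trip
test demands equality of every individual's haplotype pair, not just of
the tallies. What the generator deliberately omits: linkage between
markers, LD decay within markers, mutation/recombination processes,
genotyping error and missingness. Passing tests therefore demonstrate the
correctness of extraction, tallying, normalization and the statistics —
not robustness to real-data artifacts, which enter only through the
explicit exclusion rules above.

Determinism: all randomness flows from one integer seed; every marker,
chromosome and population consumes a substream keyed by hashing its name
with the seed (CRC-32 into a `SeedSequence`), so fixed seeds give
byte-identical VCF output and enlarging a simulation leaves previously
generated records untouched.

## Problem sizes used by the test suite

The recovery suite simulates 26 populations × 500 individuals × 20 markers
(13,000 individuals, ~70 variants) — large enough that binomial standard
errors are a few parts per thousand — and completes in seconds; oracle
comparisons use 200 random Weir–Cockerham configurations (K ≤ 4, ≤ 5
alleles), 1,000 random amplicon tuples, and 200 random marker sets for
neighbor distances. A note on the 3-standard-error recovery check: with
thousands of simultaneous estimates, some true frequencies of order 10⁻⁵
are observed once in 1,000 alleles, which a normal 3·SE band flags even
though the census is exact; the per-individual inversion test and the
allele-total identities are the sharp correctness checks.

## Known limitations

- No LD or marker-independence assessment beyond physical distance
  reporting; closely spaced markers are flagged only by geometry.
- F_ST is undefined for markers observed in fewer than two populations
  with diploid individuals, and excludes male X genotypes.
- The detail-view layout is this package's own fixed format, stable for
  golden-file testing but not a reproduction of any other tool's output.
- Alternate-assembly coordinates are carried as data only; no liftover is
  computed.
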