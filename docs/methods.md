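# Methods

popscan implements the post-variant-calling half of a small-cohort
resequencing analysis: it consumes a multi-sample VCF, gene models, a
reference sequence and accession metadata, and produces filtered
genotypes, windowed diversity and LD tracks, codominant genetic
distances, per-gene differentiation and selection statistics, and
variant-effect annotations.  This note records the statistical models,
the defaults and why they hold, the numerical choices, and what the
synthetic cohort generator does and does not emulate.

## Filtering model

Genotype calls are masked (set to missing) when read depth is below 10
or genotype quality below 20; both thresholds are strict, so calls at
exactly DP = 10 / GQ = 20 survive.  Sites are then removed when they are
non-biallelic (more than one declared ALT) or when, *after* masking,
strictly more than 30% of calls are missing.  The ordering matters: the
missing fraction is evaluated on the masked matrix, and in the removal
report each site is attributed to the first rule that fires
(non-biallelic before missingness), which makes the accounting exact and
idempotent.  Indels pass through filtering — their proportion is a
reported quantity — but are excluded from π, LD, Fst, Tajima's D and
distance computations, which operate on biallelic SNPs only.

Per-accession summaries classify each called site as hom-ref
(invariant), het (biallelic-variable: one allele matches the reference)
or hom-alt (monoallelic-variable).  Percent missing and observed
heterozygosity Ho use all retained sites as denominator; because pooled
accessions blend five plants into one diploid call, Ho here measures
apparent pool heterozygosity, not individual-plant heterozygosity.

## Diversity

Per-site nucleotide diversity uses the unbiased pairwise estimator
π = 2c(n−c)/(n(n−1)) for a biallelic site with n called allele copies, c
of them alternate; sites with fewer than 4 called copies are undefined
(NaN).  Windowed π divides the summed site values by the *full* window
length, so monomorphic positions implicitly contribute zero — this is
the per-bp convention that makes window values comparable across window
sizes.  Per-gene π uses the gene span as denominator (an exonic-length
alternative is a one-line change via `interval_pi` on the CDS
intervals).

## Linkage disequilibrium

r² is the squared Pearson correlation of alternate-allele dosages
(0/1/2) over pairwise-complete samples — the phase-free composite
(Rogers–Huff) estimator, appropriate for unphased pooled calls.  Under
random mating it closely tracks the gametic D²/(p₁q₁p₂q₂); the test
suite verifies agreement within 0.05 at n = 500 simulated diploids.
Pairs are computed for all same-chromosome sites within 0.5 Mb; no MAF
pruning is applied (a `min_samples` floor of 3 complete observations is
the only exclusion, besides monomorphic members).

The decay curve is a tricube-weighted local quadratic regression of r²
on distance (span 0.3 of the total weight, nearest-neighbour
bandwidth), evaluated on a 1 kb grid.  For tractability the regression
operates on distance-bin means (bin width = grid step) weighted by pair
counts; with 10⁷-scale pair lists this is numerically indistinguishable
from fitting raw pairs and keeps memory flat.  Distances are rescaled
by the local bandwidth before the polynomial solve to keep the normal
equations well-conditioned.  Threshold crossings report the smallest
grid distance at which the fitted curve drops below r² = 0.6, 0.4 and
0.3.

Background LD — the r² level expected between unlinked loci at this
sample size — is estimated by bootstrap: 1000 replicates, each drawing
1000 SNPs genome-wide without replacement and averaging r² over at most
50,000 random *inter-chromosomal* pairs (background means unlinked; the
pair cap keeps 1000 replicates at desk scale).  The BLD value is the
97.5th percentile of the replicate means; `mode="pooled"` instead takes
the 97.5th percentile of the pooled pair values, for users who read the
"upper interval of the 95% confidence interval" the other way.  For
independent loci the replicate mean sits near 1/n (finite-sample
inflation of squared correlation), which is why BLD must be compared,
not assumed zero.

## Genetic distance

The Kosman–Leonard similarity of two diploid genotypes at one locus is
half the multiset intersection of their allele pairs (identical
genotypes 1, AA/AB 0.5, disjoint 0); the distance is one minus the mean
similarity over loci called in *both* accessions (pairwise deletion).
Because each pair may use a different locus set, the per-pair locus
count is reported and the matrix need not satisfy the triangle
inequality exactly; symmetry, zero diagonal and the [0, 1] range always
hold.  The matrix is exported as a NEXUS DISTANCES block (SplitsTree
input) and square PHYLIP; a neighbor-joining tree (scikit-bio, negative
branches clamped to zero) is provided as a convenience summary.

## Differentiation and selection

Fst is the two-population Weir–Cockerham (1984) estimator: per site the
variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from sample sizes,
allele frequencies and observed het frequencies; θ = a/(a+b+c).  Sites
need at least one called diploid per group and mean sample size above
one.  Multi-site values (windows, genes) are ratio-of-sums
Σa / Σ(a+b+c), the stable recommended combination; negative per-site
components are retained (flooring would bias the ratio upward).  The
"Fst = 1.00" gene class is decided by |Σ(b+c)| < 1e-12 rather than
float equality — the class exists precisely because b = c = 0 at fully
fixed genes.  θ = 1 holds for any fixed difference regardless of group
sizes, which the tests check.

Tajima's D for an interval uses only sites completely called within the
group, so n = 2 × group size stays constant as the constants a₁…e₂
require; D = (π_sum − S/a₁)/√(e₁S + e₂S(S−1)), NaN when S = 0.  The
neutral null (coalescent, n = 20, θ = 10) has mean D slightly below
zero, as expected for the statistic.

The scans flag genes with θ strictly above 0.80, genes in the fixed
class, and genes with π strictly above the 99th percentile of the
per-subspecies gene-π distribution (exclusive lists = flagged in
exactly one subspecies).  Note the arithmetic of the percentile scan:
with G genes, only ~G/100 can exceed the 99th percentile, so planted
enrichments are only fully recoverable when they are at most 1% of the
gene set.

## Effect annotation

Regions follow standard annotation-tool conventions: splice
donor/acceptor are the first/last two intronic bases (HIGH); the splice
region is intronic bases 3–8 from a junction or the three exonic bases
flanking it (LOW); "splice site region" tallies count the union.
Variants outside a gene span but within 5 kb are upstream/downstream by
that gene's strand; beyond all flanks, intergenic.  Coding SNPs rebuild
the affected codon on the coding strand and translate with the standard
nuclear code (start codon ATG only); CDS indels are frameshift unless
the length change is a multiple of 3.  A 5′-UTR substitution that
creates a new ATG on the mRNA strand is a premature-start gain (LOW).

Each (variant, gene) pair keeps one primary record with the
highest-impact candidate effect, and the record's region is made
consistent with that effect (a missense two bases from a junction is
reported as an exonic missense, not a splice-region variant); the
standalone `classify_region` applies the pure location precedence for
Table-style tallies.  Impact tiers are a fixed total map (HIGH: stop
gain/loss, start loss, splice donor/acceptor, frameshift; MODERATE:
missense, in-frame indels; LOW: synonymous, splice region, stop
retained, UTR start gain; MODIFIER: all non-coding).  Ka/Ks is the raw
count ratio of non-synonymous to synonymous *changes*, not a per-site
normalized dN/dS; Ts/Tv counts A↔G and C↔T as transitions.  Per-group
summaries attribute a variant to a group when at least one member
carries a non-reference allele; private variants (present in one group,
absent in all others) drive the HIGH/MODERATE private-gene sets.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not sequence realism.  Eight accessions (five subspecies *pepo*, three
*ovifera*, each a pool of five plants) are simulated on 4 chromosomes of
1 Mb with 20,000 variant sites and one gene per 20 kb — a deliberate
scale-down of a 263 Mb, 3.8M-SNP, 20-chromosome study to desk size;
statistics that depend on absolute counts (totals, percentages of
scanned genes) therefore differ from the full-scale study, while
estimator behaviour (Fst recovery, D null, LD structure) carries over.

Allele frequencies follow a hierarchical Balding–Nichols model:
ancestral frequency uniform on (0.05, 0.95), subspecies frequency ~
BN(p, F = 0.3), accession frequency ~ BN(p_sub, F = 0.1).  Plant
haplotypes use a block-copying model: one latent uniform per 20 kb
block per haplotype decides all alleles in the block (perfect
within-block association for frequency-matched sites), redrawn with
probability 0.5 at block boundaries, giving geometric LD decay.  Pooled
calling maps the 10-allele alternate fraction f to hom-ref (f < 0.15),
hom-alt (f > 0.85) or het, emulating the inflated apparent
heterozygosity of pooled accessions.  Depth is negative-binomial (mean
33, dispersion 8), quality clamped normal (60 ± 15), with 2% random
missingness; transitions are drawn with probability 0.62 per SNP
(Ts/Tv ≈ 1.6) and 20% of sites are 1-bp indels.

Planted features carry machine-readable truth: tri-allelic sites and
just-over-30%-missing sites (for exact filter accounting — a repair
pass guarantees no unplanted site crosses the missingness cutoff, and a
breaker pass downgrades one call in any gene that would be a perfect
fixed difference by chance, so the "Fst = 1.00" truth class is exactly
the planted set); fixed-difference genes (unit frequency gap at every
informative site); high-π genes (all-het in one subspecies, silenced in
the other); and private HIGH/MODERATE effect variants whose codon
context is written into the reference so the planned consequence (stop
gain, missense, frameshift) is guaranteed.  What the generator does
*not* emulate: mapping or reference bias, linked selection, realistic
site-frequency spectra (frequencies are exchangeable across sites),
indel length spectra, and any form of purifying selection — hence the
cohort's neutral Ka/Ks (~2.5, the mutational-opportunity ratio) rather
than a selection-shaped value below 1.  Passing tests demonstrate
estimator correctness under these conditions, not robustness to
artefacts of real data.

A small Hudson coalescent sampler (exponential coalescence times,
Poisson mutations on branches, infinite sites, no recombination)
provides neutral site-frequency spectra for the Tajima's D null; it is
cross-checked against msprime's mean segregating-site count in the test
suite.

All randomness derives from one root seed through labelled child
streams (seed, CRC32(label)), so adding a component never perturbs
another's stream and fixed seeds give byte-identical output files.

## Numerical and engineering choices

Coordinates are 0-based half-open internally; VCF/GFF3 conversion
happens once at the I/O boundary.  Genotypes are unphased throughout.
Pairwise r² is computed in banded chunks via masked moment matrices
(five matrix products per chunk), and the pipeline reduces each
chromosome's pairs into window means and decay bins immediately, so
memory stays bounded at tens of millions of pairs.  The pipeline's
problem sizes (default cohort, 1000×1000 BLD bootstrap, 500-replicate
null) complete in a couple of minutes on one CPU.  Degenerate inputs
return NaN with a warning rather than raising wherever a statistic is
merely undefined (monomorphic Tajima intervals, empty LD windows,
zero-transversion Ts/Tv); hard errors are reserved for contract
violations (unmasked input to the site filter, overlapping Fst groups,
single-chromosome BLD).

## Known limitations

Only two-population Fst is implemented; multi-allelic sites are
filtered rather than decomposed; the splice model is positional (no
canonical GT/AG check); UTR start-gain scanning is local to the variant
window; the NJ tree is a convenience, not a substitute for the
neighbor-net the distance export targets; and the Kosman–Leonard matrix
may violate the triangle inequality when missing-data locus sets
differ, which is reported rather than corrected.
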