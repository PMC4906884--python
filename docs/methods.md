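# Methods

## Genetic model

A single founder sire carries a dominant, fully penetrant, perinatally
lethal point mutation as a post-zygotic mosaic: fraction `f_g` of germ
cells and `f_s` of somatic (blood) cells carry the mutant allele. Each
conceptus receives exactly one paternal gamete, so under full penetrance
the probability that a calf is affected equals `f_g`, and affection status
is identical to the transmission flag. Dams never carry the allele; there
is no inbreeding pathway. These assumptions are what the segregation check
tests on real data (affected heterozygous, dams homozygous reference, sire
sub-heterozygous) and what the simulator enforces by construction.

## Allele-sharing linkage

The analysis is exact single-point sharing on informative markers, a
deliberate simplification of multipoint NPL: no inheritance-vector HMM, no
genetic-map modelling. Per marker, the sire-transmitted allele of each
affected half-sib is deduced only when the sire is heterozygous and the
maternal allele can be subtracted unambiguously; ambiguous configurations
(sire, dam and calf all heterozygous) are dropped and the per-marker
informative count `n` is reported. The statistic `S` counts affected pairs
sharing the transmitted allele; its exact null moments come from
`k ~ Binomial(n, ½)` via integer arithmetic (regression-tested against full
`2^n` enumeration for `n ≤ 12`). The Kong–Cox LOD uses the linear model
`ℓ(δ) = Σ_f ln(1 + δ Z_f)` maximised over `δ ∈ [0, δ_max]` with
`δ_max = min(1, min_{Z_f<0} −1/Z_f)`; the δ cap of 1 makes the single-family
boundary case well-defined, and a boundary maximiser is reported, not an
error.

Chromosome-wide significance is a permutation test: transmissions are
redrawn i.i.d. Bernoulli(½) per informative case per marker, preserving
each marker's informativeness pattern; a marker's empirical p is the
fraction of permutations whose chromosome-maximum Z reaches its observed Z,
with the tie-safe `(r+1)/(N+1)` estimator (1000 permutations by default).
Two consequences matter for interpretation:

* Because the permutation null treats markers as independent, the test is
  calibrated for unlinked markers and conservative for tightly linked
  ones. The calibration experiment in the acceptance suite therefore uses
  a per-interval recombination fraction of 0.5; at the default 0.01 the
  test under-rejects, which only makes reported regions more conservative.
* The statistic saturates at small case numbers: with four informative
  cases the largest attainable Z (complete sharing, S = 6) also arises by
  chance somewhere on any 200-marker chromosome in far more than 5% of
  permutations, so no marker can reach chromosome-wide p < 0.05. Sharing
  statistics on a handful of cases need multipoint aggregation to be
  powerful; the single-point design regains the nominal power once a dozen
  or more informative cases are available. The power experiment therefore
  simulates a cohort of 120 genotyped half-sibs (≈18 affected at
  `f_g = 0.15`); its rare failures are exactly the replicates whose
  binomial draw produced fewer than about ten affected calves.

Significant markers are merged into regions, bridging up to two
non-significant markers (`gap_tolerance = 2`); intervals are 1-based
inclusive internally and emitted as 0-based half-open BED.

## Variant filtering

Cohort membership is an exact `(chrom, pos, ref, alt)` match — a different
ALT at a known site is still private; no indel normalisation is performed
(the generator emits SNVs only). Region boundaries are inclusive; the
region stage's excluded fraction is kept at full precision and displayed as
a round-half-away-from-zero integer percent. The functional classes are
coding (inside a CDS exon) and splice_site (first/last two intronic bases,
the canonical GT/AG window); the candidate-gene stage keeps coding/splice
variants inside candidate genes overlapping the regions by at least 1 bp.
All stage counts are emitted, including zeros, plus the in-region
splice-site count as an extra funnel stage.

## Splice annotation

Gene models are single-transcript and fully coding (CDS = exons), which is
sufficient for intronic variants adjacent to CDS; UTR coordinates
(`c.-…`, `c.*…`) are out of scope. Intron offsets follow HGVS in transcript
orientation (`+1` first donor base, `−1` last acceptor base; mid-intron
ties go to the donor side), alleles are reported in transcript orientation,
and notation is emitted without spaces (`c.2463+1G>A`). A reference-base
mismatch with the variant's REF is a hard error rather than a warning,
since every dinucleotide conclusion would otherwise be meaningless. The
bundled COL2A1-like fixture is synthetic: 54 uniform-intron coding exons
laid out so the cumulative coding length through exon 36 is 2463 with the
canonical donor at intron 36 — it encodes the coordinate arithmetic of the
real transcript, not its genomic coordinates.

## Mosaicism

Peak-area ratios from Sanger traces are modelled as binomial counts at an
effective depth (default 1000 per site, 3 sites per tissue) — an explicit
simplification of chromatogram physics with no per-base error model. The
pooled fraction uses the 95% Wilson score interval (well-behaved at 0 and
1, where the Wald interval degenerates; the exact Clopper–Pearson interval
serves as a test oracle only). Exact enumeration over binomial outcomes
shows Wilson coverage at depth 1000 is 0.946–0.954 for fractions 0.05,
0.15 and 0.5, inside the 94–96% band the tests assert. Tissue labels use
configurable bands: absent (CI upper < 0.01), mosaic (CI upper < 0.35),
heterozygous (CI overlapping [0.35, 0.65]). The consistency test between
offspring prevalence and the semen fraction is the exact two-sided binomial
test with the minimum-likelihood two-sided rule.

## Breeding statistics

The tally enforces its identities on every construction
(`followed_up = total − alive_normal`;
`confirmed + reported_normal + excluded = followed_up`;
`denominator = total − excluded`) and refuses to emit a ratio from
inconsistent counts. The denominator excludes only non-respondents. The
Welch statistic is computed from the definition with Welch–Satterthwaite
degrees of freedom and a two-sided p (sidedness is not otherwise
determined by the design; two-sided is conservative); it is cross-checked
against an independent reference implementation to 1e-9 in the tests.
Display rounding is one decimal for percentages and day means.

## Synthetic-data generator

What it emulates: a paternal half-sib AI family (default 120 dams/calves);
germline fraction 0.15 and somatic fraction 0.05; array-like biallelic
SNPs (MAF 0.3) on a toy genome of 10 chromosomes × 10 Mb with 200 evenly
spaced markers each, dropped through the pedigree with a fixed per-interval
recombination probability (0.01, no interference — marker spacing carries
no genetic map); a causal locus at chromosome 5:3,200,000 whose ±500 kb
window co-segregates perfectly with transmission (the window is scaled to
the toy chromosome so it spans ~10 markers); a case variant set of 900
cohort-shared and 100 private variants of which a deterministic
round-half-away 13% lie in the linked region, 15% of those coding (placed
in non-candidate genes), plus exactly one splice-donor GT→AT variant in a
candidate gene; 9 of 95 candidate genes inside linked regions; gestation
lengths Normal(280.2, 5) vs Normal(276.2, 5) days truncated to [240, 300]
(the paper-scale means; the SD is a modelling choice since only means are
recorded, and the truncation brackets observed affected deliveries at
gestation days 269–273).

Within the causal window the generator also forces full marker
informativeness (sire heterozygous with the mutant haplotype carrying the B
allele, dams homozygous A) — the toy-scale analogue of a dense commercial
array always containing fully informative markers near any locus. Counts
derived from fractions use round-half-away-from-zero so partition sizes are
exactly assertable, and a fixed seed yields byte-identical output files
(each operation draws from its own seeded stream).

What it does not model: linkage disequilibrium, genotyping error or
missingness, X-chromosome inheritance, signal-intensity data, indels or
structural variants, chromatogram noise beyond binomial sampling. Passing
tests therefore demonstrate the correctness and calibration of the
inference machinery under the stated generative model, not robustness to
the artefacts of real array/sequencing data.

## Problem sizes and numerical choices

Test-suite experiments use desk-scale designs chosen for exactness and
reproducibility: the type-I calibration runs 500 replicates of a
one-chromosome, 50-marker, 24-case null with 1000 permutations; power runs
50 replicates of a 5-chromosome × 100-marker scan; cascade recovery runs
50 seeded fixtures; interval coverage is evaluated by exact enumeration
(no Monte-Carlo noise). Optimisation of the Kong–Cox likelihood uses
bounded scalar minimisation (`xatol = 1e-10`) with endpoint checks; the
single-family case uses the closed form. Degenerate inputs fail loudly:
fewer than two half-sibs, empty regions, zero depth, zero-variance Welch
samples and out-of-domain proportions all raise typed errors.
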