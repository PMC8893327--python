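# Methods

This note records the models, conventions and numerical choices behind
`telscope`, in the order data flows through the package.

## Pooled-sample model

A sample is a bag of `2N` haplotypes from `N` individuals (default 10,
matching small pooled cohorts).  A planted insertion with penetrance `p` is
carried by exactly `round(p · 2N)` haplotypes chosen by a seeded draw, so
penetrance is identical to haplotype frequency; there is no diploid pairing
logic because pooled WGS observes only allele frequency.  Insertion plans
must keep loci at least twice the read length apart (default 150 bp) so
truth loci remain separable; the plan generator additionally keeps 500 bp
(tests use more) away from the pre-existing TE copies embedded in the
genome.  Coordinates are 0-based half-open everywhere internally and in BED
output; 1-based coordinates appear only in human-readable messages.

## Synthetic references and libraries

`build_reference` produces per-chromosome random DNA (minimum 100 kb per
chromosome), one full-length pre-existing copy of each TE consensus
(default 5 families × 5 kb) recorded in an annotation BED, `n_ige`
immobile-gene intervals (default 100 × 1.5 kb, mirroring the 100-gene IGE
benchmark set), and a spike-in plasmid roster (pUC19 2.7 kb, pMaxGFP
3.5 kb, pGSH0 5.2 kb, pCENPm3 6.3 kb added post-extraction at a
1 : 0.1 : 0.01 : 0.001 mass series; pGL3-DmPiwipro1 7 kb and
pJDS246-CarhCas9 11 kb added pre-extraction).  The four post-extraction
plasmids share an 800 bp cloning backbone so multi-site read assignment is
exercised; the pre-extraction vectors are unrelated sequences — if they
shared the backbone, ambiguous backbone reads would dilute the
extraction-recovery QC signal they exist to provide.

WGS libraries draw `round(depth · L / (2 · read_length))` fragment pairs
uniformly across haplotypes; insert sizes are truncated normal (default
350 ± 35 bp, floored at the read length), read 1 is the forward fragment
end and read 2 the reverse complement of the other end.  The default
library is error-free and chimera-free so algorithmic behaviour is tested
in isolation; substitution errors and chimeras are opt-in.  Chimeras are
modelled as amplified template-switching artifacts: a genomic locus with a
random ~400 bp foreign segment spliced in, expanded into ~20 read pairs
(PCR duplication).  This is what makes chimeric junctions *recurrent* and
able to accumulate read support on both flanks of one locus — uniformly
random single-molecule chimeras would never reach a 4-read threshold and
would make the two-sided rule look trivially perfect.  Read names encode
full provenance (haplotype, fragment start, length, or chimera template),
which is what the test oracles consume.

eccDNA libraries draw reads from circular coordinates: fragment starts are
uniform on each circle, sequences come from the doubled circle so reads
wrap the head-to-tail junction with probability `(read_length − 1) / L`
per read.  Read share per circle is proportional to copies × length.
Pre-extraction plasmid abundance is multiplied by an `extraction_loss`
factor (default 1.0) *before* sampling while post-extraction plasmids are
unaffected, making their ratio the recovery observable.  A configurable
fraction of reads (default 0) comes from linear genome surviving
digestion.  The generator does not model amplification bias, quality-score
realism or long reads; passing tests therefore demonstrate algorithmic
correctness under idealized sampling, not robustness to real library
artifacts.

## Mapping

The bundled mapper is an exact-seed mapper: a 15-mer index over the
combined reference (genome + TE consensus + IGE + plasmids) with full
verification of every candidate placement.  It is sufficient for the
error-free fixtures this package targets; with `max_mismatches > 0` it
tolerates a few substitutions through multi-offset seeding.  Two contracts
are exposed.  `genome_split` takes the best full-length placement, with the
genome preferred on ties (a read inside a TE copy counts as genome, never
IGE), and falls back to aligning the longest exactly matching prefix or
suffix (minimum 20 bp) with the remainder soft-clipped — this preserves
junction evidence.  `consensus_end_to_end` accepts full-length placements
only and prefers consensus entries over the genome, the contract the
coverage profiler needs; clipped reads count as unmapped there.
Multi-mapping ties are broken by (category priority, target name,
coordinate, strand) for determinism.  Alignments round-trip through
standard sorted/indexed BAM via pysam.

Depth matching subsamples read pairs with keep probability equal to the
mapped-read ratio rounded **up** at the 4th significant digit
(0.572135 → 0.5722), read literally as a ceiling; nearest-rounding is
available as an option.  Pairs are kept or dropped atomically.

## Insertion calling

Evidence: a split read has a genome-unique segment and a ≥15 bp clip
mapping to TE consensus, a pre-existing TE copy, or an IGE; either segment
may be the primary alignment (when the element part is longer, the clip is
the genome-unique flank and becomes the anchor — dropping that case would
halve junction sensitivity).  A discordant pair has one full-length
genome-unique mate and the other mate inside TE/IGE sequence, with the
anchor's strand assigning the flank side.  Evidence anchored inside
annotated pre-existing TE copies is excluded (with a warning when no
annotation exists); for real genomes a RepeatMasker-style BED is accepted
as input, never computed.

Same-family evidence within a clustering window (default 420 bp = insert
mean + 2 SD, bounding discordant-pair uncertainty) merges into one
candidate, accepted iff total support ≥ 4 **and** each side ≥ 2.  The
per-side floor of 2 is configurable to 1.  Position is the median
split-read junction (fallback: median discordant estimate); orientation is
the majority strand vote with `.` on ties.

`r`, the reference-allele count, is the number of concordant unclipped
genome pairs whose fragment covers `[position − read_length, position +
read_length]` entirely; the window is a declared convention since no
standard exists.  `CR = i / (r + 1)`; `CR > 2` (strict) classes a call as
deeply penetrant.  IGE calls are reported separately and excluded from the
TE landscape; the IGE false-positive rate is `|IGE| / (|TE| + |IGE|)`.

## Coverage profiling

Per TE family and IGE gene: mapped read count, RPM (per million mapped
library reads) and mean per-base coverage.  Because "average read
coverage" is ambiguous between per-base mean and mean read count, both the
per-base mean and the raw count are emitted.  The aged/young comparison
reports per-target RPM ratios (zero-denominator targets flagged and
excluded) and three rank-sum summaries: aged vs. young across TE families,
the same across genes, and TE ratios vs. gene ratios.

## Landscape comparison

The bootstrap keeps each pair with probability `fraction` (default 0.5)
under seed = iteration number (1..20 by default; the 100-permutation mode
is a flag away), re-runs clustering on the retained evidence and records
insertions per million mapped reads.  The denominator is the full
library's mapped count by default: permutation values then scatter around
the full-data landscape size, which is the quantity the error bars
describe (per-permutation denominators are available via
`normalization="permutation"`; at fraction 0.5 they would re-scale every
value by ~2 since well-supported calls survive halving).  The 95% CI is
the 2.5/97.5 percentile of permutation values, with a normal-approximation
CI as an option.

Two call sets partition into common and unique by greedy nearest-first
one-to-one matching: same chromosome, same family, positions within 100 bp
(configurable; 0 gives exact matching — slop is needed because
discordant-only calls are interval-resolved).  Family composition lumps
families under 1% into "Others"; percentages sum to 100.  The paired
signed-rank test runs on per-family (unique_aged, unique_young) counts and
refuses with fewer than 3 informative pairs; per-family count data are
tie-rich, so both Wilcoxon tests use the exact conditional null given the
observed midrank pattern, computed by subset-sum dynamic programming over
doubled midranks for up to 25 observations (per group), with the
continuity-corrected normal approximation beyond.  Absent-family ratios
get an optional +1 pseudocount and a flag.

## eccDNA quantitation

Each consensus and plasmid is concatenated head-to-tail with itself;
alignments are canonicalized to `start mod L`, and a read is a
circular-junction read when it covers the boundary by ≥ m bases on each
side (default m = 10; junction detection is disabled with a warning when
`read_length < 2m`).  A read matching k plasmid sites contributes 1/k to
each (site normalization for the shared backbone).  `v = ((x/y)·10⁶)/z`
with `z` the site-normalized post-extraction spike-in count *per million
aligned reads* — plasmid frequencies are depth-normalized like everything
else, which makes `v` invariant to subsampling; `z = 0` withholds `v`
while RPM is still reported.  Aging ratios are emitted in RPM-only and
spike-in modes side by side, plus a mode dividing the RPM ratio by the
pre-extraction reference plasmid's (pGL3-DmPiwipro1) coverage ratio.  QC
reports each post-extraction plasmid's count relative to the
pre-extraction reference per sample, the cross-sample CV of those ratios,
a >3-fold-from-median flag, and the library's residual IGE read total
(expected ≈ 0 after complete digestion).  External circle-discovery scores
(e.g. CIRCLE-Map) are accepted only as an optional pre-filter table and
never computed.

## PCR calculators

ddPCR: `λ = −ln(N_neg / N)`, concentration `= dilution · λ / volume`;
droplet volume is instrument-specific and therefore a required input with
no default.  The 95% CI applies the binomial-delta interval on the
negative fraction through the log transform (lower bound clipped at
0.5/N), the standard open-form realization of instrument-software Poisson
intervals; simulated-well coverage sits near 95%.  Wells under 10,000
droplets are rejected; fully positive wells are flagged saturated with no
estimate.  Copies per genome divide the TE concentration by half the
*Rp49* concentration (diploid single-copy normalizer), with first-order
propagation of both intervals.  qPCR fold change is `2^−ΔΔCt` with the
ΔΔCt SD propagated in quadrature through the four replicate means
(SD/√n each); the fold interval is `2^−(ΔΔCt ± SD)`.

## Problem sizes in the test and acceptance runs

The suite exercises a 200 kb / 3-family / 20-IGE study at 20X for unit and
property tests, and a 1 Mb / 5-family / 100-IGE study at 20X (≈133 k read
pairs) with 100 planted insertions for end-to-end recovery, penetrance
separation (60 fixed + 60 rare loci) and bootstrap checks; the partition
scenario uses 500 kb with 80 shared + 2×10 sample-specific insertions, and
eccDNA scenarios use 50 k pairs of 36 bp reads.  These sizes were chosen
as the smallest at which junction support, CR separation and spike-in
counting statistics are comfortably away from their thresholds.

## Known limitations

The mapper is exact-seed and intended for synthetic or very clean data;
real libraries should be depth-matched and mapped with a production
aligner and imported via BAM.  Insertion depletion calls, genotype
likelihoods, target-site-duplication reconstruction and breakpoint
assembly are out of scope.  The eccDNA module quantifies only the provided
consensus/plasmid universe and does not discover circles genome-wide.
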