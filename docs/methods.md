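# Methods

`hybridmeth` analyses whole-genome bisulfite sequencing (WGBS) of a
reciprocal cross between two inbred mouse strains (P1 ≈ C57BL/6N, P2 ≈
C3H/HeN): six animals per parental strain (three sires, three dams) and
six F1 hybrids per cross direction (three males, three females, all
virgins), 24 animals in total. Because ~150× whole-genome data per
genotype is not reproducible at desk scale, the package ships a
first-class synthetic study generator with complete ground truth; every
downstream stage is exercised and scored against that truth.

## Synthetic study generator

**Genomes.** Each autosome is an i.i.d. base sequence (A/T 30%, C/G 20%
each) with `cpg_island_count` embedded G+C/CpG-rich stretches
(A/T 15%, C/G 35%) of `cpg_island_length` bp serving as CpG islands.
The P2 assembly differs from P1 only at SNVs drawn per base at
`snv_rate` (default 1/900 bp, the genome-wide density implied by ~2.8
million autosomal SNVs over ~2.5 Gb). A fraction
`cpg_snv_fraction` (default 0.2) of SNVs is placed to create or destroy
CpG dinucleotides, which exercises context validation. The P1 assembly
doubles as the alignment reference. An unmethylated 20 kb `lambda`
contig models the conversion-QC spike-in.

**Methylation truth.** Baseline CpG methylation is bimodal: 0.1 inside
islands, 0.85 elsewhere. Planted DMRs centre the contrast at
intermediate methylation: the hypomethylated group sits at
`0.5 − δ/2`, the hypermethylated group at `0.5 + δ/2`, so the
between-group difference is exactly δ (δ ∈ (0.2, 0.8]). This choice
keeps the planted contrast exact after clamping to [0, 1]; a literal
additive shift on a 0.85 background would saturate. DMR axes:

* *genotype* — acts in **cis**: each F1 haplotype carries the truth of
  the strain it was inherited from, so the F1 haplotype contrast is
  exactly δ inside the DMR and 0 outside;
* *sex* — depends only on the animal's sex, both haplotypes equally;
* *parity* — dams versus everyone else (the study design nests parity
  in sex among parents: all dams are female, all sires male, so a sex
  contrast legitimately detects parity-DMRs — the evaluation code
  accounts for this confound rather than calling such detections false).

Default planted-DMR polarity mixes echo the study's observed
asymmetries (genotype balanced; sex ~2:1 female-hyper; parity almost
entirely virgin-hyper). Planted DMRs are mutually separated by ≥500 bp
and required to contain ≥8 strain-shared CpGs so each is a callable
unit.

Biological replicate noise is one Gaussian(0, `bio_sd`) draw per
(animal, site), shared by the animal's two haplotypes and clamped after
addition; the default `bio_sd = 0.05` reproduces the ~5-percentage-point
replicate-SD floor seen at high depth. The generator does not attempt to
decompose this floor into technical versus biological components — it is
a single knob. An optional `variable_fraction` marks extra sites as
highly variable (baseline 0.5, SD `variable_sd`), emulating the
top-variable-site analysis.

**Reads.** Per sample, `round(depth × genome_length /
fragment_length_mean)` paired-end fragments (exactly; largest-remainder
allocation across chromosomes) are placed uniformly, with
Normal(300, 30) lengths (clamped to [read length, mean + 5 SD]) and
PE100 geometry. F1 fragments draw their haplotype Bernoulli(0.5). Each
cytosine on the fragment's original strand is methylated with its
site's truth probability; unmethylated cytosines convert to T with
probability `conversion_rate` (default 0.995, matching an observed
conversion >99%); uniform substitution errors are applied at
`error_rate`; the methylation-call string (`XM`, Bismark convention) is
then derived from the *final* base, as a methylation extractor would —
so conversion failures surface as spurious methylated calls, exactly
the bias the lambda QC measures. Reads are emitted as already-aligned
SAM (mapping taken as perfect; alignment is upstream of the analysis),
with tags `XG` (OT/OB strand), `XM`, and `XH` (truth haplotype — used
only for scoring, never by analysis code). Mapping-error simulation,
indels, CNVs, PCR duplicates and sex chromosomes are out of scope.

## Context validation

A cytosine context (CpG/CHG/CHH) is *validated* when (a) the context
class agrees between the reference and both strain assemblies and
(b, c) at least 75% of mapped bases at offsets N, N+1, N+2 are
consistent with the expected context in each parental read group
separately. Consistency is conversion-aware (a T on an original-top
read is consistent with an expected C; an A on an original-bottom read
with an expected G) and evaluated against the context *pattern*: for
CpG the expected symbols are (C, G, any); for CHG (C, H, G); for CHH
(C, H, H), where H admits any base except the (conversion-aware) G or
C complement. The pattern reading — rather than the literal assembly
base at every offset — is what makes the validated CpG set equal the
direct sequence-scan oracle on error-free data: an SNV at the
pattern-irrelevant third offset of a conserved CpG must not invalidate
it. Minimum coverage is one read per offset per group; zero coverage at
a required offset flags the site as *insufficient*, distinct from a
threshold failure. For CpG, validation on either strand suffices (the
site is keyed by the plus-strand C); CHG/CHH validate per strand.
Offsets for minus-strand cytosines run in minus 5'→3' direction. Sites
whose trinucleotide runs off the chromosome are never validated; the
test oracle replicates this edge rule.

## Quantification

Extraction applies the study's processing rules: the first four and
last one base of every read2 are clipped (positional methylation bias),
each genomic position is counted at most once per fragment with read1
winning mate overlaps, tallies are restricted to validated CpGs, and
both strands' observations merge onto the plus-strand C key (CpGs are
counted as dinucleotide units). The weighted methylation score of a
region is Σ methylated / Σ total over its covered CpGs (undefined and
flagged at zero depth); it is invariant to splitting a region and
re-pooling counts. Conversion QC estimates the conversion rate as the
unmethylated fraction of all lambda cytosine calls and fails below 99%.

Replicate variability follows the depth-binned design: a site enters a
bin only when every replicate's depth lies in the bin; up to 20,000
eligible sites per bin are sampled; SDs are population SDs of
per-replicate methylation percentages. Default bins are 1–10, 11–20,
21–50, 51–100 and 101–400: at desk scale the ~5% floor only emerges
once the binomial component √(p(1−p)/d) is small against `bio_sd`,
which needs per-site depths beyond 100, hence the wide top bin.
Top-variable sites use the all-animal SD over animals with depth >10,
require ≥18 of 24 informative animals, select the top 5% (deterministic
position tie-break with a warning in the degenerate all-equal case) and
draw an equal-size random control from the remaining eligible sites;
both sets are characterized by 500 nt window occupancy, methylation
level and CpG-island overlap.

## Differential methylation

**DMCs.** Per site, group means are unweighted means of per-sample
fractions over samples with coverage (a coverage-weighted alternative
is selectable); the test is a two-sided exact test on the pooled 2×2
(meth/unmeth × group) table. A DMC requires p < 0.01 and |difference| ≥
0.2. No multiple-testing correction is applied by default, matching the
fixed-threshold design; a Benjamini–Hochberg option exists. The pooled
exact test is a transparent, oracle-checkable stand-in for the
beta-binomial and rank-based models of established callers; externally
called regions can be ingested via `import_dmrs` and pass through the
same filter suite with recomputed statistics.

**DMR segmentation.** Within runs of consecutive validated CpGs whose
inter-site gap is ≤300 bp (the sub-kilobase scale of observed DMRs),
the caller finds the window of ≥5 sites maximising the absolute mean
per-site group difference. Searching window lengths in
[min_cpgs, 2·min_cpgs − 1] is exact: any longer window splits into two
windows in that range, one with at least the same mean. The core window
is extended outward while flanking per-site differences keep the sign
and stay above min_diff/2 (a single below-threshold site may be skipped
when its neighbour rescues it — this protects boundary accuracy against
isolated noisy sites). A candidate is accepted when the pooled
weighted-score difference reaches 0.2 and a two-sided rank-sum test on
*per-sample* regional scores (n = animals, avoiding pseudo-replication)
gives p < 0.05; accepted windows are excised and both flanks
re-searched, so candidates never overlap. Candidates whose groups lack
two covered samples are emitted flagged, not dropped.

**Filters.** Independently evaluated and each failure recorded:
≥5 validated CpGs; weighted-score difference ≥20%; no group with
average depth >500×; depth ratio between groups ≤5. Region statistics
are recomputed from the counts on entry, making filtering idempotent
and applicable to imported intervals. Summaries report counts by
polarity, DMCs inside DMRs (count and %), % of DMR CpGs that are DMCs,
and the DMR footprint as % of the genome. Score matrices give per-DMR
per-sample weighted scores (missing at zero coverage), with quartile
grouping per polarity by decreasing hypermethylated-group score.

## Allele assignment

Bisulfite conversion collapses base identities strand-dependently, so an
inter-strain SNV is diagnostic only through bases unique to one
allele's bisulfite image (OT: C→{C,T}, others identity; OB: G→{G,A},
others identity). Partial diagnosability is exploited: for a C/T SNV on
the OT strand an observed C proves the C allele while an observed T
proves nothing — asymmetric evidence is counted, conversion is never
mistaken for genotype (an auditable invariant). Fragments are assigned
when they carry ≥`min_support` (default 1) allele-unique observations
for exactly one parent, after the same clipping/dedup rules as
quantification; fragments with evidence for both parents are reported
as conflicts, never silently dropped. Allelic methylation pools the
CpG calls of P1- and P2-assigned fragments per DMR and pairs them with
the parental animals' weighted scores; fractions are undefined
(flagged) where no assigned observations exist — in the default
simulation roughly one third of DMRs carry no diagnostic SNV, mirroring
the real fraction of SNV-free DMRs. Read-level matrices render
fragment × CpG calls (methylated / unmethylated / covered-noncytosine /
absent) grouped by assigned parent in deterministic order.

## Enrichment

The permutation null preserves the query set's length multiset: per
iteration, each query region is matched by one region of identical
length placed uniformly over allowed autosomal space (assembly gaps
excluded when a mask is supplied; chromosome-matched placement is an
option — the default is genome-wide, the looser of the two defensible
nulls). Overlap is region-level (a region counts once regardless of how
many track intervals it hits, with ≥1 shared base); the empirical p
carries an add-one correction, (1 + #{null ≥ observed}) / (1 + n_iter),
so it is never zero and its minimum at 1000 iterations is 1/1001.
Proximity statistics report per-region SNV counts and boundary
distances (0 inside), TSS distances (plus-strand TSS at gene start,
minus-strand at the 3'-most coordinate) with the >10 kb fraction, and
CpG dinucleotide density, each compared to a matched random set by
rank-sum. Rank-sum tests use exact enumeration for small tie-free
samples and the tie-corrected normal approximation otherwise.

## Numerical and evaluation choices

* Coordinates: 0-based half-open internally and in BED; 1-based in
  VCF/SAM output. CpG site key = plus-strand C position.
* Truth-recovery checks compare empirical methylation to the *apparent*
  truth p′ = p + (1 − p)(1 − conversion rate), since conversion failure
  is part of the observation model; at the default 0.995 conversion the
  adjustment is 0.5 percentage points.
* Recovery scoring counts a planted DMR as recovered when a reported
  region overlaps it with both boundaries within two validated CpGs of
  the planted edges; false discoveries are reported regions overlapping
  no planted DMR of any axis (see the parity-in-sex confound above).
* Problem sizes: the shipped test-suite and acceptance runs use
  1–2 chromosomes of 100–300 kb at fragment depths 9–300 with the full
  24-animal design (or the 12 parental animals where offspring are not
  needed). These sizes give tens of thousands of CpGs per run —
  enough that every stochastic check is measured with comfortable
  margins while a complete run stays in the minutes range.

## What passing tests do and do not show

The generator emulates the study's design variables (genotype, sex,
parity, cis inheritance, SNV density, coverage, conversion failure,
sequencing error, replicate noise) but not mapping artefacts, PCR
duplicates, M-bias beyond the fixed clipping rule, beta-binomial
overdispersion beyond the Gaussian replicate noise, or genuine
biological covariance between neighbouring sites. Passing recovery
tests therefore demonstrate the correctness and calibration of the
implementation under the stated generative model, not the performance
of the method on real libraries.
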