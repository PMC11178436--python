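# Methods

This note documents the models and estimators implemented in `lemnapop`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate
about real data.

## The biological setting

*Lemna minor* and *L. japonica* are cryptic species: *L. japonica* is a
hybrid of *L. minor* (sub-genome M) and *L. turionifera* (sub-genome T),
typically triploid with an M/M/T configuration. Both propagate clonally, so
a pond usually contains near-identical individuals. Three signals separate
the species and reveal the hybrid's dosage from short-read data:

1. **Allele balance.** Mapped against an *L. minor* reference, all three
   haplotypes of a hybrid pile onto the M coordinates. At a site fixed
   between the parents, an M/M/T individual shows ~1/3 of reads carrying the
   T (alternative) allele; M/T/T shows ~2/3; a diploid heterozygote shows
   ~1/2. A diploid variant caller emits all of these as 0/1, so the read
   ratio — not the genotype call — carries the ploidy signal.
2. **Sub-genome coverage.** Mapped against a combined M+T reference,
   haplotypes sort onto their own sub-genome: M/M/T gives a 2:1 M:T mean
   coverage ratio, while pure *L. minor* leaves T essentially uncovered.
3. **Assignment markers.** SNPs whose genotype is strongly and consistently
   associated with one species across all populations.

Clonal structure is read from allele-sharing distances: within-pond
distances are clone-scale (sequencing noise plus somatic mutation),
between-pond distances are dominated by which founder clone colonized each
pond, and a weak increase of distance with geography (isolation by
distance) sits on top.

## Synthetic cohort model

The generator (`lemnapop.cohort`) produces exactly the structure the
analyses assume, with hidden truth retained for parameter-recovery tests.

- **Geography.** Ponds are placed uniformly in a square of side
  `region_extent_km` (default 200 km, the scale of a regional survey).
- **Founder frequencies.** Per site, an ancestral alt frequency is drawn
  from Uniform(0.05, 0.95). Isolation by distance enters as a per-site
  random planar gradient added on the logit scale, scaled by
  `ibd_strength` (default 1.0: logit shifts of order ±1 across the region),
  so nearby ponds get correlated local frequencies. Each pond then drifts
  by the Balding–Nichols model: frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
  with F = `fst_drift` (default 0.2, moderate differentiation). With
  F = 0 the drift and gradient degenerate and every pond returns the
  ancestral frequency exactly. A fraction `fixed_diff_fraction` (default
  0.1) of sites is fixed between the parents: alt frequency 0 in every M
  lineage and 1 in the T lineage.
- **Samples.** Species-1 ponds are diploid (M/M); species-2 ponds carry the
  hybrid configuration (`sp2_ploidy`, default M/M/T; M/T and M/T/T
  available). One founder genotype is drawn per pond; every sample copies
  it and then differs per site with probability `clone_mutation_rate`
  (default 10⁻³, one random haplotype flipped) — vegetative propagation
  with somatic mutation. True dosage per site is recorded
  (∈ {0, 1/3, 1/2, 2/3, 1}).
- **Reads and calls.** Depth ~ Poisson(`mean_depth`, default 60; the
  sequencing effort per sample is held constant across ploidies). Alt reads
  ~ Binomial(depth, d(1−e) + (1−d)e) with d the dosage and e =
  `error_rate` (default 0.001), a symmetric per-read error with no mapping
  bias. The diploid caller is emulated with fixed thresholds on the alt
  fraction: ≤ 0.15 → 0/0, ≥ 0.85 → 1/1, else 0/1; no call below depth 4.
  The thresholds are placed so that binomial noise at depth ≥ 10 rarely
  flips a diploid call; note that triploid 1/3-dosage sites sit only ~3
  binomial standard deviations above the 0.15 threshold at depth 60, so
  triploid clone-mates differ at a ~10⁻³/site rate even without somatic
  mutation — real callers behave the same way. Genotypes are additionally
  masked missing with probability `missing_rate` (default 0.02). Site QUAL
  is min(99, 3 × mean depth), an arbitrary monotone stand-in whose ordering
  is all the filter tests need.
- **Mapping modes.** `minor_ref` (default) emulates alignment to the
  single-species M reference: all haplotypes contribute to each site, so
  hybrid allele balance shows the 1/3 signal. `combined_ref` emulates the
  concatenated M+T reference: each haplotype contributes only to its own
  sub-genome's contig (sites are split between an M and a T contig), with a
  small cross-mapping rate (0.0005 of `mean_depth`) leaking onto the absent
  sub-genome, as residual mis-mapping does after mapping-quality filtering.
  The two modes mirror the two alignments a real study runs.

Determinism: one `numpy` Generator seeded from `CohortSpec.seed` drives all
stages in a fixed order, so identical specs give byte-identical VCFs.

What the generator does **not** model: linkage disequilibrium (sites are
independent), indels and multi-allelic sites, pooled samples (a real sample
may pool tens of fronds; the generator models one clone per sample),
mapping bias between sub-genomes, and any asymmetric base-error process.
Consequently a passing test suite demonstrates correctness of the
estimators under the stated sampling model, not robustness to
reference-bias artifacts — notably, the empirically observed tendency of
real allele-ratio modes to sit slightly below theory is not reproduced by
this symmetric error model, and tests assert the theoretical modes.

## Variant filtering

Sites pass when QUAL ≥ `qual_min` (20) **and** at least
⌈`completeness` × n_samples⌉ samples have `dp_min` ≤ DP ≤ `dp_max`
(10–1000). All bounds are inclusive and the completeness count rounds up —
the conservative reading where boundary semantics are not otherwise
dictated. Coverage is taken from DP by default with an AD-sum fallback for
callers that omit DP. Multi-allelic and non-SNP records are dropped at read
time (the three-level genotype coding assumes biallelic states).
Filtering is idempotent and never drops samples.

## Distances

The allele-sharing distance is the mean over pairwise-complete sites of
|g₁ − g₂|/2, g ∈ {0, 1, 2}. Unphased het-vs-het counts as zero difference:
"fraction of alleles that differ" is ambiguous without phase, and the
dosage metric is the deterministic resolution (documented and
oracle-tested). Pairs with no shared called sites are flagged NaN, never
silently 0, and per-pair shared-site counts are stored so low-overlap pairs
can be screened. Kinship matrices convert to distances as 1 − K with the
diagonal forced to 0 and negative entries floored (with a warning).
Clustering is scipy average linkage by default, exported as newick, with
flat groups at a user height; the pipeline's default cut (0.05) sits an
order of magnitude above clone-scale distances and well below between-pond
distances.

## k-mer kinship

The reference-free path counts canonical k-mers (lexicographic min of a
k-mer and its reverse complement; k must be odd, default 31) above a
per-sample count threshold (`min_count` = 2, discarding sequencing-error
singletons). Kinship between two samples is the fraction of polymorphic
k-mers (present in ≥ 2 and ≤ n−1 samples) with identical presence state.
This is deliberately not a reimplementation of any external k-mer GWAS
kinship estimator — those pipelines are used as black boxes and their
internals are replaceable; the module exists to support the comparison of
reference-free with alignment-based structure, which it reproduces (Mantel
r > 0.7 against SNP distances on simulated cohorts, near 1 in practice).

## Assignment-marker scan

Per site, binary species membership is regressed on the genotype factor
under three codings — the three-level factor and the two
dominant/recessive collapses (0/0 vs rest; 1/1 vs rest) — and the coding
with the highest %-DEV is kept (ties prefer the two-level codings, which
spend fewer degrees of freedom). For a single categorical predictor the
logistic ML fit is closed-form (fitted probability per level = group
proportion in that level — the fixed point IRLS converges to), so fits are
exact and fast, and perfect separation is handled without iteration:
residual deviance below 10⁻⁸ reports %-DEV = 100, a `separated` flag, and
a p-value computed with deviance and dispersion floored at 10⁻⁸. The F
statistic is ((D₀ − D)/Δdf)/φ̂ with φ̂ the Pearson dispersion of the fitted
model (the quasibinomial convention), referred to F(Δdf, n − levels).

One p-value per site (the selected coding's) enters Benjamini–Hochberg
across all scanned sites. This post-selection FDR replicates the standard
procedure and is mildly anti-conservative in the mid-range of the p
distribution; the significance rule (FDR < 0.05 **and** %-DEV ≥ 80,
inclusive) is driven by the effect-size threshold, which no null site
approaches at realistic sample sizes. Sites with fewer than 3 called
samples per group, or a single observed genotype level, are skipped.

**Calibration testing.** At n = 24 the F statistic's null support is a
finite set of contingency tables, so raw p-values are discrete and cannot
be distribution-uniform no matter the implementation; a plain
Kolmogorov–Smirnov test against Uniform(0,1) rejects for any discrete
statistic at these sample sizes. Uniformity is therefore checked the
standard way for discrete p-values: each observed p is mapped through its
exact label-permutation null CDF (enumerated via the multivariate
hypergeometric distribution of per-level group counts) with randomization
within atoms; the transformed values are exactly uniform under the null
and are KS-tested. Tail calibration — the fraction of null p-values below
0.05, which is what FDR control consumes — is additionally asserted
directly and holds without adjustment.

## Allele-balance ploidy inference

Only 0/1 calls with AD depth ≥ `min_depth` (20) enter a sample's spectrum:
homozygous calls contribute only error noise, and below ~20× the binomial
spread of the 1/3 and 1/2 modes overlaps badly (SD ≈ 0.11 at 20×). The
histogram uses 1%-bins over (0,1). Because the alt fraction takes discrete
values k/depth, individual bins can be artificially fat or thin depending
on where those atoms fall relative to bin edges; a plain smoothed argmax
can therefore sit a bin sideways of the true mode (at depth ≈ 60 the
k = depth/2 ± 1 atoms land asymmetrically around the 0.50 edge). The mode
estimator consequently works in two stages: a 3-bin moving average locates
the peak neighborhood, and the maximum raw bin within that neighborhood is
reported. This keeps the estimator in the histogram family (a mixture-model
fit is out of scope) while removing the quantization artifact; modes land
within one bin of 1/3, 1/2 and 2/3 across seeds.

Classification windows are placed midway between adjacent theoretical
modes, with extra allowance below 1/3 and above 2/3 because observed
ratios in real data run slightly low: [0.28, 0.41) → M/M/T,
[0.45, 0.55] → diploid het, (0.59, 0.72] → M/T/T. A spectrum with fewer
than 200 usable sites is UNINFORMATIVE; a mode outside every window, or
two windows within 10% mass of each other, is AMBIGUOUS. Confidence is the
mass fraction in the winning window.

Sub-genome coverage summaries report mean DP per sub-genome tag, the M:T
ratio, and the fraction of T sites with nonzero depth; < 5% covered T
sites → pure species, ratio in [1.5, 2.5] → M/M/T, [0.75, 1.33] → M/T,
[0.4, 0.67] → M/T/T, else flagged. Splitting SNPs by sub-genome and
correlating the per-partition distance matrices (Mantel) tests whether
both sub-genomes carry the same post-hybridization structure — near 1 for
a single-origin hybrid cohort.

## Structure statistics

Distances to group centroids use the principal-coordinates construction:
eigendecompose the double-centered −½D², embed on positive-eigenvalue axes
and "imaginary" negative-eigenvalue axes, and compute squared centroid
distance as the positive-axis deviation minus the negative-axis deviation,
floored at 0 (the standard correction for non-Euclidean distance
matrices; verified against the reference R implementation with
`type="centroid"` and against coordinate-space oracles). The dispersion
test is a one-way ANOVA F on centroid distances with a group-label
permutation p-value (centroids recomputed per permutation).

Mantel tests correlate off-diagonal upper triangles (Pearson), jointly
permuting rows and columns of the second matrix. All permutation p-values
use the observed-included convention p = (1 + #{stat ≥ obs})/(1 + nperm),
whose floor at 9999 permutations is exactly 0.0001. Isolation by distance
floors physical pair distances at 1 m before log10 (co-located samples
would otherwise produce −∞; an exclude-within-pond flag is available for
the regression) and supplements the Mantel test with an OLS ANOVA of
genetic on log-physical pair distance — reported with the caveat that
pairs are not independent, so the permutation test is the inferential
statement. Geographic distances are great circles on a 6,371,000 m sphere;
out-of-range latitudes fail loudly (a swapped lat/lon column is a classic
metadata error).

Note that sample-level IBD tests on clonal cohorts are confounded at lag
zero: clone-mates are both co-located and genetically identical, which
alone produces a positive Mantel statistic. Null-calibration experiments
therefore use one sample per pond; applied analyses should either do the
same or interpret the within-pond contribution explicitly. An exclusion
list in the pipeline config removes flagged outlier samples without any
algorithmic special-casing.

## Pipeline

`run_pipeline` chains simulate/load → filter → distances/clustering →
species split → scan → ploidy → structure and writes a JSON report with
every threshold echoed, per-file SHA-256 checksums, per-stage timings and
seeds. The species split uses, in order of preference: sub-genome coverage
calls (when both sub-genome tags are present), allele-balance dosage
classes (diploid vs triploid — available from any single-reference VCF
with AD), and a two-way tree cut as last resort; the report records which
rule fired. The two-way cut is known to be fragile when between-pond
distances within a species approach between-species distances, which is
why the dosage rule outranks it.

## Problem sizes

Defaults are chosen at the scale of a regional survey (12 ponds, 3–6
samples each, 4000 SNPs, 60× depth) so that a full simulate-analyze-verify
cycle completes in seconds; calibration suites (hundreds of replicate
cohorts, thousands of null sites) complete in minutes. All sizes are
plain parameters and scale up without code changes.
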