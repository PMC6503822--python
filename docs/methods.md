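# Methods

herdscan reimplements, as one tested pipeline, the computational core of a
whole-genome diversity and demography analysis for diploid livestock
genomes: per-site heterozygosity from read pileups, run-of-homozygosity
(ROH) detection, genotype QC and LD pruning, the three-population f3
admixture test, and LD-decay-based effective-population-size estimation.
Every stage is validated by parameter recovery on synthetic data whose
generative laws are stated below.

## Data model

The sequencing stages consume per-site pileups: `(chrom, pos, depth, nA,
nC, nG, nT)` with 1-based positions, produced upstream from alignments
(mapping/base-quality filtering is assumed done there). The genotype stages
consume diploid biallelic genotype matrices (alt-allele dosage 0/1/2,
missing), read from VCF. Intervals are 0-based half-open internally; BED
output keeps that convention, pileup/VCF positions stay 1-based on disk.

## Site filtering and heterozygote calling

Only sites with depth between 4 and 30 (inclusive) are used, trimming both
unreliable shallow sites and collapsed-repeat pileups. A site is called
heterozygous when its second-most-frequent base is covered by at least 2
reads *and* at least 20% of the reads — the allele-support thresholds of
common short-read callers. Both knobs, and whether the two thresholds are
combined with AND or OR, are configurable; the joint (AND) rule is the
default because the OR variant lets a single error read at depth 4–5 pass
the fraction branch, which at realistic error rates floods low-diversity
tracts with false heterozygotes.

The joint rule has a known cost: at a true het site the minor allele is
read `min(X, d−X)` times with `X ~ Binomial(d, 1/2)`, so at depth 4 a
true het is missed 62.5% of the time and at mean depth 10 roughly 8% of
hets are dropped overall. This *allele dropout* is fully determined by the
call rule and the observed depths; `het_call_sensitivity` computes
`s(d) = P(min(X, d−X) ≥ threshold(d))` exactly, and rate estimates that
should be comparable to θ (π_in/π_out below) divide the het count by
`Σ s(d_i)` instead of the plain site count. The correction has no free
parameter. Raw fractions are always reported alongside.

## Windowed heterozygosity

Non-overlapping windows (default 10 kb) tile each chromosome from
coordinate 0; each window reports covered sites, het calls and their
ratio. Windows whose covered fraction falls below `min_covered_fraction`
(default 0.2, our choice — sparse windows otherwise produce wild rates)
are flagged and excluded from genome-wide averages. Pooled window counts
reproduce the genome totals exactly (a conservation property the tests
assert).

## Joint ML estimation of θ and ε

Per filtered site with sorted base counts `n1 ≥ n2 ≥ n3 ≥ n4` and depth
`d`, the likelihood is a two-component mixture:

* homozygous (weight `1 − h`): the true base is the major base; each read
  errs with probability ε, uniformly over the other three bases —
  multinomial with `p = (1−ε, ε/3, ε/3, ε/3)`;
* heterozygous (weight `h = θ/(1+θ)`): the two true alleles are the two
  most frequent bases; a read picks either allele with probability 1/2 and
  then errs the same way — `p_allele = (1−ε)/2 + ε/6` for each allele,
  `ε/3` for each other base.

`h = θ/(1+θ)` is the stationary single-site heterozygosity under the
infinite-allele approximation, so for small θ the estimate is directly the
per-site heterozygosity. Sites are pooled by their sorted count vector
(a sufficient statistic under both components), reducing a 5-Mb genome to
a few thousand weighted classes; the summed log-likelihood is maximised
with L-BFGS-B in log-parameter space from a 3×2 multistart grid
(θ ∈ {1e-4, 1e-3, 1e-2} × ε ∈ {1e-3, 1e-2}) because the mixture surface
can be flat near the boundary. Estimates pinned to the box are flagged
`at_bound`; inputs under 1,000 sites are flagged `low_confidence`. This is
a reimplementation of the model class, validated by recovery (θ within
10%, ε within 25% on 5-Mb simulations at θ=ε=0.002, depth 10), not by
matching any particular tool's output bit-for-bit.

## ROH calling

The genome is tiled into consecutive 10-kb bins; each informative bin
carries its het-call count ("SNP count"). With `A` the genome-wide mean
SNP count per informative bin, the caller scans each chromosome:

1. a bin is **low** when its count is `< 0.25·A`;
2. a candidate run opens at a low bin and ends at a low bin; between low
   bins it may pass over bins of ordinary diversity provided each stays
   `≤ 2·A` (the relaxation that absorbs isolated assembly/alignment
   artifacts inside a genuine tract);
3. whenever the run reaches a further low bin, its mean count must remain
   `≤ (2/3)·A`; the scan stops at the first violation and the candidate is
   trimmed back to the last low bin reached;
4. runs are emitted iff they span ≥ 20 bins and ≥ 20×bin_size bp; the scan
   resumes after an emitted run, so calls are disjoint.

Two prose-level ambiguities had to be made precise. First, requiring runs
to *end* at low bins is essential: if ordinary-diversity bins may trail a
run (with only the 2/3 running-mean rule as a brake), a finished tract of
~37 low bins can drag in ~28 average bins before the mean budget runs out,
which destroys boundary accuracy and bin-level precision; with low-bin
endpoints, boundaries land within one bin of the planted truth. Second,
the "at least 20 kb" minimum length is inconsistent with "20 consecutive
10-kb bins" (= 200 kb); the bin rule is operative and the length floor
defaults to `min_bins × bin_size`, overridable. Bins with fewer covered
sites than 20% of their width are *no-data*: they neither extend nor break
a run when at most 2 consecutive; 3+ consecutive break it (our choice —
a conservative gap rule). The seed comparison uses SNP *counts* against
0.25× the mean count per bin; with uniform coverage this equals comparing
per-bp diversities, and a per-bp mode is exposed through the summary's raw
rates.

An O(n²) brute-force enumeration (slice sums recomputed from scratch,
no shared code) reproduces the scanner bin-for-bin on random genomes; the
suite checks 50 genomes of up to 2,000 bins per run.

`summarize_roh` reports N_ROH, cumulative length, F_ROH = cumulative
length / assayed (informative-bin) length, and dropout-corrected π inside
and outside the ROH union.

## Genotype QC and LD pruning

QC applies, in fixed order: drop samples with > 10% missing calls, then
variants missing in > 5% of the retained samples, then variants with MAF
< 1% — recomputing statistics on the retained samples so the filter is
idempotent. LD is the squared Pearson correlation of dosages over
pairwise-complete samples (composite, genotype-based r²; phasing is out of
scope, and for array-density data composite r² is standard practice).
Pruning is greedy within 50-SNP windows advancing by 5 (window/step are
not dictated by the r² target and follow common tool defaults): while any
retained window pair exceeds r² = 0.10, the lower-MAF member of the worst
pair is dropped (tie: later position); passes repeat until a full pass
drops nothing, so windows are always evaluated on the retained SNP
sequence. Because windows start at multiples of the step, the guarantee
covers pairs within `window − step` SNPs of each other (the envelope every
evaluated window spans); the tests audit exactly that envelope,
exhaustively, on panels with planted LD blocks.

## Three-population f3

For target C and references A, B with per-variant sample frequencies
`a, b, c` and `n` non-missing target allele copies:

    D_i = (c_i − a_i)(c_i − b_i) − c_i(1 − c_i)/(n_i − 1)

The subtracted term removes the target's sampling-noise bias (the target
frequency enters the product twice); reference noise inflates variance
only, so it is left uncorrected. f3 is the unweighted mean of `D_i` over
variants polymorphic in at least one population; the standard error is a
delete-one-block jackknife over contiguous blocks of 1,000 SNPs in genome
order (weighted form for the shorter final block), robust to local LD.
Z = f3/SE, with Z < −3 declared significant. Genetic-distance blocking is
not provided (no recombination map in scope). On Balding–Nichols panels
the population-level limit `f3 → −α(1−α)·mean((p_A−p_B)²)` as target
drift vanishes is exact and is used as the test oracle.

## LD decay and Ne

All intra-chromosomal variant pairs with 5,000 ≤ |Δpos| ≤ 2,000,000 bp
(bounds inclusive; MAF ≥ 0.05) are assigned to 50 equal-width distance
bins; each pair contributes `r²_adj = r² − 1/n` (n = complete-case sample
count), removing the finite-sample inflation of the dosage correlation.
Physical distance maps to recombination fraction at a constant 1 cM/Mb
(`c = bp × 1e-8`, configurable); each bin is inverted through Sved's
equilibrium approximation

    E[r²] ≈ 1/(1 + 4 Ne c)   ⇒   Ne(c) = (1/(4c)) (1/r²_adj − α)

with α ∈ {1, 2, 2.2} encoding the mutation model (default 2), and dated at
t = 1/(2c) generations before present. Bins with fewer than 100 pairs or
outside the invertible domain are skipped with a warning. The inversion is
exact on closed-form Sved values (round-trip test) and recovers Ne = 500
within 25% from two-locus Wright–Fisher simulations.

## Synthetic-data generators

The generators' defaults are the operating conditions of the recovery
benchmarks; they emulate the statistical structure the estimators assume,
not read-level realism (no mapping error, CNV depth structure, indels or
phasing).

**Pileup genome.** Each site is heterozygous independently with
probability θ (θ times a residual factor inside planted tracts); depth is
Poisson (mean 10 in the benchmarks; sites with zero depth are not
emitted); reads err with probability ε uniformly to the other three
bases. θ is parameterised directly as P(het) — valid for θ ≪ 1 — so every
recovery target stays analytic; there is no coalescent machinery. Planted
tracts are bin-aligned and separated by at least 40 bins (400 kb). The
separation is a resolvability condition of the benchmark design: the
caller's relaxation rules can legitimately bridge two low tracts through
up to ~27 bins of ordinary diversity before the 2/3 mean budget runs out,
so closer tracts merge and bin-level precision against the planted truth
stops being well defined. Benchmarks use ε = 0.002, a typical short-read
substitution error rate and the same value as the θ/ε recovery condition.

**Admixed panel.** Ancestral frequencies are uniform on [0.05, 0.95];
populations A and B drift via Balding–Nichols (Beta with drift F = 0.05 in
the benchmarks); the target's pre-drift frequency is `α p_A + (1−α) p_B`
followed by its own drift (F = 0.001); genotypes are Binomial(2, p). True
frequencies are stored in the truth record, making the population-level
f3 computable exactly as an oracle.

**Two-locus Wright–Fisher.** Many independent systems of 2·Ne haplotypes
over two loci, initialised at frequency 0.5 per locus in linkage
equilibrium and resampled multinomially each generation after
deterministic recombination (D decays by factor c per generation). The
default burn-in of Ne generations is several times the LD relaxation time
`1/(c + 1/(2Ne))` whenever 4Nec ≳ 1, long enough for equilibrium r²;
longer burns only lose systems to fixation (which thins the usable pairs
and roughly doubles the estimator's replicate SD at 2Ne) without changing
equilibrium LD. Optional epochs append population-size changes after the
burn-in, which is how the bottleneck contrast is simulated. Sampling is
without replacement (multivariate hypergeometric) and the two loci are
placed at the physical distance that maps back to c at 1 cM/Mb.

## Problem sizes used by the shipped experiments

The test suite runs the benchmarks at 10-Mb genomes (20 seeds) for ROH
recovery, 5-Mb genomes (20 seeds) for θ/ε, 50k-SNP panels (20 + 20 seeds)
for f3, one 2,000-system WF panel for Ne, and 20 replicate pairs for each
demographic contrast. `scripts/acceptance.py` reports the same quantities
from 3–10 fresh seeds per stage, derived from its `--seed` argument. The
analysis drivers under `analysis/` use one mid-sized instance of each
input so a full narrative run completes in about a minute.

## Known limitations

* The pileup generator draws sites independently; it cannot exercise
  linkage structure in the θ estimator (none is assumed) and its planted
  tracts are sharp-edged, unlike coalescent IBD segments.
* π corrections assume the binomial allele-sampling model; systematic
  allele bias (reference bias, mapping bias) is not modelled.
* Composite r² differs from haplotype r² when genotype frequencies depart
  from Hardy–Weinberg; the Ne estimator inherits that approximation.
* The physical→genetic map is a global constant; a recombination-map mode
  is deliberately out of scope.
* f3 is implemented for a single target trio at a time; no f4/D statistics
  or graph fitting.
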