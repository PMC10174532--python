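# Methods

## The mapping problem

A bulk-segregant experiment compares two pools of cells drawn from the
extremes of a phenotype distribution in a recombinant haploid population
from a BY × RM yeast cross. At a locus affecting the phenotype, selection
enriches one parental allele in the high pool and depletes it in the low
pool; everywhere else the pools share the population frequency of ~0.5.
The package turns per-marker pooled allele counts into LOD scores, QTL
calls, and cross-reporter overlap statistics, and ships a forward simulator
whose ground truth makes every stage testable.

Sign conventions are fixed package-wide: genotype 0 = BY, 1 = RM; phenotype
is the TFT degradation score −log₂(RFP/GFP), higher = more proteasome
activity; ΔAF = RM frequency (high pool) − RM frequency (low pool), so a
positive ΔAF means the RM allele increases activity.

## Simulator

**Recombination.** Meiotic products are generated per chromosome: the
starting parent is Bernoulli(½) and crossovers follow a unit-rate Poisson
process on the genetic map (Haldane model, no crossover interference).
The physical↔genetic scale is a single parameter, 2,200 bp/cM, matching
the BY × RM cross. Between adjacent markers d bp apart the implied phase
switch probability is r = ½(1 − e^(−2d/(100·2200))). Implementation note:
crossovers are bucketed into marker intervals and genotypes are cumulative
parities; the cumulative sum runs in int8 and is allowed to wrap, which is
exact mod 2 and keeps a 50,000 × 18,871 genotype matrix under 1 GB.

**Phenotype.** Strictly additive: the sum of signed locus effects (in units
of the residual SD) over RM-carried loci, plus Gaussian(0, noise_sd) noise.
Epistasis is deliberately excluded — pooled sequencing cannot detect it, so
simulating it would only blur the calibration the tests measure.

**Selection.** The top and bottom `fraction` (default 2%) of phenotypes
form the tails; `n_cells` (default 20,000) cells are sampled from the tail
without replacement when the tail is large enough, with replacement
otherwise (a sorter can re-encounter clonal copies). Benchmark runs use
50,000 segregants so a 2% tail holds 1,000 distinct genotypes — the same
number the LOD model assumes as its effective pool size, which makes the
calibration experiments self-consistent. The real experiment sorts from a
much larger population; a configurable `n_segregants` covers that case.

**Sequencing.** Per-marker depth is Poisson(coverage), default 21, the
median coverage of the motivating experiment; the RM read count is
Binomial(depth, pool frequency), optionally Beta-Binomial with dispersion
ρ (trials share a Beta(p·(1−ρ)/ρ, (1−p)·(1−ρ)/ρ) frequency). Default ρ = 0:
only coverage summaries are known for the real data, and the effective-pool
correction already absorbs the dominant extra-binomial variance. No
read-level error model is simulated; the marker panel is taken as given.

## Allele-frequency tracks

Zero-depth markers are dropped (frequency undefined), then markers with raw
per-pool frequency strictly below 0.1 or strictly above 0.9 are removed as
artifact-prone; boundary values stay. Frequencies are smoothed per
chromosome by local-linear loess. The window is expressed in bp (default
50 kb) and converted to a per-chromosome fraction, because QTL support
intervals are tens of kb and the smoothing must not erase them; smoothing
never crosses chromosome boundaries and fits are clamped to [0, 1]. ΔAF is
the difference of smoothed tracks on the shared marker set.

## LOD model

Counts are summed into 100-bp bins (right edge inclusive) and pooled along
the chromosome with a Gaussian kernel (SD 10 kb, truncated at 4 SD, never
crossing a chromosome boundary). The pooled totals are then rescaled by the
harmonic effective-size correction n′ = n·N/(n+N), N = 1,000: a pool
contains N independent genomes, so the variance of a frequency estimate
from n reads is ≈ p(1−p)(1/n + 1/N), which equals a binomial with n′
trials. The correction is applied **after** kernel pooling, not per marker:
reads at nearby markers resample the same N genomes, and capping the pooled
total is what actually bounds the information at N. (Applying it per marker
and then summing lets the trial count grow past N with marker density,
inflating LOD under the null.)

Per bin, LOD is the log₁₀ ratio of the causal model (each pool at its own
binomial MLE k/n) to the noncausal model (both pools at the pooled MLE).
The MLEs make the ratio closed-form; 0·log 0 is treated as 0, zero-depth
bins score 0, and non-integer kernel-weighted counts are handled by the
xlogy form (binomial coefficients cancel). Bulk-segregant studies usually
compute this statistic with the MULTIPOOL tool, whose information sharing
is a dynamic-Bayesian-network smoother; this package replaces that with
the transparent kernel scheme above and does not attempt to reproduce
MULTIPOOL's exact LOD values, only the two-model likelihood ratio, the
100-bp bins, the 2,200 bp/cM scale, and the N = 1,000 pool size.

**Calling.** QTLs are maximal runs of bins with LOD ≥ 4.5 (the threshold
empirically calibrated to a 0.5% FDR for this reporter system; no per-run
permutation). The peak is the leftmost maximal bin (deterministic
tie-break); the support interval extends outward to the first bins where
LOD ≤ peak − 2 and is clipped at chromosome ends (a clipped bound is
reported as the end coordinate); the direction is the sign of ΔAF linearly
interpolated at the peak. Reported QTLs must appear in both biological
replicates with peaks within 100 kb and the same direction (greedy
nearest-peak pairing); reported values — peak, LOD, ΔAF, and the interval
bounds themselves — are arithmetic means of the two replicates (averaging
bounds, rather than taking the union of intervals, is a deliberate choice).

## Overlap statistics

Two QTLs overlap when their peaks are within 100 kb on the same chromosome
and their ΔAF signs agree. A ΔAF of exactly 0 has no direction and raises
an error rather than guessing (it does not occur in the packaged table).
The overlap fraction between two reporters is matched pairs / (matched
pairs + unmatched QTLs of both sets), with one-to-one greedy nearest-peak
matching; this convention reproduces the published value of 0.2 for the
ODC/Rpn4 pair (3 pairs, 8 + 4 reporter-specific QTLs). Distinct loci are
single-linkage connected components of the overlap relation across all
sets — single linkage (rather than complete) reproduces the published
18 → 15 reduction. Pairwise overlap matrices filter out sets with fewer
than 7 QTLs, the smallest reported set size.

## Flow cytometry

Event processing follows the standard TFT analysis: per-replicate median
forward-scatter gate (±10% for flow analysis, ±7.5% available for sorting
gates), −log₂(RFP/GFP) scoring with non-positive intensities dropped and
tallied, per-replicate OLS regression of score on acquisition time with the
residual-plus-mean as the corrected score (the mean is re-added so group
contrasts stay interpretable), and z-scoring of replicate medians with the
control group's median mapped to 0. The drift regression is per replicate
by default (the alternative, per plate, is a trivial relabelling of the
replicate column). Doublet removal and FCS binary parsing are out of scope;
the module reads delimited event tables. The synthetic event generator uses
log-normal intensities with a configurable per-group mean score and linear
drift — enough to exercise every processing step, but it does not emulate
spectral spillover, maturation kinetics, or autofluorescence.

## Calibration experiments and their scale

Two benchmark loops characterise the caller end to end (both seeded, both
shared by the test suite and the acceptance script):

- **Recovery**: 20 full-scale experiments (16 chromosomes, ~12.07 Mb,
  18,871 markers, 50,000 segregants, 2% tails, pools of 20,000, coverage
  21, two replicates), each planting three QTLs of 0.75/1.0/1.25 SD with
  random signs and positions on distinct chromosomes. A locus counts as
  recovered if a concordant call lands within 30 kb with the correct sign.
- **FDR**: 100 experiments on the desk-scale genome (16 × 75 kb, markers
  every 640 bp — the full-scale marker density on a smaller genome), each
  planting three 1-SD QTLs and leaving 13 chromosomes null. A concordant
  call with no planted locus within 100 kb is a false discovery.

The desk profile exists so that a single experiment runs in ~2 s and the
hundred-experiment calibration stays a few minutes; the recovery loop runs
at full scale because peak-localisation error only makes sense on real
chromosome lengths.

What passing these tests shows — and what it does not. The simulator
realises exactly the model the caller assumes (binomial sampling, additive
phenotypes, no interference, no sequencing error, known marker panel), so
the benchmarks measure the *method's* calibration, not robustness to
model misspecification. Real data add alignment artifacts, segmental
coverage variation, and selection imperfections that the 0.1–0.9 AF filter
only partially absorbs. One systematic effect visible in the benchmarks:
at strong planted effects the pool frequencies approach the 0.1/0.9 filter
bounds, censoring flattens the LOD summit, and peak estimates can wander a
few tens of kb even when both replicates agree — weaker, realistic effects
(|ΔAF| ≤ ~0.25) do not reach the bounds and do not show this.

## Numerical choices

- Loess uses zero robustness iterations (no outlier reweighting): the
  binomial noise has no heavy tails, and the estimator stays exactly linear
  on linear signals (tested to 1e−6).
- The loess fraction is floored at 3 points so local fits are determined;
  chromosomes with < 5 markers pass through unsmoothed with a warning.
- Greedy matchings (replicate pairing, overlap pairing) sort candidates by
  peak distance, making results order-independent and deterministic.
- All randomness flows through numpy `SeedSequence` spawning: one run seed
  derives per-replicate and per-stage (genotype / phenotype / sorting /
  sequencing) streams, so a stage can be varied without touching others and
  reruns are byte-identical.
- `kernel_sd_bp = 0` is accepted as "no pooling" for degenerate-kernel
  checks; otherwise the kernel SD must be at least one bin.

## Known limitations

- The LOD values are not numerically comparable to MULTIPOOL's; only the
  model class and settings correspond.
- Heritability and variance-explained are not estimated, and epistasis is
  not detectable — inherent to pooled designs.
- The overlap fraction depends on the one-to-one matching convention; sets
  with genuine many-to-many structure have no unique answer, and the greedy
  rule is a documented determinism choice.
- The simulator does not model diploid intermediates, mating-type or
  selection-marker genetics, read-level errors, or FASTQ output.
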