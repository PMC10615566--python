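# Methods

`popscan` implements a genome-scan workflow for recent positive selection in
a cohort stratified into subpopulations: quality control and
population-structure stratification of phased SNP array data, per-group
integrated-haplotype-score (iHS) scans, Hudson F_ST differentiation scans
between groups, and identity-by-descent (IBD) based density-of-recent-
coalescence (DRC) scans with an empirical Gamma null, followed by
multiple-testing thresholds, locus merging, and structural-variant
exclusion. Because cohort genotypes of this kind are not publicly
redistributable, the package ships a forward simulator that generates
phased two-subpopulation panels with known ground truth; every statistic is
validated against those simulations and against independent naive
reimplementations of the exact quantities.

## Quality control

Variants are removed when call rate < 97% or the exact Hardy–Weinberg
test's two-sided p-value is below 1e-6 in the pooled sample. The HWE test
is the standard conditional exact test: given the allele counts, the
probability of every possible heterozygote count is computed (in log space
for stability) and the p-value sums the probabilities no larger than the
observed count's. Deviations caused purely by stratification (the Wahlund
effect) are recovered in a second stage: a variant failing pooled HWE is
kept iff it passes HWE at the same level in *every* subgroup separately.
The `QcReport` reconciles exactly: final = initial − removed + recovered.

Relatedness uses a method-of-moments pi-hat from genome-wide
identity-by-state counts with allele-frequency correction (expected IBS
profiles for IBD states 0/1/2 inverted for P(IBD=k); pi-hat = P(IBD=1)/2 +
P(IBD=2), clipped to [0,1]). One member of each pair with pi-hat >= 0.25 is
dropped, greedily by number of flagged pairs, then lower call rate, then
input order (the removal order is a package choice; any defensible order
yields an unrelated set).

Structure: LD pruning with a 100-SNP window, 10-SNP step, genotype r² >
0.2 (later-indexed SNP removed; MAF >= 5% floor; missing genotypes
mean-imputed for the correlation only), then PCA on centered,
frequency-standardized dosages via SVD (top 20 components by default), and
a single-pass outlier rule removing samples more than 3 SD from the mean on
PC1 or PC2.

## iHS

For a core SNP, EHH(x) of one allele is the probability that two randomly
drawn carrier haplotypes are identical at every marker from the core out to
distance x. The implementation walks outward refining an identity
partition of the carriers (one numba-compiled pass per side) and is tested
against a brute-force pairwise enumeration. iHH integrates EHH over genetic
distance by the trapezoid rule, proceeding outward and stopping after the
first marker whose EHH falls below 0.05 (that crossing trapezoid is
included — the integration boundary is fixed and documented so it is
testable). Curves hitting the chromosome edge first are flagged
edge-truncated. No between-marker gap penalty is applied: array-density
data (and the simulator) have near-uniform marker spacing.

iHS_raw = ln(iHH_ancestral / iHH_derived), computed for variants with MAF
>= 1% and an established ancestral state; zero-iHH variants are flagged
undefined. Raw scores are standardized within 100 equal-width
derived-allele-frequency bins (sample SD, ddof 1; bins with fewer than two
defined scores are flagged, never imputed). P-values are two-sided normal,
p = 2·Φ(−|z|): selection can lengthen either allele's haplotype background,
so both tails are informative.

## Hudson F_ST

Per SNP, N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) and
D = p1(1−p2) + p2(1−p1); multi-SNP summaries use the ratio of averages
ΣN/ΣD with a delete-one-block jackknife SE over contiguous variant blocks
(default 100 blocks; the block count should keep blocks much longer than
the local LD scale — the validation studies use 20 blocks of 6 cM).
Approximate one-sided p-values model the positive part of the per-SNP
estimates as a scaled chi-square with 1 df (a biallelic per-SNP
differentiation statistic has one degree of freedom); the scale is a moment
fit, c = mean of max(fst, 0)/df. Negative estimates keep their reported
value but map to p = 1. The 2×2 Pearson chi-square (df 1, no continuity
correction) and the haplotype LD r² helper support allele-frequency
contrasts between groups.

## IBD and DRC

IBD detection is a hash-seeded match-and-extend heuristic in the GERMLINE
family, replacing a coalescent-HMM decoder: windows of `seed_snps`
consecutive *informative* markers (sample MAF >= 5% — rare-allele runs
match between any two haplotypes and would seed spurious segments) are
hashed, windows start every `seed_snps`/2 markers so tracts barely longer
than one window still contain an aligned window, and identical pairs are
extended in both directions. Extension tolerates isolated mismatches
(stopping where two mismatches fall closer than 1/max_mismatch_per_cM cM):
a whole-segment average-density rule cannot separate a tract from a
clustered error region, so the rule is local by design. Per-pair
extensions are merged, and segments of at least `min_length_cM` are
reported with quality = matching fraction of informative sites inside the
segment (a bounded [0,1] stand-in for a model-based posterior quality).

Segment age uses the expected-tract-length heuristic: a tract inherited
from a common ancestor g generations back has expected genetic length
100/(2g) cM, so ĝ = 50/ℓ. Consequently DRC_T is driven by segments of at
least 50/T cM (2.5 / 1 / 1/3 cM for T = 20/50/150); the age heuristic
cannot distinguish a genuinely recent tract from an old pair's
chance-long tract, which sets the background level of the statistic.

DRC_T per non-overlapping 0.05-cM bin is the quality-weighted count of
segments with ĝ <= T overlapping the bin (each haplotype pair counted once
per bin, with the larger quality on ties) divided by C(n_haplotypes, 2), so
it is a per-pair density in [0,1] and nested in T by construction. The
empirical null is a Gamma distribution fitted by maximum likelihood
(moment-fit initialization, location 0) on putatively neutral bins, defined
iteratively: fit, compute upper-tail p for all bins, exclude bins below the
exclusion alpha (default: the scan's Bonferroni threshold), repeat to
convergence. Zero-valued bins never enter the likelihood; their mass is
recorded so the p-values are explicit conditional tail probabilities. The
null is fitted genome-wide (pooling chromosomes) per timescale.

## Post-filtering

Thresholds are alpha / (tests × groups × timescales), reported at full
precision and at 3 significant digits. Significant records within 0.1 cM
merge into loci (bounds = min/max member positions, lead = smallest p).
Structural-variant exclusion retains SVs with length >= 10 kb and allele
frequency >= 1% and flags a locus iff its overlap with some retained SV is
at least 10% of that SV's length (inclusive at exactly 10%); segmental-
duplication exclusion reuses the same operation with a second interval set.
Flagged loci stay in the output with a flag rather than disappearing.

## The simulator

A founder pool of diploids carries haplotypes drawn site-wise from a
neutral SFS (density ∝ 1/x truncated to keep sites polymorphic; derived
alleles coded 1, REF fixed as ancestral). The population evolves as a
discrete Wright–Fisher process: children draw two parents
(fitness-weighted 1+s per derived focal copy under a sweep) and each
gamete recombines the parent's haplotypes with Poisson(L/100) crossovers.
After an optional split, two demes of `pop_size` diploids evolve with
symmetric per-haplotype migration. Sites are evenly spaced at 1 cM/Mb.
`sample_size` draws a cohort smaller than the population, as real studies
do. All randomness flows from one seeded generator; runs are
bit-reproducible.

Founder bottlenecks, not mutation, create LD: haplotypes are mosaics of
the founder set, so the model reproduces LD decay, EHH structure, and IBD
sharing, but not mutation–drift equilibrium, gene conversion, genotyping
error, or realistic demography. Passing tests therefore demonstrate the
statistics behave correctly under a clean, known genealogy — not that the
pipeline is robust to array artifacts.

Sweeps act on a focal biallelic site. `focal_initial_freq` pins the
founder frequency to an exact copy count; `de_novo` instead injects a
single derived copy at `sweep_start_generation`. `simulate_conditioned`
performs rejection sampling on the final focal frequency (hard sweeps are
usually lost to drift), aborting trajectories early on loss or fixation.

## Validation studies and their design

The study conditions are fixed design choices:

* **Neutral iHS calibration** — one panmictic population, 1,000 sampled
  haplotypes, 2×10⁴ markers on 200 cM. The 1%-tail check presumes the
  normal approximation for standardized iHS, which is asymptotic in
  haplotype count (at 200 haplotypes the score distribution is visibly
  platykurtic and the nominal tail under-fills); the sample is the largest
  that keeps the study in minutes on one CPU.
* **Sweep power** — hard sweep with s = 0.05: one derived copy among 600
  founder haplotypes, selected through a 150-generation expansion to a
  large population (the largest background the runtime budget allows),
  0.01 cM marker spacing over 60 cM, 300 sampled diploids, conditioned on
  focal DAF in [0.4, 0.8] at sampling. The deterministic logit arithmetic
  (−6.4 + 150·ln 1.05 ≈ +0.9) lands trajectories mid-window, and the
  expansion makes establishment nearly certain, keeping rejection rates
  low. Background coalescence depth controls the contrast: with s fixed,
  the sweep's age (~150 generations) must be much smaller than the
  population's pairwise coalescence scale for either statistic to have
  power — exactly the regime of real cohorts, where the ratio is far more
  favorable than any desk-scale simulation can afford.
* **DRC top-bin granularity** — every carrier tract covers the focal site
  *and* several neighboring 0.05-cM bins, so sweep bins tie within a few
  percent and the single argmax bin wobbles 1–3 bins around the focal site
  even when the sweep's p-value is astronomically small. Sweep detection
  is therefore scored as "the genome-wide minimum-p DRC_150 bin lies
  within ±0.25 cM (half the minimum DRC_150 tract length) of the focal
  site"; the strict same-bin rate is also reported. This is a property of
  any tract-based statistic binned finer than the tract length, which is
  why locus-level reporting (merged intervals), not per-bin ranking, is
  the right unit of interpretation.
* **Panmictic F_ST** — cohorts of 100 diploids sampled from 1,000-diploid
  demes: sampling the whole population would add sib-clustering covariance
  that SNP-block jackknives cannot see; 20 blocks of 6 cM stay well above
  the ~1 cM LD scale.
* **Structure** — split at 60 generations (expected F_ST ≈ 0.06): PC1
  separation with literally zero overlapping samples needs roughly an 8-SD
  gap between cohorts, well above the detectability threshold.

## Numerical choices and degenerate inputs

Exact HWE works in log-space weights (stable to 2n in the thousands);
monomorphic sites return p = 1. Genetic-map interpolation is
piecewise-linear with terminal-rate extrapolation floored at 0 cM.
Undetermined ancestral states are flagged and excluded from haplotype
statistics, never guessed. Gamma fits reject constant input; normalization
bins with zero spread flag their members. The Bonferroni helper rejects
zero counts. Ties in LD pruning resolve by index order; ties in
relatedness removal by the documented greedy order.

## Known limitations

The IBD age heuristic ĝ = 50/ℓ ignores the length–age distribution's
spread, so DRC backgrounds include misclassified old tracts; the Gamma
null absorbs this, at the cost of conservatism for extreme values. The
simulator's founder model caps background coalescence at the burn-in
depth, making desk-scale sweep contrast weaker than cohort-scale reality.
Phasing is assumed perfect (the simulator emits phase); phasing error
would deflate EHH and fragment IBD segments. The F_ST chi-square fit's
df = 1 is an assumption, exposed as a parameter.
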