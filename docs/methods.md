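# Methods

## Logistic estimation of r and K

Each replicate growth curve is a series of cell counts N(t) on a shared time
grid (the standard screen grid is 217 points, 0–72 h at 20-minute
intervals). We fit the logistic solution

    N(t) = K / (1 + (K/N0 - 1) e^{-r t})

by unweighted least squares, estimating all three parameters (N0, r, K)
jointly. The optimizer is a Levenberg–Marquardt iteration on
(log N0, r, log K): the log scale keeps the two population-size parameters
positive and comparably scaled across the orders of magnitude a curve spans,
and the implementation is vectorized over curves so a full simulated screen
(tens of thousands of replicates) fits in seconds on one core.

Starting values are data-driven: N0 from the first observed count (floored
at 1 cell), K from the maximum count, r from the slope of log-counts over
the first quarter of the time points. Curves for which that start stalls are
retried from a closed-form start based on the fact that 1/N(t) decays
exponentially toward 1/K, so three equally spaced points give exact
(N0, r, K) on noise-free data. Parameter bounds are r in [0, 10] per hour
and K at most 1e4 times the maximum observed count — wide enough that a
curve cut off far from saturation can still be recovered, while fits pinned
at a bound, or failing to reduce the sum of squares, are flagged
`converged = False` and never enter downstream analyses. A count of exactly
zero at t = 0 is replaced by the smallest positive observed count. Goodness
of fit is R_g² = 1 − SSE/SST with SST the total sum of squares of the counts
about their mean; R_g² is stored unclipped (negative for terrible fits, NaN
for constant counts where SST = 0) because the quality filters below, not
clipping, are responsible for removing such fits.

**Quality control.** Within one environment, medians of r and K are taken
over all converged fits; a replicate is retained iff it converged and its r
lies within 50–200% of the median r and its K within 25–400% of the median
K. Because the medians are always computed over converged fits (not over
previously retained ones), the filter is idempotent. Genotype trait values
are means of retained replicates; standard errors are sample SD/sqrt(n),
undefined for single retained replicates. `min_reps` (default 1) optionally
drops genotypes with too few retained replicates.

## Environment-level r–K analysis

Environment quality Q is the unweighted mean r over all genotypes in the
environment; rho_rK is the Spearman rank correlation (midranks for ties,
two-sided p from the large-sample t approximation) between genotype-level r
and K. Constant inputs have no defined rank correlation and are signalled
explicitly rather than returned as NaN. Cross-environment trends are
Spearman correlations of (Q, rho_rK) and (mean K, rho_rK) over environments.

For the turning-point analysis, genotypes are sorted by r (ties broken by
genotype label for reproducibility) and cut into consecutive bins of exactly
`bin_size` (default 500); a trailing partial bin is discarded so bin means
stay comparable. Each environment contributes the mean r of its
highest-mean-K bin (ties broken toward the lower-r bin); r_tp is the
unweighted mean of those peaks across environments.

## QTL mapping

Genotypes are coded 0/1/2 (copies of one parental allele); runs of
consecutive SNPs in complete linkage disequilibrium are collapsed to their
middle member (lower middle for even runs) before mapping. Missing codes are
mean-imputed per SNP. The per-SNP test is the additive ordinary
least-squares t-test of the phenotype on the code; dominance is not
modelled.

Mapping proceeds in rounds (default 6). In each round the working phenotype
is the residual of the raw phenotype on all previously accepted QTL codes
(round 1 uses the raw phenotype). Each chromosome nominates its
largest-|t| SNP not yet accepted (ties toward the smaller position). The
null distribution is built by permuting the working phenotype across
genotypes (default 1,000 permutations; the acceptance studies use 200) and
recording every chromosome's best |t| per permutation. A candidate with
statistic s gets

    q(s) = E_perm[ #(chromosome-best permuted |t| >= s) ]
           / #(real candidates this round with |t| >= s)

and is accepted when q <= FDR (default 0.05). The chromosome-best null
matches how candidates are selected, which is what makes q an FDR estimate
for this selection rule. Mapping stops after the round limit or on a round
that accepts nothing; with 16 chromosomes and 6 rounds at most 96 QTLs can
be mapped per trait. Identical seeds give identical QTL lists, including
tie-breaks.

**Variance explained and pruning.** R² of a QTL set is from the joint OLS of
the phenotype on all member codes (least-norm solution when collinear).
Backward pruning repeatedly removes the QTL whose removal reduces the joint
R² least, recomputing each step, until k (default 36) remain; the
implementation works on the (k+1)×(k+1) normal equations so each step costs
solves of small systems rather than fresh n×k regressions. Random-SNP
baselines draw `n_samples` sets of k distinct SNPs and report the add-one
empirical p-value (1 + #{null R² >= observed}) / (n_samples + 1).

**Effects and pleiotropy.** Effects of the mapped QTLs on r and on K are the
coefficients of the two joint regressions of each trait on all k QTL codes
simultaneously. Same nonzero signs = concordant; opposite signs =
antagonistic; a zero or collinearity-flagged coefficient = null (flagged
columns are those reconstructable from the remaining columns to numerical
precision). Segment enrichment tiles chromosomes with fixed 3,000-bp
half-open windows anchored at position 1, counts pooled QTL instances per
window (one per trait × environment hit), marks windows with >= 4 instances
as enriched, and estimates the null enriched-window count by redrawing each
trait × environment's set as distinct SNPs uniform on the mapping map —
preserving SNP density, since a uniform base-pair null understates clustering
on a map whose SNPs are themselves clustered. Representative-SNP effects are
homozygote contrasts (mean at code 2 minus mean at code 0, heterozygotes
excluded) with the usual two-sample standard error.

## The cost model

Per-generation resource cost at population sizes far below K:

    C(r) = (a ln2 / r + b) / f(r),        f(r) = 1 - (r / r_max)^w

with maintenance cost a (energy per cell per hour; default 0.01), division
cost b (energy per new cell; default 1), r_max the maximum possible growth
rate (default 0.5 per hour) and efficiency exponent w > 0 (default 3); any
user-supplied decreasing f with f(0) <= 1, f >= 0 is also accepted, with
derivatives then taken numerically. The analytic derivative is

    dC/dr = [ -a ln2 f(r)/r^2 - f'(r) (a ln2/r + b) ] / f(r)^2 .

For any a > 0 the maintenance term dominates near r = 0 (dC/dr < 0,
trade-ups) and the efficiency collapse dominates near r_max (dC/dr > 0,
tradeoffs). The interior minimum r_star is located by a 1,000-point scan of
the derivative followed by Brent root refinement inside the bracketing
interval (tolerance 1e-6); no sign change is signalled as a boundary
minimum, and more than one is signalled as multimodality rather than
silently resolved. At the default parameters r_star = 0.1281, i.e. 0.13 to
two decimals. The carrying-capacity proxy for a fixed resource pool is
K = R_total / C(r); a discrete-generation depletion simulator (every cell
pays C per generation, population doubles while resource lasts, the last
partial generation pro-rated) provides an independent consistency check on
the ordering of K across r.

## The synthetic-data generator

The generator emulates a biparental yeast screen:

* **Cross.** Two haploid panels (85 MATa, 86 MATalpha by default) are
  simulated as two-parent mosaics per chromosome: Bernoulli(1/2) starting
  allele and Markov switching along the SNP map with Haldane recombination
  fractions, using the advanced-intercross map expansion factor
  generations/2 (= 6 for an F12 intercross) on a default 100 cM chromosome.
  Diploids are all MATa × MATalpha pairs (7,310 at full panel sizes); codes
  are 0/1/2 allele counts. Adjacent-SNP correlation decays with map
  distance, giving realistic local LD.
* **Phenotypes.** A shared set of causal SNPs (default 20) acts additively
  on latent r around each environment's mean (defaults: nine environments
  with mean r evenly spanning 0.04–0.35 per hour). Effects are scaled so the
  causal SNPs explain exactly h² (default 0.75) of the realized r variance —
  consistent with top-QTL panels explaining 65–81% of r variance in screens
  of this design — with Gaussian residual environmental noise making up the
  rest (coefficient of variation of r: 0.12). K follows the cost model,
  K = R_total / C(r) × lognormal noise (sigma = 0.05); per-environment
  resource pools R_total of 0.8–1.5 × 1e6 cost units put K near 1e6 cells
  and vary between environments independently of quality, as media
  composition does. A null mode draws r and K from independent normals
  instead, for estimation-validation studies.
* **Curves.** Logistic curves on the standard grid with additive Gaussian
  noise. The per-point noise variance is (1 − target R²_g) × SST / n where
  SST is the noise-free curve's total sum of squares and n the number of
  time points: with the total noise budget spread over the grid this way,
  the expected SSE of a refit equals (1 − target) × SST, so the median
  refitted R²_g lands on the target (default 0.99) by construction.
  Negative noisy counts are clipped at zero.
* **Initial population.** N0 defaults to 1e5 cells: colonies are initiated
  from pinned precultures, so the starting population is macroscopic and
  growth spans roughly one order of magnitude to a visible plateau within
  72 h. This matters: with a microscopic N0 (say 1e3) and K near 1e6,
  poor-quality environments never approach saturation within the window, K
  becomes weakly identified, and the fitting errors in r and K acquire a
  spurious correlation — a regime in which no estimator could reproduce the
  recovery accuracy that screens of this type report. At N0 = 1e5 the
  independent-r/K null simulation shows no significant refitted r–K
  correlation in any environment, and recovery accuracy (58–75% of genotypes
  within 1% of the true r per environment, essentially all within 20%)
  matches the reported behaviour of such screens.
* **No-saturation preset.** For robustness checks, carrying capacities are
  recomputed from each genotype's r so the per-capita growth rate at 72 h is
  a configurable fraction (default 23.3%) of the initial rate; refits on
  such curves remain nearly unbiased (median relative bias of r and K below
  2%).

What the generator does **not** emulate: plate-spatial and neighbour
effects, biological replicate-to-replicate variation (so simulated standard
errors are smaller than a real screen's), heteroscedastic or multiplicative
measurement noise, missing genotype calls, and genotyping error. Passing
tests therefore validate the estimation and mapping machinery under the
stated noise model, not robustness to those artefacts.

## Problem sizes and numerical choices

The validation studies in the test suite run at reduced but statistically
adequate sizes, chosen as the package's own defaults for routine
verification: estimation validation at 9 environments × 2,000 genotypes × 4
replicates; QTL machinery at ~2,000 genotypes × 2,000 SNPs on 16
chromosomes with 200 permutations; the end-to-end pipeline at 9 environments
× ~1,370 genotypes × 4 replicates with 960 mapping SNPs, 200 permutations
and top-36 pruning. Tolerances follow the quantity: exact-model identities
at 1e-5–1e-6 relative error, analytic-vs-numeric derivatives at 1e-6,
Monte-Carlo comparisons at multiples of their standard errors.

Deterministic tie-breaks are used everywhere randomness is not intended:
candidate SNP ties toward the smaller position, acceptance ordering by
statistic then chromosome then position, bin ties by genotype label,
peak-bin ties toward the lower bin. All stochastic stages take explicit
seeds; a pipeline run records its seed and package version in the summary,
and identical configuration plus seed reproduces the summary bit for bit.

## Known limitations and open choices

* The permutation-FDR construction (chromosome-best null, acceptance by
  q <= FDR per round) is one defensible formalization of "FDR by
  permutation test" for per-chromosome forward selection; other choices
  (e.g. pooled-SNP nulls) would give somewhat different QTL counts.
* The multiple-testing correction in the null-calibration check is
  Bonferroni over environments.
* The segment-enrichment null preserves SNP density but not local LD blocks;
  it will understate clustering induced by long-range LD.
* The cost model's K proxy uses the N << K cost C(r); the population-size
  dependence of C_N along a growth curve is acknowledged and not modelled
  (the depletion simulator operates at fixed r by design).
* Uniqueness of the interior cost minimum is verified numerically per
  parameter set, not proven for all w > 0.
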