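# Methods

`msatabc` infers the demographic history of a set of diverged populations
from multilocus microsatellite genotypes by Approximate Bayesian
Computation (ABC), and computes the descriptive microsatellite and mtDNA
diversity statistics commonly reported next to such an analysis.  This
note records the model, the numerical choices, and the reasoning behind
the design decisions that were genuinely open.

## Demographic model

Three sampled populations (labelled WIT, WIB, WDIN after the wolf
populations of the Italian peninsula, the Iberian peninsula and the
Dinaric region that motivate the default configuration) descend from a
common ancestral population of diploid effective size `NA`.  Four
competing scenarios combine two binary features:

| id | split      | bottleneck |
|----|------------|------------|
| 1  | simultaneous | no  |
| 2  | simultaneous | yes |
| 3  | sequential   | no  |
| 4  | sequential   | yes |

Under the simultaneous scenarios all three populations split from the
ancestor `t1` generations ago.  Under the sequential scenarios pop2 and
pop3 split from each other at `t1` and their ancestor splits from pop1 at
`t2 > t1`; pop1 as the outermost branch is one of three possible
labellings and is configurable (the labelling cannot be read off the data
without refitting, so the package fixes one and documents it).  The
intermediate ancestor of pops 2 and 3 is given size `NA`: the
parameterisation has no dedicated symbol for it, and using the ancestral
size for every unsampled ancestral population is the most parsimonious
completion.

A bottleneck is parameterised backwards in time: population *i* has its
current (post-decline) size `Ni` on `[0, db)` generations before present
and its larger pre-decline size `Nib` on `[db, t_split)`.  `db` is thereby
both the onset of the reduced phase and its duration to date, which makes
`db x generation_time` directly interpretable as "the bottleneck happened
this many years ago" — the reading used for the headline conversions.

Ordering constraints (`db < t1`, and `t1 < t2` for sequential scenarios)
are enforced at sampling time by jointly resampling the constrained time
parameters, which leaves each marginal uniform on the accepted region.

### Priors

All priors are uniform and overridable in configuration.  Defaults:

| parameter | default | meaning |
|---|---|---|
| `N1,N2,N3,NA` | U[100, 10000] | diploid effective sizes |
| `N1b,N2b,N3b` | U[100, 30000] | pre-bottleneck sizes |
| `t1,t2,db` | U[100, 10000] | times, generations |
| `mu_mic` | U[1e-4, 1e-3] | mean mutation rate /locus/generation |
| `p_mic` | U[0.1, 0.3] | geometric step parameter |
| `sni_mic` | U[1e-8, 1e-5] | single-nucleotide indel rate |

The ranges were chosen once to contain the 90% posterior intervals
reported for the wolf analysis with room on both sides, and to match the
customary microsatellite mutation-rate priors of DIYABC-style analyses.

## Coalescent simulation

Genealogies are simulated per locus under the continuous-time structured
coalescent with piecewise-constant sizes: within a population of diploid
size `N`, `k` lineages coalesce at total rate `k(k-1)/(4N)` per
generation; waiting times are exponential and re-drawn at every
demographic event, which is exact by memorylessness.  The continuous-time
approximation (rather than generation-by-generation Wright–Fisher) is
justified because sample sizes (<= 99 diploids) are far below the
prior range of `N`.  A cross-check against msprime on identical
demographies (two-sample Kolmogorov–Smirnov on TMRCA distributions) is
part of the test suite.

Mutations follow the generalised stepwise model (GSM): Poisson(`mu * b`)
mutations per branch of length `b`, each stepping the repeat count by
`±k` with fair sign and `P(k) = (1-p) p^(k-1)`; `p = 0` recovers the
strict stepwise model with mean step 1, and the mean step is `1/(1-p)`.
Single-nucleotide indels in the flanking sequence are an independent
Poisson(`sni * b`) overlay of ±1-nucleotide offsets, taking alleles off
the repeat ladder.  The root state is fixed at 20 repeats, offset 0; all
statistics computed downstream are translation invariant, so the choice
is inert.  The allele ladder is unbounded by default; a reflecting-bounds
option (`ladder_bounds=(lo, hi)`) emulates engines that constrain the
allele range.  Per-locus Gamma-distributed mutation rates are available
(`gamma_rate_shape`) but off by default: the emulated analysis reports
only mean rates.

The simulation kernels are compiled with numba and are bitwise
reproducible from an integer seed.

## Summary statistics

Alleles are identified by their **length in nucleotides**
(`motif_length * repeat + offset`), the quantity actually scored in
fragment analysis.  Two alleles that differ in repeat count and indel
offset but coincide in length are therefore the same allele; this also
makes the Genepop 3-digit encoding lossless for every statistic.

The ABC feature vector (21 entries for three populations, fixed order):

* per population — mean number of alleles per locus; mean genetic
  diversity (unbiased expected heterozygosity,
  `2n/(2n-1) * (1 - sum p^2)`); mean allele-size variance (sample
  variance, `ddof=1`, of allele lengths across gene copies — the unbiased
  estimator whose expectation under the strict stepwise model at
  equilibrium is `2 N mu` in repeat units);
* per population pair — mean number of alleles and mean genetic diversity
  of the pooled sample; Weir–Cockerham theta accumulated over all alleles
  and loci as a ratio of sums of the a/(a+b+c) variance components; the
  shared-allele distance `DAS = 1 - mean(shared/2)` over all
  inter-population individual pairs and loci, where a pair of diploid
  genotypes shares 0, 1 or 2 alleles counting multiplicity.

The descriptive report per population gives `Ao` (observed alleles per
locus), `Ae` (effective alleles, `1/sum p^2`), `Ho`, unbiased `He`, and
`F = 1 - Ho/He` computed from the locus-averaged heterozygosities (a
per-locus Weir–Cockerham f is deliberately not the default; the
locus-averaged form is what the emulated report prints).  Monomorphic
populations flag `F` as missing.  Hardy–Weinberg testing is provided as a
per-locus Monte-Carlo permutation test (heterozygote deficit) with a
Bonferroni threshold.

Note that the Weir–Cockerham estimator is unbiased but not exactly zero
on duplicated samples: with identical allele frequencies the
among-population component is at its negative extreme, giving theta of
order `-1/n`.  The tests assert near-zero rather than zero.

### mtDNA statistics

Per-region alignments are concatenated sample-wise (default region
lengths 498/588/231/847 bp, 2164 bp total).  Haplotype collapsing is
indel-aware: sequences are identical only if equal at every column
including gaps.  Haplotype diversity uses the unbiased estimator
`H = n/(n-1) (1 - sum p_i^2)`.  Nucleotide diversity is
`pi = n/(n-1) sum_{i<j} 2 p_i p_j d_ij / L` with `d_ij` counting
differences only at columns where both sequences carry a base (gap sites
excluded from the count, the DnaSP convention) and `L` the full alignment
length by default (overridable to exclude gap columns).

## ABC machinery

* **Reference table** — rows of (scenario, parameter draw, statistic
  vector) simulated from the priors; reproducible from a seed.
* **Rejection** — statistics standardised by the table median and MAD
  (robust to the long-tailed prior predictive; zero-MAD statistics are
  dropped with a warning); Euclidean distance; the closest
  `ceil(fraction * n)` rows retained (`fraction = 0.01` by default).
* **Scenario choice** — the direct estimate is the retained-set
  proportion.  The logistic estimate fits an Epanechnikov-weighted
  multinomial logistic regression of the scenario indicator on the
  standardised statistic offsets and evaluates it at offset zero.  By
  default the offsets are first projected onto their linear-discriminant
  axes (n_scenarios - 1 dimensions) before the regression — the
  stabilisation modern ABC engines apply before their logistic step,
  which matters at the package's scaled-down table sizes where a
  21-covariate regression on a few hundred retained rows is
  separation-prone and noisy.  `lda=False` regresses on the raw offsets.
  The ridge stabiliser is weak (`C = 1e4`); confidence intervals come
  from a nonparametric bootstrap of the retained set.
* **Parameter posteriors** — Beaumont-style local-linear adjustment with
  the parameter logit-transformed to its prior interval, so adjusted
  draws can never leave the prior support (asserted on every run).
  Weighted least squares uses the Epanechnikov weights; rank-deficient
  designs fall back to the minimum-norm solution with a flag.  Posterior
  summaries (median, q050, q950) are weighted quantiles by the same
  kernel weights.  Parameter estimation is run on the retained subset of
  the chosen scenario's simulations only.
* **Units** — time parameters convert to years at 3 years per generation
  (configurable); bottleneck severity is reported as `R = Nb/N` from the
  posterior medians, to one decimal.
* **Model checking** — `n_ppc` datasets are simulated at parameter
  vectors resampled (weight-proportionally) from the adjusted posterior;
  per statistic the two-sided tail probability
  `min(1, 2*min(P(sim<=obs), P(sim>=obs)))` uses add-one smoothing, with
  the Bonferroni threshold `alpha / n_statistics`.  Because the marginal
  adjustment can break the joint ordering constraints, posterior
  predictive draws are restricted to constraint-satisfying rows (or the
  offending times are minimally repaired when no row qualifies, with a
  warning).  `n_ppc >= ~1000` is needed for the Bonferroni threshold at
  21 statistics to be attainable at all.
* **PCA pre-evaluation** — the observed vector is projected into a PCA of
  a z-standardised reference-table subsample to visualise whether it lies
  inside the simulated cloud.

## Synthetic data

The generator reproduces the emulated study design: 3 populations sampled
at 39/20/40 diploids, 39 loci (32 dinucleotide + 7 tetranucleotide motifs
— the motif labels are metadata; the default mutation model does not
depend on them), and a four-fragment mtDNA alignment (498/588/231/847 bp)
with a configurable haplotype-count vector and number of segregating
sites; the canonical pseudo-observed dataset is simulated under scenario
2 at the reported posterior-median parameters.  Fixture sequences use a
uniform random base composition, which no implemented statistic depends
on.

What the generator does **not** emulate: missing genotypes, genotyping
error and allele dropout, linkage between loci, dog admixture or hybrid
individuals, selection, and population structure within the three
samples.  Passing recovery tests therefore demonstrate that the inference
machinery is self-consistent under the stated model, not that the model
is adequate for any particular real dataset.

## Problem sizes used by the test suite

The published analyses of this kind run millions of simulations per
scenario; the package's experiments are scaled down to remain a
few-minute computation: reference tables of 10,000 simulations per
scenario (4 scenarios, 39 loci, samples 39/20/40), 50 pseudo-observed
replicates sharing one reference table (replicates are therefore
correlated through the table; fully independent tables would cost 50x
the simulation effort), 20 calibration replicates with 1,000
posterior-predictive simulations each.  The full-scale setting remains
available through configuration (`n_per_scenario`).

## Known limitations

* Scenarios 2 and 4 are nested at `t2 -> t1`: a sequential history with
  near-simultaneous splits is observationally equivalent to the
  simultaneous one, which bounds achievable scenario-recovery rates from
  above and concentrates misclassifications between those two.
* A pseudo-observed dataset generated at posterior-median parameters sits
  in the low-diversity tail of the prior predictive (the mutation-rate
  prior is wide), so the observed vector lies near the edge of the
  retained cloud and the regression step extrapolates; this inflates the
  variance of the logistic scenario probabilities at small table sizes.
* The local-linear adjustment is applied marginally per parameter; joint
  constraints among time parameters can be violated by adjusted draws and
  are handled by restriction/repair only at the posterior-predictive
  stage.
* Uniform (not log-uniform) priors on mutation rates concentrate prior
  predictive mass at high diversity; this follows the emulated engine's
  convention but is a modelling choice worth revisiting for real data.
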