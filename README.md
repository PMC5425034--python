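# msatabc

Coalescent simulation and Approximate Bayesian Computation (ABC) for
microsatellite-based demographic inference, built around the question of
when a set of isolated populations — the motivating case is the grey wolf
(*Canis lupus*) populations of the Italian peninsula, the Iberian
peninsula and the Dinaric region — diverged from their common ancestor,
and whether they went through bottlenecks.  It is aimed at population
geneticists who want a self-contained, testable re-implementation of the
DIYABC-style workflow: scenario simulation, summary statistics, rejection
+ regression ABC, and model checking, plus the descriptive microsatellite
and mtDNA diversity statistics reported alongside such analyses.

## The model in brief

Three diploid populations of effective sizes N1, N2, N3 descend from an
ancestor of size NA.  Four scenarios combine *simultaneous* vs
*sequential* splits (at times t1, and t2 for the sequential case, in
generations) with *bottleneck* vs *no bottleneck* (sizes Nib > Ni before
db generations ago).  Microsatellites mutate under the generalised
stepwise model — Poisson(μb) mutations per branch, ±k repeat steps with
P(k) = (1−p)p^(k−1) — with a single-nucleotide-indel overlay at rate
`sni` that takes alleles off the repeat ladder.  Inference follows
Beaumont-style ABC: a reference table of (scenario, θ, S(θ)) rows is
simulated from uniform priors; the 1% of rows whose 21 summary
statistics (per population: mean allele number, mean unbiased expected
heterozygosity, mean allele-size variance; per pair: pooled allele
number and diversity, Weir–Cockerham Fst, shared-allele distance DAS)
are closest to the observed vector are retained; scenario probabilities
come from retained proportions and from a weighted multinomial logistic
regression evaluated at the observed point; parameter posteriors come
from logit-transformed local-linear regression adjustment.  Time
parameters convert to years at 3 years/generation; bottleneck severity
is reported as R = Nb/N.

Formulas, conventions and design decisions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import msatabc as m

# a pseudo-observed dataset: 39 loci, samples 39/20/40, simulated under
# the simultaneous-split + bottleneck scenario at realistic parameters
spec = m.FixtureSpec(seed=1)
observed, truth = m.make_pseudo_observed(spec)

model = m.DemographicABC(observed, fraction=0.01)
res = model.fit(n_per_scenario=10_000, seed=7)   # ~6 min on one core
print(res.summary())
```

```text
Approximate Bayesian Computation results
========================================
reference table : 40000 rows (10000 per scenario), 39 loci, samples [39, 20, 40]
retained        : 400 rows (fraction 0.01)

Scenario posterior probabilities
--------------------------------
 scenario  p_direct  p_logistic
        1    0.2825      0.1677
        2    0.2425      0.2647
        3    0.2075      0.3878
        4    0.2675      0.1798

Parameter posteriors under scenario 3 (generations / diploid sizes)
------------------------------------------------------------
           median      q050      q950
N1           3343      1601      5122
N2           3627      1630      5570
N3           5661      2453      8668
NA           6879      3025      9527
t1           4680      2100      6998
t2           7820      4052      9351
mu_mic  0.0001444 0.0001118 0.0002798
p_mic       0.122    0.1026    0.1789
sni_mic 1.589e-06 5.352e-07 7.067e-06

Time parameters in years (generation time 3 y)
------------------------------------------------------------
      median      q050      q950
t1 1.404e+04      6300 2.099e+04
t2 2.346e+04 1.216e+04 2.805e+04
```

The scenario table gives the posterior probability of each demographic
history by both estimators; the parameter block gives posterior medians
and 90% intervals (q050–q950) in generations and diploid sizes, repeated
in years for the time parameters.  When the chosen scenario has a
bottleneck the summary also prints R, the median pre- to post-bottleneck
size ratio per population.  Note the nearly flat scenario probabilities:
at 10⁴ simulations per scenario the four histories are only weakly
distinguishable for this dataset (the generating scenario here was the
simultaneous-split bottleneck, scenario 2, yet the near-equivalent
sequential variant edges it out), which is exactly what the probabilities
report — production analyses of this kind use hundreds of times more
simulations.  `res.model_check(n_ppc=500)` simulates from the fitted
posterior and reports, per summary statistic, the two-sided tail
probability of the observed value with a Bonferroni threshold — this fit
passes with 0 of 21 statistics significant.

The same pipeline is scriptable:

```bash
msatabc make-fixtures --seed 1 --out fixtures/
msatabc run --seed 7 --genepop fixtures/pseudo_observed.gen --out run/
msatabc report run/
```

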