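# Methods

This note documents the statistical models, the simulators behind the test
suite, the numerical choices, and the known limitations of `corrlink`.

## Estimation model

All pairwise estimators condense the data for a marker pair into the 3×3
table `m[i, j]` of joint allele-count codes (`X_A = i`, `X_B = j`,
codes 0/1/2, heterozygote always 1). The population model is a biparental
cross with fully inbred founders, a coupling-phase F1 (`AB/ab`), and
subsequent generations produced by self-fertilization; heterozygosity at
generation t is `H_t = (1/2)^(t−1)`. Assumptions: no segregation
distortion, no crossover interference, biallelic codominant markers.

**Correlation estimator (`pcorr`).** Under this model the allele-count
correlation is `r = 1 − 2θ` at every generation t ≥ 2 (the variance
`1 − H_t` cancels between covariance and marginal variances), so
`θ̂ = (1 − r̂)/2` with `se = (1 − r̂²)/(2√(n − 3))` from Fisher's
large-sample variance of a correlation. A negative `r̂` would map above
0.5; it is clamped by setting `r̂ := 0` *before* the SE formula, so a
clamped estimate reports `θ̂ = 0.5`, `se = 1/(2√(n − 3))` and a `clamped`
flag. Preconditions: n ≥ 4 and non-degenerate margins at both loci.

**Codominant EM (`em_codominant`).** Writing `m2` for the recombinant-gamete
count of the unambiguous cells (2 per corner repulsion cell, 1 per edge
cell) and `m0` for the non-recombinant analogue, only the double
heterozygote `m22` is ambiguous: it is `AB/ab` (0 recombinant gametes) or
`Ab/aB` (2), with posterior double-recombinant probability
`ρ = θ²/(θ² + (1−θ)²)`. The EM update is gamete counting with the imputed
count: `θ ← (m2 + 2ρm22)/(2n)`. The Louis observed information at the
converged estimate is

    I(θ̂) = (m2 + 2ρm22)/θ̂² + (m0 + 2(1−ρ)m22)/(1−θ̂)²
           − [2/(θ̂(1−θ̂))]² · m22·ρ(1−ρ),

i.e. the posterior-expected complete-data information minus the posterior
variance of the complete-data score (which here is linear in the imputed
count, so the variance term is exact). `se = I(θ̂)^{−1/2}`. The unit tests
gate this algebra against the numerical Hessian of the observed-data
log-likelihood; agreement is at relative 1e−3 or better at interior optima.

**Dominant EM (`em_dominant`).** For dominant markers only four phenotype
classes are visible, with probabilities `(½ + π/4, (1−π)/4, (1−π)/4, π/4)`
in `π = (1 − θ)²`. The dominant class splits into a constant-probability
component and a `π/4` component; imputing the latter's count with
`ρ = π/(2 + π)` gives the update

    π ← [π·n_AB + (2+π)·n_ab] / [π·n_AB + (2+π)(n_ab + n_Ab + n_aB)],

then `θ̂ = 1 − √π̂` and, via Louis information on π and the delta method,
`var(θ̂) = var(π̂)/(4π̂)` with

    I(π̂) = (ρ·n_AB + n_ab)/π̂² + (n_Ab + n_aB)/(1−π̂)² − n_AB·ρ(1−ρ)/π̂².

The phenotype collapse of a codominant table assumes coupling-phase coding
(code 2 = homozygote for the dominant allele at both loci).

**EM controls.** Defaults: start θ = 0.25 (phase-agnostic midpoint),
tolerance 1e−10 on the iterated parameter, 1000 iterations maximum.
Both updates are contractions on these problems and typically converge in
well under 50 iterations; non-convergence is flagged, never silent.
Boundary estimates (θ̂ = 0, or π̂ ∈ {0, 1}) report `se = None` rather than
0, because the observed information degenerates there.

**Diagnostics.** `segregation_chisq` tests one locus' genotype counts
against the generation-t expectation `((1−H_t)/2, H_t, (1−H_t)/2)` with
df = 2 and no continuity correction. `pooled_correlation` implements the
within-family (pooled) correlation — within-group deviations summed over
groups — for collections of families where linkage disequilibrium persists
only within families.

## Linkage maps

Adjacent within-chromosome pairs (marker order fixed by the physical map)
are estimated and converted with the Haldane function
`d = −50·ln(1 − 2θ)` cM, assuming no interference. Because the clamp can
produce exactly θ = 0.5 where the function diverges, estimates at or above
0.4999 are mapped to the (finite) distance at 0.4999 and flagged `capped`.
Pairs whose estimator preconditions fail contribute 0 cM and a `failed`
flag instead of aborting the chromosome. The linkage-map TSV round-trips
exactly (floats are written in shortest-repr form and parsed in round-trip
mode), including the `capped`/`failed` flags.

## The F_t simulator

**Table mode** (`simulate_ft_pair` without distortion) draws i.i.d.
two-locus genotypes from a generalized F_t joint table in which θ is the
*generation-t effective* recombination fraction. A subtlety forced this
design: extending the classical F2 table to F_t by replacing the marginal
weights with `H_t`-based ones does not produce a probability distribution
for t > 2 (the cells no longer sum to one), and the exact selfing
recursion with a fixed per-meiosis θ has correlation `(1−2θ)/(1+2θ)` in
the inbred limit, not `1 − 2θ`. The generalized table used here is the
unique 3×3 law with (i) margins `((1−H_t)/2, H_t, (1−H_t)/2)` at both
loci, (ii) allele-count correlation exactly `1 − 2θ`, and (iii) a
double-heterozygote cell whose recombinant bookkeeping matches the EM
complete-data score — in closed form, with `ρ = θ²/(θ²+(1−θ)²)`:

    side   = H·(θ − ρ)/(1 − 2ρ),      centre = H·(1 − 2θ)/(1 − 2ρ),
    coupling corner  = [(1−H)(1−θ) − side]/2,
    repulsion corner = (1−H)/2 − coupling − side.

It reduces exactly to the classical F2 table at t = 2, is non-negative over
the whole (t, θ) range used in testing, and keeps both the correlation
estimator and the codominant EM centred on θ at every generation — which is
what makes it the right null model for estimator calibration.

**Mechanistic mode** tracks meioses. For a single pair,
`ft_recursion_table` iterates the exact 16-state ordered-haplotype-pair
selfing recursion (offspring = two independent gametes of the same parent);
`effective_theta` / `meiotic_theta` convert between the per-meiosis and the
generation-t effective scales by evaluating/inverting that recursion. For
whole chromosomes, `simulate_ft_genome` advances single-seed-descent lines
(one selfed offspring per line per generation) through the meiosis engine
below. Only this mode reproduces map expansion across generations, because
recombination accumulates over successive meioses.

**Segregation distortion** multiplies gamete-class probabilities before
renormalization — `allelic` favours A-carrying gametes (AB, Ab),
`nonrecombinant` favours parental gametes (AB, ab) — applied independently
to both gametes of every meiosis, at every generation, with default weight
2 (exposed as a parameter). Under nonrecombinant distortion the transmitted
recombinant frequency is strictly below θ, and all three estimators shift
downward; under allelic distortion the marginal ratios break and the
correlation estimator is biased noticeably more than the codominant EM.
These directions are asserted by the acceptance tests.

**What the simulator does not emulate:** genotyping error, missing-data
patterns (beyond explicit missing codes in IO), crossover interference,
selection during line advancement, and residual founder heterozygosity.
Passing tests therefore validate estimator correctness under the idealized
model, not robustness to those artefacts — except for distortion, which is
modelled explicitly.

## Meiosis engine and genomic mating

A gamete is simulated per chromosome as: Bernoulli(½) start strand,
crossover count ~ Poisson(length in Morgans), crossover positions i.i.d.
Uniform(0, L), strand switching at every crossover (zero-crossover meioses
are kept — no obligate chiasma; the count is per chromosome, not per arm).
This is the no-interference model whose marker-pair recombinant fraction is
exactly the Haldane transform of the cM distance; the implementation is a
single vectorized routine, and the single-gamete call is its n = 1 case.

The base population for the mating illustration is an F2 of (by default)
500 individuals, 20 chromosomes × 101 markers at 1 cM spacing (2020
markers), additive effects ~ N(0, 0.5) and dominance effects ~ N(0, 1.0) —
the spreads are read as *variances*, and both are configurable in case the
SD reading is wanted. The residual variance is configurable with default
900, chosen to put broad-sense heritability near 0.74 at this effect scale.
The phenotype model is `y = μ + Zγ + Wδ + ε` with intercept-only fixed
effects (μ default 0); no further systematic environment is modelled.

REML maximizes the restricted log-likelihood of
`V = K_γσ²_A + K_δσ²_D + Iσ²_E` (kinships `ZZᵀ/C_γ`, `WWᵀ/C_δ`,
`C = trace/n`) by bounded L-BFGS-B on log-variances — the log scale
enforces non-negativity, with components at the lower bound reported as
zero. Each objective evaluation uses one Cholesky factorization of V;
at n = 500 that is cheap enough that no eigen-decomposition reuse is
needed. Recovery tests (20 replicated populations at full scale) show mean
estimates within 10% of the generating values; the dominance component is
the hardest because `WWᵀ` is strongly rank-deficient in an F2.

BLUP predictions follow the conditional expectations
`ξ̂_γ = σ̂²_A K_γ V̂⁻¹(y − Xβ̂)` (dominance analogue alike) with GLS fixed
effects. Marker effects are back-solved as `γ̂ = Zᵀ(ZZᵀ)⁻ξ̂_γ` using a
minimum-norm least-squares solve (relative cutoff 1e−10), which preserves
`Zγ̂ = ξ̂_γ` to numerical precision even when the cross-product is
singular.

Cross values are predicted two ways: (1) per-marker Mendelian expectations
`E[Z] = (g_s + g_d)/2`, `E[W] = p_s + p_d − 2p_s p_d` with `p = g/2`, and
(2) repeated simulated meiosis from the phased parents, which additionally
yields the SD of a single progeny's value (the Mendelian sampling spread —
deliberately *not* the standard error of the mean; divide by √N for that).
The exhaustive scheme search scores all `d!/(v!)^s` labeled assignments of
dams to sires by the mean of the assigned cross values, breaks ties toward
the lowest enumeration index, and reports the percent gain of the best
scheme over the all-scheme average (the random-mating baseline); the gain
is only meaningful when that average is positive, which holds at the
default selection intensities.

## Problem sizes used in testing

The replicated estimator study uses 100 replicates of n = 200 per θ on a
0.05-spaced grid; F_t calibration checks use n = 2000 with 12 replicates
per (t, θ); the meiosis check uses 1e5 gametes; REML recovery uses 20
full-scale (n = 500, m = 2020) replicates; map expansion uses 50 replicates
of 191 single-seed-descent lines on an 11-marker 100 cM chromosome; the
cross-table agreement check uses N = 1000 meioses per cross over the 3×9
cross table. These sizes give Monte-Carlo standard errors comfortably
below the tolerances asserted.

## Known limitations

* The correlation/EM estimators are for biparental inbred-founder designs;
  in random-mating populations the correlation reflects historical linkage
  disequilibrium, not θ, and the right tools are IBD-based (out of scope).
* Marker ordering is taken from the physical map and never re-estimated;
  no Kosambi or interference-aware mapping functions are provided.
* The dominant-model collapse assumes coupling phase; repulsion-phase F1
  parameterizations are not implemented.
* The exhaustive scheme search is capped (default 2×10⁶ schemes); larger
  (d, s) need heuristic search, which is out of scope.
* The rice example ships only the two worked marker-pair tables, not the
  full genotype matrices; whole-genome analyses in the tests run on
  simulated data.
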