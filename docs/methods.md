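# Methods

`enksim` simulates recurrent selection in hybrid breeding programs whose trait
genetics follow an ensemble of NK fitness landscapes, one per discrete
environment type (ET), under a target population of environments (TPE) whose
ET frequencies drift year over year and shift over breeding cycles. This note
documents the model, its parameters and defaults, the numerical choices, and
what the synthetic data do and do not represent.

## Genetic architecture: NK submodels and the E(NK) ensemble

A trait is the mean of `N = 500` *fitness components*. Each component is a
random function of the diploid dosages (0/1/2) at a set of member genes drawn
uniformly from the `N = 500` biallelic genes; its values are i.i.d.
Uniform(0, 1) across distinct member-genotype configurations and components.
The complexity parameter `K` (1–15) is the mean component size: at `K = 1`
every gene belongs to exactly one single-gene component (a random bijection)
and heterozygote values are set midway between the homozygotes, so gene
action is strictly additive; for `K > 1` component sizes are Poisson(`K`)
samples conditioned on [1, 15] (the conditional, renormalized distribution)
and genes typically act in several components, i.e. pleiotropically and
epistatically. Single-gene components arising under `K > 1` do *not* get the
midpoint rule: intragene interaction (dominance) is part of the intended
complexity at `K > 1`.

Because the best homozygote at a locus is the larger of two Uniform(0, 1)
values, the expected maximum attainable fitness at `K = 1` is
`E[max(U1, U2)] = 2/3` — a useful closed-form check of the whole pipeline.

Environmental interactivity comes from an ensemble of `E = 12` NK submodels,
one per ET on an ordinal scale. ET1 is assembled from scratch; each following
ET retains a uniformly chosen 75% of the previous ET's components unchanged
(same identity, same values) and assembles the remaining 25% anew. Expected
component sharing between ETs at lag `L` is `0.75^L`, and since fitness is a
mean of component values, the genetic correlation between ET-specific fitness
decays the same way (≈0.75 at lag 1, <0.25 by lag 5). Replaced components are
chosen uniformly and independently at each step; at `K = 1` the replacement
components' genes are a random permutation of the vacated genes, so the
one-gene-one-component bijection holds within every ET.

### The component random function

The original formulation uses a sequential pseudorandom generator for the
component values. Here the random function is a counter-based keyed integer
hash: the member dosages are packed base-3 into a 64-bit code, mixed with the
component's random 64-bit uid and passed through two rounds of a
splitmix64-style finalizer, then mapped to [0, 1). Consequences:

- evaluation is stateless and O(1) per (component, genotype) with no memory
  of evaluation order — caching can never change a value;
- the whole architecture is reproducible bit-for-bit from the master seed
  (uids are drawn from a seeded stream; values follow from uids);
- marginal uniformity and cross-component independence are properties of the
  mixer, verified in the test suite by Kolmogorov–Smirnov and correlation
  checks at n = 1e5.

A compiled (numba) kernel and a vectorized numpy path implement the same hash
bit-identically; the compiled path is used when numba is importable.

## TPE schedules

A TPE is a strictly positive frequency vector over the 12 ETs. Per cycle the
true TPE is one Dirichlet draw with concentration `kappa * w(cycle)`:

- **gradual**: `w` is a Gaussian kernel over ET index centered at
  `mu(cycle) = 1 + 11 (cycle-1)/(n_cycles-1)` (ET1 in cycle 1 to ET12 in
  cycle 30), `kernel_width = 2.0` ET units, `kappa = 300`;
- **sudden**: `w` is near-uniform over ETs 1–6 through cycle 20 and over ETs
  7–12 afterwards, with a floor of 0.004 on out-of-block ETs, `kappa = 29`.

`kernel_width` and `kappa` are not identifiable from the qualitative
description of the scenarios alone; they were calibrated once, by simulation
over 200 schedule replicates, so that the cycle-averaged effective number of
ETs (inverse Simpson index `1/Σb²`) is ≈5.9 under gradual and ≈5.4 under
sudden change — the level at which fewer than half of the 12 ETs have an
effective presence at any time. Both are exposed as configuration knobs.

Programs observe the TPE through their multi-environment trials: per program
and cycle, MET weights are one Dirichlet draw with concentration `500 b`
around the true TPE `b`, so programs' trial networks differ slightly from
each other and from the truth.

## Genome, meiosis, and line derivation

Ten chromosomes of 1 Morgan carry 50 evenly spaced loci each (locus `j` at
`(j - 0.5)/50` Morgan, leaving half-interval margins at the ends). Meiosis
follows the Haldane model: per chromosome a Poisson(1) number of crossovers
(zero allowed — no obligate chiasma), uniform positions, equiprobable
starting phase, no interference, independent assortment. The implementation
bins crossovers to inter-locus intervals and takes a parity cumsum, which is
O(B·N) for a batch of B meioses and is validated against the map function
r = (1 − e^(−2d))/2.

Recombinant inbred lines are derived from each breeding cross by three
generations of single seed descent (one selfed offspring kept per
generation, no selection within SSD) followed by one doubled-haploid step, so
every line in every cycle is fully homozygous.

## Founder population

The base population is 1,000 inbred lines with two prescribed properties:
minor allele frequencies uniform on [0.35, 0.50], and expected pairwise LD
between loci `t` Morgan apart of `r² = 0.5 · 2^(−t/0.1)` within chromosomes
(background `≈ 1/n_lines` across chromosomes). The generator draws, per
chromosome, correlated standard normal deviates from a stationary Gaussian
process and thresholds them at per-locus allele-frequency quantiles (the '1'
allele is the minor allele with probability 1/2). The latent autocorrelation
`rho(t)` is calibrated numerically — via the bivariate normal orthant
probability, evaluated with Owen's T function — so that the expected squared
indicator correlation, averaged over the MAF distribution and random allele
labeling, matches the target r² curve at every inter-locus distance. The
assembled correlation matrix is eigenvalue-clipped to PSD if needed. The
calibration is deterministic, cached per process, and costs about a second.

The LD fit used for QC regresses log2 of binned mean r² on distance,
excluding bins beyond 0.5 Morgan where the true r² falls below the
finite-sample noise floor (~1/n_lines) and would bias the fit.

## The breeding cycle

Five program structures share identical per-heterotic-group totals (500
lines, 125 selected parents, 125 experimental hybrids): *distributed* (5
programs of 100+100, exchange every cycle), *centralized* (one program of
500+500), *iso* (5 programs, never exchanging), *iso7* (exchange in cycles 7,
14, 21, 28) and *iso21* (exchange only in cycle 21).

Per cycle and program:

1. **Testcross GCA.** Every line is crossed to `n_testers = 5` lines drawn
   uniformly without replacement from the opposite-group subpopulation of the
   same program (independently per line and cycle). Testcross hybrid values
   are the MET-weighted ensemble performance of the F1 dosage; a line's true
   GCA measure is its tester mean. Gaussian entry-mean noise with variance
   `Var(true) (1−h²)/h²`, recomputed per subpopulation and cycle (zero noise
   if the true means are constant), yields observed GCA at heritability
   `h² = 0.75`.
2. **Hybrid prediction and selection.** All intergroup pairs are scored by
   the sum of their parents' observed GCAs; the top `n_experimental_hybrids`
   (ties broken lexicographically by parent index) form the experimental
   hybrids, whose *true* performance is computed under the true TPE weights.
   Their mean ranks the programs; the best single hybrid across programs is
   the operation-level performance metric of the cycle.
3. **Exchange proportions.** In exchange cycles, the rank-`r` program (0 =
   best) conducts `x_r = Pmax · r/(R−1)` of its breeding crosses with
   external parents (`Pmax = 0.25`), sourced from strictly higher-ranked
   programs in proportion to the performance gaps (equal split if all gaps
   are zero). The top program never imports.
4. **Contributions and crosses.** Within each subpopulation the top 25 lines
   by observed GCA receive one Dirichlet contribution draw whose
   concentration weights halve with every one-fifth rank quantile
   (`w_r = 2^{−(r−1)/(n_sel/5)}`); lower-ranked lines are excluded. Each of
   the 100 breeding crosses is independently designated external with
   probability `x_r`; external crosses pair an internal parent with a donor
   line (donor program by share, line by that program's contributions),
   internal crosses draw two internal parents (the second resampled until it
   differs — no selfing; repeated pairs allowed). Breeding crosses stay
   strictly within a heterotic group; hybrids strictly across groups within
   a program.
5. **Advance.** Each cross yields one SSD+DH line; the new lines completely
   replace the generation.

The total Dirichlet concentration of the contribution draw (default 600) is
not pinned down by the halving-per-quintile shape alone; it was calibrated
once so that the realized cycle-averaged effective parent number (inverse
Simpson index of parent-slot proportions across a heterotic group) in the
isolated structure is ≈65, the targeted level for that structure. It is a
configuration knob.

## Recorded metrics

- **%GCA** — share of general-combining-ability variance in total genetic
  variance of the testcross factorial, from a two-way random-effects
  decomposition (GCA of each parent group + pair residual = SCA) fitted to
  the *true* (noise-free) testcross values by Henderson's method 3 (quadratic
  forms via rank-revealing QR; negative components truncated at zero). The
  estimator returns exactly 1 on exactly additive tables regardless of design
  imbalance. Estimated per program, then averaged. For programs with more
  than 100 lines per group the factorial is subsampled to 100 random lines
  per side — the estimator is unbiased under subsampling and this keeps the
  per-cycle cost flat. The quantity targeted is an estimator-agnostic
  variance ratio; a moments/projection estimator keeps the inner loop cheap
  where a Bayesian MCMC mixed model would dominate the runtime.
- **GCA correlation** — every third cycle, for one program pair: the lines of
  program 0 (group 1) are testcrossed against 5 random testers from program
  1's group-2 subpopulation under program 0's MET weights, noiselessly; the
  Pearson correlation with their regular noisy GCA measures transferability
  of genetic effects. With additive genetics its expectation is ≈ √h² ≈ 0.87
  (the noisy side attenuates; the foreign side adds tester-sampling noise, so
  realized values sit slightly below). Not applicable to the centralized
  structure.
- **Fst** — heterozygosity-ratio estimator `1 − mean(H_S)/mean(H_T)` over
  loci polymorphic in the pooled sample, among the subpopulations of a
  heterotic group, averaged over the two groups. A dosage-based
  Weir–Goudet-style estimator can differ by a small bias; the
  heterozygosity-ratio form was chosen for closed-form testability.
- **UW** — fraction of the 500 loci with minor allele frequency below 5%
  (fixed loci count), per subpopulation, then averaged.
- **Ne** — constant-size temporal estimator: for the pooled allele
  frequencies of a heterotic group, the standardized per-generation change
  `F = (p′−p)²/(p(1−p))` averaged over segregating loci and transitions
  gives `Ne = 1/(2 mean F)`, capped (default 1e6) when no drift signal
  remains; per cycle the engine fits the whole pooled trajectory up to that
  cycle, averaged over groups. The estimator is validated against a
  Wright–Fisher oracle with known Ne. It is qualitative under selection
  (drift and selection response both move frequencies), and it has a known
  boundary behavior: once isolated subpopulations have fixed for alternative
  alleles the pooled frequencies freeze, the drift signal stops, and the
  estimate inflates instead of settling at the number of subpopulations — a
  limitation of any purely temporal method on frozen trajectories. The
  estimator sits behind a single function and can be swapped.
- **Top-rank stability** — across replicates, the probability that the
  top-ranked program repeats from the previous cycle; ≈0.2 under i.i.d.
  random ranking of 5 programs. Optional lowess smoothing (span 0.3) for
  display; the raw series is always stored.
- **Effective parent number** — inverse Simpson index of the realized
  parent-slot proportions across heterotic-group-1 subpopulations.

## Seeds, determinism, and numerical choices

Every stochastic step draws from its own substream keyed by (master seed,
replicate, purpose, cycle, program, group) via `numpy.random.SeedSequence`
spawn keys. Identical configurations and master seeds reproduce every record
bit-for-bit; replicates can run in any order or in parallel without changing
results; and structures sharing a topology run on common random numbers —
the founder population and landscape of a replicate are identical across
structures, the isolated and distributed structures coincide exactly at
`Pmax = 0`, and iso21 tracks iso bit-for-bit through cycle 20.

Tie-breaks (hybrid selection, program ranking, GCA ranking) are lexicographic
by index, for reproducibility. Frequency vectors are renormalized after
sampling with a 1e-12 floor against underflow. Deterministic comparisons in
tests use tolerances of 1e-9 or tighter; statistical checks state their
standard errors.

## Scale of the shipped experiments

The framework's full production grid — 350 replicates × 15 complexity levels
× 2 scenarios — is cluster scale. The package's own experiments (test suite
and acceptance script) run the same machinery at desk scale, chosen as the
smallest sizes at which the targeted quantities are statistically
resolvable: 50 model replicates × 250 genotypes for the lag profile, 5
replicates × 30 cycles for the K=1 system limits, 10 replicates for the K=8
structure-ranking sign test, 100 schedule replicates for the TPE
calibration. Run manifests flag replicate counts below the full 350.

## What the synthetic data do not capture

Fitness components are idealized random functions: there is no mutation, no
epigenetics, no crop–environment feedback, and the biallelic, evenly spaced
genome abstracts from real marker maps. The founder generator reproduces the
two stated population properties (MAF spectrum, LD decay) but not the
haplotype-block or demographic structure of real breeding germplasm. Passing
tests therefore certify the simulation machinery and its internal
consistency, not predictions for any particular crop program. Cyclical or
extreme-event TPE scenarios and the economic dimension of program design are
out of scope.
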