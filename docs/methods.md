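# Methods

## The inbreeding-purging model

`ip_model` implements the closed-form theory for a population of constant
effective size N_e whose concealed load δ (lethal equivalents) is eroded by
two forces: random fixation/loss of deleterious alleles (drift) and their
selective elimination when inbreeding exposes them in homozygosis (purging).
Drift is captured by Wright's F_t = 1 − (1 − 1/(2N_e))^t; purging by the
purged inbreeding coefficient g_t, which obeys the recursion given in the
README with damping factor (1 − 2dF_{t−1}). The purging coefficient
d = s(½ − h) is the per-locus recessive component hidden in heterozygotes;
since s ≤ 1, d ≤ ½, which the parameter container enforces. Purging is
effective when N_e·d > 1.

Assumptions worth keeping in mind: no epistasis, no new mutation, no
non-purging (standard) selection, and a single effective d summarising a
whole distribution of per-locus effects. The model is therefore expected to
overpredict late fitness slightly in large populations, where new mutation
matters most.

Design choices where the theory leaves gaps:

* **g_0 = 0**, matching F_0 = 0. This makes g_1 = 1/(2N_e) = F_1 for every
  d, and collapses g onto F when d = 0 — both identities are tested.
* **The load prediction at t = 0** uses the limit g_t/F_t → 1, returning δ₀
  rather than 0/0.
* **Estimating d** from an observed (t, δ̂) trajectory minimises the sum of
  squared deviations from the purging-model prediction over d ∈ [0, 0.5]:
  a dense grid (step 0.001) followed by bounded golden-section refinement
  around the best grid point; ties break toward smaller d (the first grid
  minimum). An optional residual bootstrap refits on the grid to give a
  percentile 95% CI. Noiseless trajectories are recovered to grid
  resolution; under realistic assay noise the closed-loop test recovers
  d = 0.3 within ±0.05.
* Trajectories are computed eagerly for all generations 0..T; T is at most
  a few thousand in any realistic use.

## Load estimation and bootstrap conventions

δ = ln(P_O/P_I)/F̄, with F̄ the mean of the inbred scheme's parental and
progeny inbreeding coefficients (productivity depends on both genotypes;
the standard design gives F̄ = (0.25 + 0.375)/2 = 0.3125). The outbred
scheme must carry F = 0 and never contributes to the denominator.

The bootstrap resamples **pairs** (the experimental unit) with replacement,
independently within each scheme — no pairing exists across schemes —
recomputing δ per replicate; `se` is the replicate standard deviation.
Replicates with a zero scheme mean are redrawn rather than dropped, keeping
the replicate count fixed (the redraw count is reported). Conventions for
the p-values, which the underlying theory does not dictate:

* `p_leq_zero` is the one-sided fraction of replicates δ* ≤ 0. For unimodal
  data this tracks the normal approximation Φ(−δ̂/se) within ±0.03 at
  B = 1000 (tested).
* `compare_loads` pairs two replicate series by index, orients them so the
  larger estimate comes first, and reports the fraction of differences ≤ 0.
  Series of unequal length have the shorter resampled (seeded) to match.
* `test_against_prediction` takes the tail on the side opposite the
  observed deviation from the model value.

These are conventions, not unique choices; they reproduce the magnitudes of
published estimates (e.g. δ̂ = 0.145, se = 0.098 ⇒ p ≈ 0.066).

## DFE families and the equilibrium solver

The gamma family draws s from gamma(mean s̄, shape β = 0.2), truncating
s > 1 to 1 so the model owns a homozygous-lethal class, and h | s ~
Uniform(0, e^(−ks)): severe mutations are more recessive. The constant k is
solved so that E[h] = h̄ over the truncated s distribution (truncation is
applied before dominance assignment, and the s = 1 point mass is included
in the expectation, which mixes adaptive quadrature of the continuous part
with the analytic tail mass; Brent root-finding to 1e−8 in the
expectation). The lethal class receives its h from the same rule — at the
solved k values e^(−k) is tiny, so lethals are effectively fully recessive.
The piecewise small-effect family fixes s̄ = 0.0161, β = 0.186 and h = 0.25
for s < 0.02, else h = 0. A neutral family (s = h = 0) provides drift-only
controls.

Equilibrium frequencies under one-way wild-type → mutant mutation follow
the classical recursion for p′ given in the module docstring. Setting
p′ = p and eliminating p = 1 − q reduces the fixed point **exactly** to the
quadratic q²s(2h−1) − qsh(1+u) + u = 0, solved with the numerically stable
root 2u/(sh(1+u) + √disc); every returned frequency is verified against the
recursion to a residual ≤ 1e−10. The closed form was chosen over iterating
the recursion because near-recessive loci contract by only ~1 − 2sq per
step, needing ~10⁵ iterations each; the algebra costs nothing and satisfies
the same residual contract. The h = 0 and sh ≫ u limits recover the
textbook √(u/s) and u/(sh) frequencies.

One consequence of gamma-distributed effects with shape 0.2 is a heavy mass
of nearly neutral loci. Where mutation pressure beats selection (s
comparable to u, or tiny s with h > ½ drawn from the uniform), the
quadratic has no root in (0, 1): the true equilibrium under one-way
mutation is fixation of the mutant, and the solver returns q̂ = 1 (zero
inbreeding-load contribution) for those loci rather than failing.

Mutation-rate calibration holds the (s, h) draw fixed at the given seed and
finds U by Brent's method so the genomic Morton load Σ s(1−2h)p̂q̂ hits the
target within 1e−3; the reported U is conditional on the genome
realisation (seed-to-seed spread is a few percent at L = 9000). The load is
monotone increasing in U, and near-linear in u where dominance is
appreciable (tested), so the root is unique.

## Forward simulator

Dioecious individuals, sex ratio one (an odd census — the historical line
size is 43 — leaves the extra individual male), polygamous mating: each of
the N offspring draws a mother and a father independently, with
replacement, with probability proportional to fitness *within* each sex.
Fitness is multiplicative across loci with genotype factors 1, 1 − sh,
1 − s. Loci are unlinked; each parent transmits one allele per locus by a
fair Mendelian draw, and each transmitted wild-type allele mutates with
probability u. Genotypes are stored as dosages in {0, 1, 2} — phase carries
no information under free recombination and multiplicative fitness. There
is no back mutation, no linkage map, no environmental variance.

The experiment runs natural population (Hardy-Weinberg assignment from the
deterministic q̂) → base population (sampled without replacement) →
derived line (sampled without replacement at the split generation), with
the natural population generated once per experiment and all subsequent
randomness replicated. Replicates whose female or male pool reaches
all-zero fitness are discarded and counted. Mean fitness and the realised
Morton load are recorded every generation and averaged across replicates;
`fit_quality` pools base and line observations into a single mean-square
difference.

The drift-only control tracks the closed-form expectations closely: the
expected load decays as δ₀(1 − F_t) and heterozygosity as ~1/(2N) per
generation. The realised decay corresponds to N_e ≈ N + ½ — the standard
correction for separate sexes without selfing — which is within ~1% of
1/(2N) at the sizes used and invisible at three standard errors over 150
generations.

## Synthetic assay data

The generator reproduces the paired design exactly as the estimator assumes
it: outbred counts with mean P₀, inbred counts with mean P₀·e^(−δF̄), both
negative-binomial. The dispersion default (size = 20) reproduces the
overdispersion implied by the published summaries (means near 87 with
standard errors near 2 at n ≈ 100 ⇒ SD/mean ≈ 0.25, far above Poisson).
What it does **not** emulate: vial-level environmental covariates, the
between-assay environmental drift visible in the real productivity means,
non-log-linear inbreeding effects, and any correlation between schemes.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to those
departures.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the whole
suite completes in a few minutes while keeping Monte-Carlo error well below
the tolerances tested: L = 500–2000 loci and 2–10 replicates for simulator
checks (the drift oracle uses N = 40, L = 500, 150 generations, 50
replicates), L = 9000 with 10 genome seeds for equilibrium-load
decomposition, B = 50–1000 bootstrap replicates, and n up to 10⁴ pairs for
estimator asymptotics. The full experimental scale (9000 loci, N_base =
1376, 100 replicates, 334 generations) runs through the same configuration
objects.

## Known limitations

* The IP predictions ignore new mutation and non-purging selection; the
  full-model extension is out of scope.
* The effective d is a single fitted constant; per-locus heterogeneity in
  purging efficiency is only represented in the simulator.
* Bootstrap p-value conventions (sidedness, tie handling) follow the
  choices above and can differ from other software by O(1/B).
* The equilibrium solver assumes linkage equilibrium and one-way mutation;
  it is not a substitute for forward simulation when drift matters
  (N_e·s ≲ 1 at the sizes simulated).
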