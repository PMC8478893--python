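# purgekit

Tools for studying **genetic purging under slow inbreeding**: how much of a
population's concealed deleterious load (its *inbreeding load*, measured in
lethal equivalents) natural selection removes when inbreeding slowly exposes
recessive alleles in homozygosis, and how much is lost to drift alone.

The package is aimed at population, conservation and quantitative geneticists
who work with long-term inbreeding experiments or managed populations. It
implements four connected pieces:

1. **Inbreeding-purging (IP) theory.** Wright's inbreeding coefficient
   F_t = 1 − (1 − 1/(2N_e))^t and the purged inbreeding coefficient

       g_t = [1/(2N_e) + (1 − 1/(2N_e)) g_{t−1}] (1 − 2 d F_{t−1}),  g_0 = 0,

   where d = s(½ − h) is the purging coefficient. Mean fitness and load are
   predicted as E[P_t] = P_0·e^(−δ·g_t) and E[δ_t] = δ·g_t(1 − F_t)/F_t
   (drift-only versions use F_t in place of g_t), and d can be recovered from
   an observed load trajectory by least squares.
2. **Load estimation.** δ = ln(P_O / P_I) / F̄ from paired noninbred/inbred
   productivity assays, with pair-level bootstrap standard errors and
   one-sided p-values.
3. **Mutation-selection balance genomes.** Gamma-distributed homozygous
   effects (with an s = 1 lethal class), dominance h | s ~ U(0, e^(−ks))
   constrained to a target mean, per-locus equilibrium frequencies solved
   exactly from the classical recursion, Morton load decomposition
   δ = Σ s(1 − 2h)pq, and calibration of the genomic mutation rate U to a
   target load.
4. **Forward simulation.** A dioecious, fitness-proportional-mating
   Wright-Fisher simulator of the natural population → base population →
   derived line design, with replicate-averaged fitness and load
   trajectories and a mean-square fit statistic against observations.

A synthetic-data generator emulates the paired assay design with
negative-binomial counts so every estimation stage is testable end to end,
and `purgekit.datasets` ships the published productivity summaries of the
two long-term *Drosophila melanogaster* experiments (the "Madrid" and
"Vigo" populations) the methods were developed around.

## Worked example

Did the Madrid base population (N_e ≈ 1376, initial load δ₀ = 2.0, purging
coefficient d = 0.3) purge its load, or just drift it away?

```python
from purgekit import (IPParams, purged_inbreeding, predict_inbreeding_load,
                      delta_from_means, mean_inbreeding_coefficient,
                      predict_relative_line_fitness)

f_bar = mean_inbreeding_coefficient(0.25, 0.375)        # parents, offspring
delta_hat = delta_from_means(86.96, 83.11, f_bar)        # generation-234 assay
print(f"observed load at generation 234: {delta_hat:.3f} lethal equivalents")

base = IPParams(ne=1376, d=0.3, delta0=2.00)
traj = purged_inbreeding(base, 234)
print(f"IP-predicted load (purging):     {predict_inbreeding_load(base, traj, 'purging')[-1]:.3f}")
print(f"drift-only predicted load:       {predict_inbreeding_load(base, traj, 'neutral')[-1]:.3f}")
```

prints

```
observed load at generation 234: 0.145 lethal equivalents
IP-predicted load (purging):     0.178
drift-only predicted load:       1.837
```

The observed load is an order of magnitude below the drift-only expectation
but agrees with the purging prediction: after 234 generations the load is
essentially exhausted, and selection — not drift — removed it. The same
comparison for the derived lines' productivity relative to the base,

```python
line = IPParams(ne=43, d=0.3, delta0=1.402)
predict_relative_line_fitness(base, line, t_line=153, t_base=234, "purging")  # 1.000
# with d=0 in both lineages (drift only):                                       0.366
# observed: 72.04 / 86.96 =                                                     0.828
```

shows the observed ratio far above the drift-only collapse, again closer to
the purging prediction.

A command-line interface mirrors the library (`purgekit ip-predict`,
`fit-d`, `estimate-load`, `synth`, `build-genome`, `simulate`,
`fit-quality`); every run writes a manifest JSON so seeded outputs are
bit-for-bit reproducible.

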