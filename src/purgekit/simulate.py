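"""Individual-based Wright-Fisher simulation of purging experiments.

Reproduces the design of a long-term slow-inbreeding experiment: a large
natural population at mutation-selection balance is sampled to found a base
population of moderate size; after ``t_split`` generations a small line is
split off, and both are maintained synchronously while mean fitness and
inbreeding load are tracked each generation and averaged over replicates.

Model assumptions: dioecious individuals with an exact 1:1 sex ratio;
polygamous mating with parents drawn independently per offspring, with
replacement, with probability proportional to fitness within each sex;
unlinked loci with independent Mendelian transmission; multiplicative
fitness across loci (genotype factors 1, 1 - s*h, 1 - s); one-way
wild-type -> mutant mutation at rate ``u`` per transmitted allele.
Genotypes are stored as per-locus dosages (phase is irrelevant under free
recombination and multiplicative fitness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfe import GenomeDFE, locus_load

__all__ = [
    "ExtinctionError",
    "Population",
    "SimConfig",
    "SimResult",
    "genotype_fitness",
    "found_natural_population",
    "next_generation",
    "population_load",
    "run_experiment",
    "fit_quality",
]


class ExtinctionError(RuntimeError):
    """All fitness is zero within one sex; the population cannot reproduce."""


@dataclass
class Population:
    """Diploid dosage matrix ``(N, L)`` with the first ``N // 2`` rows female.

    The sex ratio is one: ``N // 2`` females and ``N - N // 2`` males (an odd
    census, such as the historical line size of 43, leaves one extra male).
    """

    genotypes: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x loci) array")
        if g.shape[0] < 2:
            raise ValueError("population needs at least one individual of each sex")
        if g.size and (g.min() < 0 or g.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")
        self.genotypes = g.astype(np.uint8)

    @property
    def N(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def L(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def n_females(self) -> int:
        return self.N // 2

    def allele_frequencies(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0


def genotype_fitness(dosages: np.ndarray, genome: GenomeDFE) -> np.ndarray:
    """Multiplicative fitness of one genotype (1-D) or a population (2-D).

    Per-locus factors are 1 for wild-type homozygotes, ``1 - s h`` for
    heterozygotes and ``1 - s`` for mutant homozygotes; an ``s = 1``
    homozygote is lethal (fitness 0).
    """
    d = np.asarray(dosages)
    factors = np.stack([
        np.ones(genome.L),
        1.0 - genome.s * genome.h,
        1.0 - genome.s,
    ])
    per_locus = factors[d, np.arange(genome.L)]
    w = per_locus.prod(axis=-1)
    return w if np.ndim(dosages) > 1 else float(w)


def found_natural_population(
    genome: GenomeDFE, n: int, seed=None
) -> Population:
    """Hardy-Weinberg assignment of mutant copies from equilibrium frequencies.

    Each individual's dosage at locus ``i`` is binomial(2, q_i), i.e. the sum
    of two independent allele draws.
    """
    if genome.q is None:
        raise ValueError("genome has no equilibrium frequencies; solve them first")
    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, genome.q, size=(int(n), genome.L))
    return Population(genotypes=genotypes)


def _sample_parents(rng, w: np.ndarray, n_offspring: int, selection: bool) -> np.ndarray:
    if not selection:
        return rng.integers(0, w.size, size=n_offspring)
    total = w.sum()
    if total <= 0:
        raise ExtinctionError("all individuals of one sex have zero fitness")
    return rng.choice(w.size, size=n_offspring, replace=True, p=w / total)


def next_generation(
    pop: Population,
    genome: GenomeDFE,
    rng,
    selection: bool = True,
    mutation: bool = True,
) -> Population:
    """Produce the next generation of the same census size.

    For each of the ``N`` offspring (``N/2`` per sex, fixed) a mother and a
    father are drawn independently with replacement, fitness-proportionally
    within their sex; each transmits one allele per locus by a fair
    Mendelian draw, and each transmitted wild-type allele mutates with
    probability ``u`` at that locus.
    """
    rng = np.random.default_rng(rng)
    N, L = pop.N, pop.L
    nf = pop.n_females
    g = pop.genotypes

    if selection:
        w = genotype_fitness(g, genome)
    else:
        w = np.ones(N)
    mothers = _sample_parents(rng, w[:nf], N, selection)
    fathers = nf + _sample_parents(rng, w[nf:], N, selection)

    half = g.astype(np.float64) / 2.0
    maternal = rng.random((N, L)) < half[mothers]
    paternal = rng.random((N, L)) < half[fathers]
    if mutation and genome.u.any():
        maternal |= rng.random((N, L)) < genome.u
        paternal |= rng.random((N, L)) < genome.u
    offspring = maternal.astype(np.uint8) + paternal.astype(np.uint8)
    return Population(genotypes=offspring)


def population_load(pop: Population, genome: GenomeDFE) -> float:
    """Realised inbreeding load: Morton sum over current allele frequencies."""
    q = pop.allele_frequencies()
    return float(np.sum(locus_load(genome.s, genome.h, q)))


@dataclass
class SimConfig:
    """Configuration of a natural -> base -> line maintenance experiment."""

    genome: GenomeDFE
    n_natural: int = 10_000
    n_base: int = 1376
    n_line: int = 43
    t_split: int = 83
    t_total: int = 250
    replicates: int = 100
    seed: int | None = None
    selection: bool = True
    mutation: bool = True
    record_replicates: bool = False

    def __post_init__(self) -> None:
        if self.t_split < 0 or self.t_total < 0:
            raise ValueError("generation counts must be non-negative")
        for name in ("n_natural", "n_base", "n_line"):
            n = getattr(self, name)
            if n < 2:
                raise ValueError(f"{name} must be at least 2, got {n}")
        if self.n_line > self.n_base:
            raise ValueError("the derived line cannot exceed the base population")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")


@dataclass
class SimResult:
    """Replicate-averaged trajectories for the base population and the line.

    ``t_base`` runs 0..t_split+t_total; ``t_line`` runs on the base
    population's time scale from ``t_split`` (the founding of the line).
    """

    t_base: np.ndarray
    w_base: np.ndarray
    w_base_sd: np.ndarray
    load_base: np.ndarray
    load_base_sd: np.ndarray
    t_line: np.ndarray
    w_line: np.ndarray
    w_line_sd: np.ndarray
    load_line: np.ndarray
    load_line_sd: np.ndarray
    n_replicates: int
    n_extinct: int
    config: SimConfig = field(repr=False)
    replicate_load_base: np.ndarray | None = field(default=None, repr=False)
    replicate_load_line: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per generation and population)."""
        base = pd.DataFrame({
            "generation": self.t_base, "pop": "base",
            "W_mean": self.w_base, "W_sd": self.w_base_sd,
            "delta_mean": self.load_base, "delta_sd": self.load_base_sd,
        })
        line = pd.DataFrame({
            "generation": self.t_line, "pop": "line",
            "W_mean": self.w_line, "W_sd": self.w_line_sd,
            "delta_mean": self.load_line, "delta_sd": self.load_line_sd,
        })
        out = pd.concat([base, line], ignore_index=True)
        out["n_replicates"] = self.n_replicates
        return out


def _run_replicate(config: SimConfig, natural: Population, rng):
    """One replicate: returns (w_base, load_base, w_line, load_line) arrays."""
    genome = config.genome
    t_end = config.t_split + config.t_total

    idx = rng.choice(natural.N, size=config.n_base, replace=False)
    base = Population(genotypes=natural.genotypes[idx])

    w_base = np.empty(t_end + 1)
    load_base = np.empty(t_end + 1)
    w_line = np.empty(config.t_total + 1)
    load_line = np.empty(config.t_total + 1)

    def record(pop, w_arr, l_arr, i):
        w = genotype_fitness(pop.genotypes, genome)
        w_arr[i] = w.mean()
        l_arr[i] = population_load(pop, genome)

    record(base, w_base, load_base, 0)
    for t in range(1, config.t_split + 1):
        base = next_generation(base, genome, rng, config.selection, config.mutation)
        record(base, w_base, load_base, t)

    line_idx = rng.choice(base.N, size=config.n_line, replace=False)
    line = Population(genotypes=base.genotypes[line_idx])
    record(line, w_line, load_line, 0)

    for j in range(1, config.t_total + 1):
        base = next_generation(base, genome, rng, config.selection, config.mutation)
        record(base, w_base, load_base, config.t_split + j)
        line = next_generation(line, genome, rng, config.selection, config.mutation)
        record(line, w_line, load_line, j)
    return w_base, load_base, w_line, load_line


def run_experiment(config: SimConfig) -> SimResult:
    """Run the replicated experiment and average the trajectories.

    The natural population (and the genome realisation it is built from) is
    generated once; each replicate re-samples founders from it and carries
    its own reproduction randomness.  Replicates that go extinct (all-zero
    fitness within a sex) are discarded and counted in ``n_extinct``.
    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    nat_ss, rep_root = ss.spawn(2)
    natural = found_natural_population(
        config.genome, config.n_natural, np.random.default_rng(nat_ss)
    )

    kept_b, kept_lb, kept_wl, kept_ll = [], [], [], []
    n_extinct = 0
    for child in rep_root.spawn(config.replicates):
        rng = np.random.default_rng(child)
        try:
            w_b, l_b, w_l, l_l = _run_replicate(config, natural, rng)
        except ExtinctionError:
            n_extinct += 1
            continue
        kept_b.append(w_b)
        kept_lb.append(l_b)
        kept_wl.append(w_l)
        kept_ll.append(l_l)

    if not kept_b:
        raise ExtinctionError("every replicate went extinct")
    w_base = np.array(kept_b)
    load_base = np.array(kept_lb)
    w_line = np.array(kept_wl)
    load_line = np.array(kept_ll)

    t_end = config.t_split + config.t_total
    ddof = 1 if w_base.shape[0] > 1 else 0
    return SimResult(
        t_base=np.arange(t_end + 1),
        w_base=w_base.mean(axis=0),
        w_base_sd=w_base.std(axis=0, ddof=ddof),
        load_base=load_base.mean(axis=0),
        load_base_sd=load_base.std(axis=0, ddof=ddof),
        t_line=np.arange(config.t_split, t_end + 1),
        w_line=w_line.mean(axis=0),
        w_line_sd=w_line.std(axis=0, ddof=ddof),
        load_line=load_line.mean(axis=0),
        load_line_sd=load_line.std(axis=0, ddof=ddof),
        n_replicates=w_base.shape[0],
        n_extinct=n_extinct,
        config=config,
        replicate_load_base=load_base if config.record_replicates else None,
        replicate_load_line=load_line if config.record_replicates else None,
    )


def fit_quality(sim: SimResult, observed_base=(), observed_line=()) -> float:
    """Mean squared difference between observed and simulated load values.

    ``observed_base`` and ``observed_line`` are sequences of ``(generation,
    load)`` pairs on the base population's time scale; base and line points
    are pooled into a single mean.
    """
    diffs = []
    for (obs, t_axis, series) in (
        (observed_base, sim.t_base, sim.load_base),
        (observed_line, sim.t_line, sim.load_line),
    ):
        for t, value in obs:
            pos = np.searchsorted(t_axis, t)
            if pos >= len(t_axis) or t_axis[pos] != t:
                raise ValueError(f"generation {t} is outside the simulated range")
            diffs.append(value - series[pos])
    if not diffs:
        raise ValueError("no observed points supplied")
    return float(np.mean(np.square(diffs)))
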