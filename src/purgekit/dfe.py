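"""Deleterious-mutation models and mutation-selection-balance equilibrium.

Builds a genome of ``L`` unlinked diploid positions, each carrying a
homozygous selection coefficient ``s``, a dominance coefficient ``h`` and a
per-locus mutation rate ``u = U/L`` (``U`` is the haploid genomic rate).
Three model families are supported:

``gamma_uniform_h``
    ``s`` ~ gamma with mean ``s_mean`` and shape ``beta``; values above 1
    are truncated to 1, creating a homozygous-lethal class.  ``h | s`` ~
    Uniform(0, exp(-k*s)), with the constant ``k`` solved so that the mean
    dominance equals ``h_mean`` (severe mutations are thereby more
    recessive).
``kim_piecewise_h``
    ``s`` ~ gamma(mean 0.0161, shape 0.186); ``h = 0.25`` for ``s < 0.02``
    and ``h = 0`` otherwise (a genomic-data-derived small-effect model).
``neutral``
    ``s = h = 0`` everywhere; used for drift-only controls.

Deterministic equilibrium frequencies under one-way mutation follow the
classical wild-type recursion

    p' = [p^2 + p q (1 - s h)] (1 - u) / [1 - 2 p q s h - q^2 s].

Setting ``p' = p`` and eliminating ``p = 1 - q`` reduces the fixed point to
the quadratic ``q^2 s (2h - 1) - q s h (1 + u) + u = 0``, which this module
solves in closed form (see :func:`equilibrium_frequency`).  The per-locus
inbreeding load is Morton's ``s (1 - 2h) p q``, summed across loci for the
genomic load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "DFEModel",
    "GenomeDFE",
    "CalibrationResult",
    "solve_k",
    "truncated_gamma_mean",
    "sample_dfe",
    "equilibrium_frequency",
    "solve_equilibrium",
    "build_genome",
    "locus_load",
    "genome_load",
    "load_fraction_below",
    "calibrate_mutation_rate",
]

KIM_S_MEAN = 0.0161
KIM_BETA = 0.186
KIM_H_THRESHOLD = 0.02
_FAMILIES = ("gamma_uniform_h", "kim_piecewise_h", "neutral")


@dataclass
class DFEModel:
    """Distribution of fitness effects plus genomic mutation parameters."""

    family: str
    L: int
    U: float = 0.0
    s_mean: float | None = None
    beta: float | None = None
    h_mean: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown DFE family {self.family!r}")
        if self.L < 1:
            raise ValueError("L must be at least 1")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.family == "gamma_uniform_h":
            if self.s_mean is None or not self.s_mean > 0:
                raise ValueError("gamma_uniform_h requires s_mean > 0")
            if self.beta is None or not self.beta > 0:
                raise ValueError("gamma_uniform_h requires beta > 0")
            if self.h_mean is None or not 0.0 < self.h_mean < 0.5:
                raise ValueError("gamma_uniform_h requires 0 < h_mean < 0.5")
        elif self.family == "kim_piecewise_h":
            self.s_mean = KIM_S_MEAN
            self.beta = KIM_BETA

    @property
    def u(self) -> float:
        """Per-locus mutation rate ``U / L``."""
        return self.U / self.L

    @classmethod
    def gamma_uniform_h(cls, s_mean: float, h_mean: float, U: float, L: int,
                        beta: float = 0.2) -> "DFEModel":
        return cls(family="gamma_uniform_h", L=L, U=U, s_mean=s_mean,
                   beta=beta, h_mean=h_mean)

    @classmethod
    def kim(cls, U: float, L: int) -> "DFEModel":
        return cls(family="kim_piecewise_h", L=L, U=U)

    @classmethod
    def neutral(cls, L: int) -> "DFEModel":
        return cls(family="neutral", L=L, U=0.0)


@dataclass
class GenomeDFE:
    """Realised per-locus parameters (and, once solved, equilibrium state)."""

    s: np.ndarray
    h: np.ndarray
    u: np.ndarray
    model: DFEModel | None = None
    seed: int | None = None
    q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if not (self.s.shape == self.h.shape == self.u.shape):
            raise ValueError("s, h and u must have identical shapes")

    @property
    def L(self) -> int:
        return int(self.s.size)


def _gamma_sh_scale(s_mean: float, beta: float) -> tuple[float, float]:
    return beta, s_mean / beta


def truncated_gamma_mean(s_mean: float, beta: float) -> float:
    """Analytic mean of ``min(S, 1)`` for ``S ~ gamma(mean s_mean, shape beta)``."""
    shape, scale = _gamma_sh_scale(s_mean, beta)
    val, _ = integrate.quad(
        lambda s: s * stats.gamma.pdf(s, shape, scale=scale), 0.0, 1.0, limit=200
    )
    return val + float(stats.gamma.sf(1.0, shape, scale=scale))


def _mean_exp_neg_ks(k: float, s_mean: float, beta: float) -> float:
    """E[exp(-k * min(S, 1))] over the truncated gamma (with mass at s = 1)."""
    shape, scale = _gamma_sh_scale(s_mean, beta)
    val, _ = integrate.quad(
        lambda s: np.exp(-k * s) * stats.gamma.pdf(s, shape, scale=scale),
        0.0, 1.0, limit=200,
    )
    return val + float(stats.gamma.sf(1.0, shape, scale=scale)) * np.exp(-k)


def solve_k(model: DFEModel, tol: float = 1e-8) -> float:
    """Solve the dominance-decay constant ``k`` so that ``E[h] = h_mean``.

    With ``h | s ~ Uniform(0, exp(-k s))``, ``E[h] = E[exp(-k s)] / 2``
    taken over the truncated ``s`` distribution.  ``E[h]`` decreases
    monotonically in ``k`` from 1/2 at ``k = 0``, so ``h_mean < 0.5`` always
    has a unique root; the solved value is cached on the model.
    """
    if model.family != "gamma_uniform_h":
        raise ValueError("k is only defined for the gamma_uniform_h family")
    target = model.h_mean

    def f(k: float) -> float:
        return _mean_exp_neg_ks(k, model.s_mean, model.beta) / 2.0 - target

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket k")
    k = float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))
    if abs(f(k)) > tol:
        raise RuntimeError(f"k solution off by {f(k):.2e} in the expectation")
    model.k = k
    return k


def sample_dfe(model: DFEModel, seed: int | None = None) -> GenomeDFE:
    """Draw the ``L`` per-locus ``(s, h)`` values for a model realisation."""
    rng = np.random.default_rng(seed)
    L = model.L
    if model.family == "neutral":
        s = np.zeros(L)
        h = np.zeros(L)
    else:
        shape, scale = _gamma_sh_scale(model.s_mean, model.beta)
        s = np.minimum(rng.gamma(shape, scale, size=L), 1.0)
        if model.family == "kim_piecewise_h":
            h = np.where(s < KIM_H_THRESHOLD, 0.25, 0.0)
        else:
            if model.k is None:
                solve_k(model)
            h = rng.uniform(0.0, np.exp(-model.k * s))
    u = np.full(L, model.u)
    return GenomeDFE(s=s, h=h, u=u, model=model, seed=seed)


def equilibrium_frequency(s, h, u, residual_tol: float = 1e-10):
    """Deterministic mutant frequency at mutation-selection balance.

    Solves the fixed point of the wild-type recursion in closed form via the
    equivalent quadratic ``q^2 s(2h-1) - q s h(1+u) + u = 0``, using the
    numerically stable root ``q = 2u / (s h (1+u) + sqrt(disc))``.  The
    result is verified against the recursion to ``residual_tol``.

    Loci where mutation pressure overwhelms selection (no interior root in
    (0, 1), e.g. nearly neutral loci with ``s`` comparable to ``u``) fix the
    mutant allele: ``q = 1`` is returned for them.  Neutral loci (``s = 0``)
    are rejected.
    """
    s_arr, h_arr, u_arr = np.broadcast_arrays(
        np.asarray(s, dtype=float), np.asarray(h, dtype=float), np.asarray(u, dtype=float)
    )
    scalar = s_arr.ndim == 0
    s_arr, h_arr, u_arr = np.atleast_1d(s_arr, h_arr, u_arr)
    if np.any(s_arr <= 0) or np.any(s_arr > 1):
        raise ValueError("selection coefficients must lie in (0, 1]")
    if np.any((h_arr < 0) | (h_arr > 1)):
        raise ValueError("dominance coefficients must lie in [0, 1]")
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("mutation rates must lie in (0, 1)")

    a = s_arr * (2.0 * h_arr - 1.0)
    b = -s_arr * h_arr * (1.0 + u_arr)
    c = u_arr
    disc = b * b - 4.0 * a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        q = 2.0 * c / (-b + np.sqrt(disc))
    fixed = (disc < 0) | ~np.isfinite(q) | (q >= 1.0)
    q = np.where(fixed, 1.0, q)

    interior = ~fixed
    if np.any(interior):
        qi = q[interior]
        p = 1.0 - qi
        si, hi, ui = s_arr[interior], h_arr[interior], u_arr[interior]
        p_next = ((p * p + p * qi * (1.0 - si * hi)) * (1.0 - ui)
                  / (1.0 - 2.0 * p * qi * si * hi - qi * qi * si))
        resid = np.abs(p_next - p)
        if resid.max(initial=0.0) > residual_tol:
            raise ArithmeticError(
                f"equilibrium residual {resid.max():.2e} exceeds {residual_tol:.0e}"
            )
    return float(q[0]) if scalar else q


def solve_equilibrium(genome: GenomeDFE) -> GenomeDFE:
    """Attach equilibrium frequencies to a genome (in place; returns it).

    Neutral loci (``s = 0``) are given ``q = 0``: the drift-only controls
    seed their frequencies explicitly rather than from a balance.
    """
    q = np.zeros(genome.L)
    sel = genome.s > 0
    if np.any(sel):
        q[sel] = equilibrium_frequency(genome.s[sel], genome.h[sel], genome.u[sel])
    genome.q = q
    return genome


def build_genome(model: DFEModel, seed: int | None = None) -> GenomeDFE:
    """Sample a DFE realisation and solve its equilibrium state."""
    genome = sample_dfe(model, seed)
    if model.family != "neutral":
        solve_equilibrium(genome)
    else:
        genome.q = np.zeros(model.L)
    return genome


def locus_load(s, h, q):
    """Morton load contribution ``s (1 - 2h) q (1 - q)`` of one locus."""
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr < 0) | (q_arr > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return s * (1.0 - 2.0 * np.asarray(h, dtype=float)) * q_arr * (1.0 - q_arr)


def genome_load(genome: GenomeDFE) -> float:
    """Total inbreeding load: sum of per-locus Morton contributions."""
    if genome.q is None:
        raise ValueError("equilibrium frequencies have not been solved")
    if genome.L == 0:
        return 0.0
    return float(np.sum(locus_load(genome.s, genome.h, genome.q)))


def load_fraction_below(genome: GenomeDFE, s_cut: float) -> float:
    """Fraction of the total load carried by loci with ``s < s_cut``."""
    total = genome_load(genome)
    if total <= 0:
        raise ValueError("total load must be positive")
    loads = locus_load(genome.s, genome.h, genome.q)
    return float(loads[genome.s < s_cut].sum() / total)


@dataclass(frozen=True)
class CalibrationResult:
    U: float
    load: float
    genome: GenomeDFE = field(repr=False)


def calibrate_mutation_rate(
    model: DFEModel,
    target_load: float,
    bounds: tuple[float, float] = (1e-6, 2.0),
    seed: int | None = None,
    tol: float = 1e-3,
) -> CalibrationResult:
    """Find the genomic mutation rate ``U`` yielding a target equilibrium load.

    The locus draw (``s``, ``h``) is held fixed at the given seed while ``U``
    varies, so the calibrated rate is conditional on that genome
    realisation; the equilibrium load is monotone increasing in ``U``, and
    the root is found by Brent's method to ``|load - target| <= tol``.
    """
    if not target_load > 0:
        raise ValueError("target_load must be positive")
    if model.family == "neutral":
        raise ValueError("cannot calibrate a neutral model")
    genome = sample_dfe(model, seed)

    def load_at(U: float) -> float:
        q = equilibrium_frequency(genome.s, genome.h, np.full(genome.L, U / model.L))
        return float(np.sum(locus_load(genome.s, genome.h, q)))

    lo, hi = bounds
    f_lo, f_hi = load_at(lo) - target_load, load_at(hi) - target_load
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target load {target_load} not bracketed by U in {bounds} "
            f"(loads {f_lo + target_load:.4g}..{f_hi + target_load:.4g})"
        )
    U = float(optimize.brentq(lambda x: load_at(x) - target_load, lo, hi,
                              xtol=1e-12, rtol=8.9e-16))
    achieved = load_at(U)
    if abs(achieved - target_load) > tol:
        raise RuntimeError(f"calibration stopped {abs(achieved - target_load):.2e} "
                           "away from the target")
    model.U = U
    genome.u = np.full(genome.L, U / model.L)
    solve_equilibrium(genome)
    return CalibrationResult(U=U, load=achieved, genome=genome)
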