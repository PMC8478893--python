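"""Estimation of the inbreeding load from productivity assays.

The inbreeding load :math:`\\delta` (in lethal equivalents) is estimated by
contrasting the mean productivity of a noninbred ("outbred") mating scheme,
:math:`P_O`, with that of an inbred full-sib scheme, :math:`P_I`:

.. math::  \\delta = \\ln(P_O / P_I) / \\bar F,

where :math:`\\bar F` is the average inbreeding coefficient of the inbred
scheme's parents and progeny (productivity depends on both genotypes).
Standard errors and one-sided p-values are obtained by a pair-level
bootstrap: pairs are resampled with replacement independently within each
scheme and the estimator recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProductivityAssay",
    "LoadEstimate",
    "mean_inbreeding_coefficient",
    "delta_from_means",
    "estimate_delta",
    "bootstrap_load",
    "compare_loads",
    "test_against_prediction",
    "estimate_loads_from_table",
]

ASSAY_COLUMNS = [
    "population", "generation", "scheme",
    "F_parents", "F_offspring", "pair_id", "pupae_count",
]


@dataclass
class ProductivityAssay:
    """Per-pair pupae counts for one evaluation scheme.

    ``scheme`` is either ``"outbred"`` (noninbred pairs, F = 0 for parents
    and progeny) or ``"inbred"`` (full-sib pairs with the scheme's expected
    inbreeding coefficients).
    """

    scheme: str
    f_parents: float
    f_offspring: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in ("outbred", "inbred"):
            raise ValueError(f"scheme must be 'outbred' or 'inbred', got {self.scheme!r}")
        for name, f in (("F_parents", self.f_parents), ("F_offspring", self.f_offspring)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if self.scheme == "outbred" and (self.f_parents != 0.0 or self.f_offspring != 0.0):
            raise ValueError("outbred scheme must have F_parents = F_offspring = 0")
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise ValueError("pupae counts must be non-negative")
        self.counts = counts.astype(float)

    @property
    def n(self) -> int:
        return int(self.counts.size)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())


@dataclass(frozen=True)
class LoadEstimate:
    """Point estimate of the inbreeding load with bootstrap inference."""

    delta: float
    se: float
    p_leq_zero: float
    n_boot: int
    seed: int | None
    replicates: np.ndarray = field(repr=False)
    n_redrawn: int = 0


def mean_inbreeding_coefficient(f_parents: float, f_offspring: float) -> float:
    """Average of the parental and progeny inbreeding coefficients."""
    for name, f in (("F_parents", f_parents), ("F_offspring", f_offspring)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    return (f_parents + f_offspring) / 2.0


def delta_from_means(p_out: float, p_in: float, f_bar: float) -> float:
    """``ln(P_O / P_I) / F_bar`` from scheme means; sign-free."""
    if p_out <= 0 or p_in <= 0:
        raise ValueError("scheme mean productivities must be positive")
    if f_bar <= 0:
        raise ValueError("mean inbreeding coefficient must be positive")
    return float(np.log(p_out / p_in) / f_bar)


def estimate_delta(outbred: ProductivityAssay, inbred: ProductivityAssay) -> float:
    """Point estimate of the inbreeding load from a scheme pair.

    The denominator F always comes from the inbred scheme's coefficients;
    the outbred scheme is validated to carry F = 0.
    """
    if outbred.scheme != "outbred" or inbred.scheme != "inbred":
        raise ValueError("expected one outbred and one inbred assay, in that order")
    f_bar = mean_inbreeding_coefficient(inbred.f_parents, inbred.f_offspring)
    return delta_from_means(outbred.mean, inbred.mean, f_bar)


def bootstrap_load(
    outbred: ProductivityAssay,
    inbred: ProductivityAssay,
    n_boot: int = 1000,
    seed: int | None = None,
) -> LoadEstimate:
    """Bootstrap the load estimator by resampling pairs within each scheme.

    Each replicate draws ``n`` pairs with replacement independently from the
    outbred and inbred counts and recomputes delta.  Replicates in which a
    scheme mean is zero are redrawn (the count is reported in
    ``n_redrawn``), keeping the number of replicates fixed.  ``se`` is the
    standard deviation of the replicate deltas and ``p_leq_zero`` the
    fraction of replicates at or below zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    f_bar = mean_inbreeding_coefficient(inbred.f_parents, inbred.f_offspring)
    delta_hat = delta_from_means(outbred.mean, inbred.mean, f_bar)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            m_out = rng.choice(outbred.counts, size=outbred.n, replace=True).mean()
            m_in = rng.choice(inbred.counts, size=inbred.n, replace=True).mean()
            if m_out > 0 and m_in > 0:
                break
            n_redrawn += 1
        reps[b] = np.log(m_out / m_in) / f_bar

    se = float(reps.std(ddof=1)) if n_boot > 1 else 0.0
    return LoadEstimate(
        delta=delta_hat,
        se=se,
        p_leq_zero=float(np.mean(reps <= 0.0)),
        n_boot=n_boot,
        seed=seed,
        replicates=reps,
        n_redrawn=n_redrawn,
    )


def _replicates(x) -> np.ndarray:
    if isinstance(x, LoadEstimate):
        return x.replicates
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError("replicate series must be nonempty")
    return arr


def compare_loads(a, b, seed: int = 0) -> float:
    """One-sided bootstrap p-value that two load estimates differ.

    Replicates are paired by index and the series are oriented so that the
    one with the larger point estimate (replicate mean) comes first; the
    returned p is the fraction of paired differences <= 0.  If the series
    have unequal lengths the shorter is resampled with replacement (seeded)
    to match the longer.
    """
    ra, rb = _replicates(a), _replicates(b)
    if ra.mean() < rb.mean():
        ra, rb = rb, ra
    if ra.size != rb.size:
        rng = np.random.default_rng(seed)
        if ra.size < rb.size:
            ra = rng.choice(ra, size=rb.size, replace=True)
        else:
            rb = rng.choice(rb, size=ra.size, replace=True)
    return float(np.mean(ra - rb <= 0.0))


def test_against_prediction(replicates, predicted: float) -> float:
    """One-sided bootstrap p-value of an observed load against a model value.

    The tail is taken on the side opposite the observed deviation: if the
    replicate mean exceeds ``predicted`` the p-value is the fraction of
    replicates at or below it, and conversely.
    """
    reps = _replicates(replicates)
    if reps.mean() >= predicted:
        return float(np.mean(reps <= predicted))
    return float(np.mean(reps >= predicted))


def estimate_loads_from_table(
    table: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Estimate delta per (population, generation) from a pair-level table.

    ``table`` follows the assay CSV schema (one row per mated pair, columns
    ``population, generation, scheme, F_parents, F_offspring, pair_id,
    pupae_count``).  Groups missing either scheme are skipped.
    """
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table is missing columns: {missing}")
    out_rows = []
    ss = np.random.SeedSequence(seed)
    groups = list(table.groupby(["population", "generation"], sort=True))
    children = ss.spawn(len(groups))
    for ((pop, gen), grp), child in zip(groups, children):
        schemes = {}
        for scheme, sub in grp.groupby("scheme"):
            schemes[scheme] = ProductivityAssay(
                scheme=scheme,
                f_parents=float(sub["F_parents"].iloc[0]),
                f_offspring=float(sub["F_offspring"].iloc[0]),
                counts=sub["pupae_count"].to_numpy(),
            )
        if "outbred" not in schemes or "inbred" not in schemes:
            continue
        est = bootstrap_load(
            schemes["outbred"], schemes["inbred"], n_boot=n_boot,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out_rows.append({
            "population": pop,
            "generation": gen,
            "n_out": schemes["outbred"].n,
            "n_in": schemes["inbred"].n,
            "P_O": schemes["outbred"].mean,
            "P_I": schemes["inbred"].mean,
            "F_bar": mean_inbreeding_coefficient(
                schemes["inbred"].f_parents, schemes["inbred"].f_offspring
            ),
            "delta": est.delta,
            "se": est.se,
            "p": est.p_leq_zero,
        })
    return pd.DataFrame(out_rows)
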