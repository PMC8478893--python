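"""Inbreeding-purging (IP) theory.

Predicts the joint evolution of mean fitness and inbreeding load in a
population of constant effective size :math:`N_e` that is slowly inbreeding
and, at the same time, purging its recessive deleterious load.

The central quantity is the *purged* inbreeding coefficient ``g``, a version
of Wright's inbreeding coefficient ``F`` discounted for the purging-driven
decline in frequency of (partially) recessive deleterious alleles.  ``g``
obeys the recursion

.. math::

    g_t = \\left[\\frac{1}{2N_e} + \\left(1 - \\frac{1}{2N_e}\\right)
          g_{t-1}\\right] (1 - 2 d F_{t-1}),

with :math:`g_0 = 0`, where ``d`` is the purging coefficient.  For a single
locus with homozygous effect ``s`` and dominance ``h``, ``d = s(1/2 - h)``,
so ``d`` is bounded by 1/2 for ``s <= 1``.  Setting ``d = 0`` recovers
``g_t = F_t`` and the model collapses to plain drift ("neutral" model).

Given an initial inbreeding load ``delta0`` (in lethal equivalents) and an
initial mean fitness ``P0``, the model predicts

* mean fitness:  ``E[P_t] = P0 * exp(-delta0 * F_t)``   (neutral) or
  ``E[P_t] = P0 * exp(-delta0 * g_t)``                   (purging);
* inbreeding load: ``E[delta_t] = delta0 * (1 - F_t)``   (neutral) or
  ``E[delta_t] = delta0 * g_t * (1 - F_t) / F_t``        (purging),
  with the ``t = 0`` value defined by the limit ``g_t/F_t -> 1``.

An effective purging coefficient can be recovered from an observed load
trajectory by least squares (:func:`fit_purging_coefficient`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "IPParams",
    "InbreedingTrajectory",
    "PurgingFit",
    "wright_inbreeding",
    "purged_inbreeding",
    "purged_inbreeding_asymptote",
    "predict_mean_fitness",
    "predict_inbreeding_load",
    "predict_relative_line_fitness",
    "fit_purging_coefficient",
]


@dataclass(frozen=True)
class IPParams:
    """Parameters of one population lineage under the IP model.

    Parameters
    ----------
    ne
        Effective population size (> 0).
    d
        Purging coefficient, ``0 <= d <= 0.5``.  ``d = 0`` means pure drift.
    delta0
        Initial inbreeding load in lethal equivalents.  Any real value is
        accepted (empirical estimates can be slightly negative).
    p0
        Initial expected mean productivity (e.g. pupae per pair).  Only
        required when mean fitness, rather than load, is predicted.
    """

    ne: float
    d: float = 0.0
    delta0: float = 0.0
    p0: float | None = None

    def __post_init__(self) -> None:
        if not self.ne > 0:
            raise ValueError(f"effective size must be positive, got {self.ne}")
        if not 0.0 <= self.d <= 0.5:
            raise ValueError(f"purging coefficient must lie in [0, 0.5], got {self.d}")
        if self.p0 is not None and not self.p0 > 0:
            raise ValueError(f"initial productivity must be positive, got {self.p0}")


@dataclass(frozen=True)
class InbreedingTrajectory:
    """Per-generation standard (``f``) and purged (``g``) inbreeding coefficients."""

    params: IPParams
    t: np.ndarray
    f: np.ndarray
    g: np.ndarray

    def __len__(self) -> int:
        return len(self.t)


def wright_inbreeding(ne: float, t):
    """Wright's inbreeding coefficient ``F_t = 1 - (1 - 1/(2*Ne))**t``.

    ``t`` may be a scalar or an array of non-negative integers.
    """
    if not ne > 0:
        raise ValueError(f"effective size must be positive, got {ne}")
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise ValueError("generation index must be non-negative")
    f = 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t_arr
    return f if f.ndim else float(f)


def purged_inbreeding(params: IPParams, horizon: int) -> InbreedingTrajectory:
    """Trajectory of ``F`` and ``g`` for generations ``0..horizon``."""
    horizon = int(horizon)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    t = np.arange(horizon + 1)
    f = np.asarray(wright_inbreeding(params.ne, t), dtype=float)
    a = 1.0 / (2.0 * params.ne)
    g = np.zeros(horizon + 1)
    for i in range(1, horizon + 1):
        g[i] = (a + (1.0 - a) * g[i - 1]) * (1.0 - 2.0 * params.d * f[i - 1])
    return InbreedingTrajectory(params=params, t=t, f=f, g=g)


def purged_inbreeding_asymptote(ne: float, d: float) -> float:
    """Fixed point of the ``g`` recursion as ``F -> 1``.

    With ``a = 1/(2*Ne)`` the asymptote is ``a(1-2d) / (1 - (1-a)(1-2d))``;
    for ``d = 0`` this is 1, matching ``F``.
    """
    a = 1.0 / (2.0 * ne)
    return a * (1.0 - 2.0 * d) / (1.0 - (1.0 - a) * (1.0 - 2.0 * d))


def _check_consistent(params: IPParams, traj: InbreedingTrajectory, model: str) -> None:
    if model not in ("neutral", "purging"):
        raise ValueError(f"model must be 'neutral' or 'purging', got {model!r}")
    if traj.params.ne != params.ne:
        raise ValueError("trajectory was computed with a different effective size")
    if model == "purging" and traj.params.d != params.d:
        raise ValueError("trajectory was computed with a different purging coefficient")


def predict_mean_fitness(
    params: IPParams, traj: InbreedingTrajectory, model: str = "purging"
) -> np.ndarray:
    """Expected mean fitness series ``P0 * exp(-delta0 * F_t)`` (or ``g_t``)."""
    _check_consistent(params, traj, model)
    if params.p0 is None:
        raise ValueError("p0 is required to predict mean fitness")
    coef = traj.g if model == "purging" else traj.f
    return params.p0 * np.exp(-params.delta0 * coef)


def predict_inbreeding_load(
    params: IPParams, traj: InbreedingTrajectory, model: str = "purging"
) -> np.ndarray:
    """Expected inbreeding-load series.

    Neutral: ``delta0 * (1 - F_t)``.  Purging: ``delta0 * g_t (1 - F_t)/F_t``
    with the value at ``t = 0`` set to ``delta0`` (the ``g/F -> 1`` limit).
    """
    _check_consistent(params, traj, model)
    if model == "neutral":
        return params.delta0 * (1.0 - traj.f)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = params.delta0 * traj.g * (1.0 - traj.f) / traj.f
    out = np.where(traj.f == 0.0, params.delta0, out)
    return out


def predict_relative_line_fitness(
    base: IPParams,
    line: IPParams,
    t_line: int,
    t_base: int,
    model: str = "purging",
) -> float:
    """Expected line productivity relative to its synchronous base population.

    Both lineages are given unit founder mean (the shared founder productivity
    cancels in the ratio), so the result is
    ``exp(-delta0_line * x_line(t_line)) / exp(-delta0_base * x_base(t_base))``
    where ``x`` is ``F`` under the neutral model and ``g`` under purging.
    """
    num_p = replace(line, p0=1.0)
    den_p = replace(base, p0=1.0)
    num = predict_mean_fitness(num_p, purged_inbreeding(num_p, int(t_line)), model)[-1]
    den = predict_mean_fitness(den_p, purged_inbreeding(den_p, int(t_base)), model)[-1]
    return float(num / den)


@dataclass(frozen=True)
class PurgingFit:
    """Result of least-squares estimation of the purging coefficient."""

    d: float
    sse: float
    ci_low: float | None = None
    ci_high: float | None = None
    bootstrap_d: np.ndarray | None = None


def _load_predictions_on_grid(
    t_obs: np.ndarray, ne: float, delta0: float, d_grid: np.ndarray
) -> np.ndarray:
    """Matrix of purging-model load predictions, one row per candidate ``d``."""
    horizon = int(t_obs.max(initial=0))
    preds = np.empty((len(d_grid), len(t_obs)))
    for i, d in enumerate(d_grid):
        params = IPParams(ne=ne, d=float(d), delta0=delta0)
        traj = purged_inbreeding(params, horizon)
        preds[i] = predict_inbreeding_load(params, traj, "purging")[t_obs]
    return preds


def fit_purging_coefficient(
    t_obs,
    delta_obs,
    ne: float,
    delta0: float,
    grid_step: float = 0.001,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> PurgingFit:
    """Least-squares estimate of ``d`` from an observed load trajectory.

    Minimises ``sum_t (delta_obs_t - E[delta_t | d])**2`` over ``d`` in
    ``[0, 0.5]`` using a dense grid (step ``grid_step``) followed by a
    bounded golden-section refinement around the best grid point.  Ties are
    broken toward smaller ``d``.  When ``n_bootstrap > 0`` a residual
    bootstrap (refit on the grid) provides a percentile 95% CI.

    Parameters
    ----------
    t_obs, delta_obs
        Observation generations (non-negative integers) and load estimates.
    ne, delta0
        Effective size and initial load held fixed during the fit.
    """
    t_obs = np.asarray(t_obs, dtype=int)
    delta_obs = np.asarray(delta_obs, dtype=float)
    if t_obs.size == 0:
        raise ValueError("at least one observation is required")
    if t_obs.shape != delta_obs.shape:
        raise ValueError("t_obs and delta_obs must have the same length")

    d_grid = np.arange(0.0, 0.5 + grid_step / 2.0, grid_step)
    preds = _load_predictions_on_grid(t_obs, ne, delta0, d_grid)
    sse = ((delta_obs[None, :] - preds) ** 2).sum(axis=1)
    i_best = int(np.argmin(sse))  # first minimum -> smaller d on ties
    d_best, sse_best = float(d_grid[i_best]), float(sse[i_best])

    lo = max(0.0, d_best - grid_step)
    hi = min(0.5, d_best + grid_step)
    if hi > lo:
        horizon = int(t_obs.max())

        def objective(d: float) -> float:
            params = IPParams(ne=ne, d=d, delta0=delta0)
            traj = purged_inbreeding(params, horizon)
            pred = predict_inbreeding_load(params, traj, "purging")[t_obs]
            return float(((delta_obs - pred) ** 2).sum())

        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if res.fun < sse_best:
            d_best, sse_best = float(res.x), float(res.fun)

    if n_bootstrap <= 0:
        return PurgingFit(d=d_best, sse=sse_best)

    rng = np.random.default_rng(seed)
    fitted = preds[i_best]
    residuals = delta_obs - fitted
    boot_d = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        sse_b = ((resampled[None, :] - preds) ** 2).sum(axis=1)
        boot_d[b] = d_grid[int(np.argmin(sse_b))]
    lo_ci, hi_ci = np.percentile(boot_d, [2.5, 97.5])
    return PurgingFit(d=d_best, sse=sse_best, ci_low=float(lo_ci),
                      ci_high=float(hi_ci), bootstrap_d=boot_d)
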