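"""Bayesian weight refinement of conformer pools against NMR/SANS observables.

The pool's conformer weights w (a point on the probability simplex) are
refined against two observable classes:

* chemical shifts: Gaussian likelihood per observation with variance
  eps_CS^2 + alpha_CS^2 (experimental plus prediction error), evaluated
  at the ensemble-average predicted shift;
* the polymer scaling factor: Gaussian likelihood with variance eps_v^2
  evaluated at the ensemble-average v.

The joint likelihood is the product of the scaling-factor term and all
shift terms.  Refinement starts from the uniform prior and repeatedly
applies Bayes' theorem, using each posterior as the next prior, so the
effective likelihood sharpens over iterations and the ensemble-average
scaling factor converges onto the observation.

Weight-space handling (an implementation choice, since the posterior
over the full simplex is intractable to grid directly): each conformer
carries a persistent one-dimensional prior density over its weight
coordinate x in [0, 1], initialized to the conditional of the uniform
simplex distribution, (1-x)^(n-2).  One iteration sweeps every
conformer in seeded shuffled order; a visit multiplies the current
joint likelihood (as a function of x, with the remaining weights scaled
proportionally by (1-x)) into that conformer's prior, normalizes by the
trapezium rule on a fixed 201-point grid, sets the weight to the
posterior mean and renormalizes the rest.  The grid is densified toward
0 and 1 (smoothstep warp) so that the simplex-conditional prior, whose
mass sits at x ~ 1/n, is resolved for large pools.

Convergence is monitored through the trajectory of the ensemble-average
scaling factor; ensembles are compared by a two-sided rank-sum test on
their final per-conformer weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .conformers import ConformerPool, predict_shifts

__all__ = [
    "ShiftObservation",
    "ScalingObservation",
    "ObservationSet",
    "WeightedEnsemble",
    "ensemble_average",
    "shift_loglik",
    "nu_loglik",
    "joint_loglik",
    "refine",
    "select_top",
    "compare_ensembles",
]

# default per-atom chemical-shift prediction errors alpha_CS (ppm)
ALPHA_CS_DEFAULTS = {"CA": 0.4, "CB": 0.5, "C": 0.5, "N": 1.2, "HN": 0.2}


@dataclass
class ShiftObservation:
    """One measured chemical shift with experimental and prediction errors."""

    residue_index: int
    atom: str
    value: float  # m_i, ppm
    eps: float  # experimental error eps_CS, ppm
    alpha: float | None = None  # prediction error alpha_CS, ppm

    def __post_init__(self) -> None:
        if self.alpha is None:
            self.alpha = ALPHA_CS_DEFAULTS.get(self.atom, 0.5)
        if self.eps <= 0 or self.alpha <= 0:
            raise ValueError("eps_CS and alpha_CS must be > 0")

    @property
    def variance(self) -> float:
        return self.eps**2 + self.alpha**2


@dataclass
class ScalingObservation:
    """The measured polymer scaling factor with its error."""

    value: float
    eps: float

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps_v must be > 0")
        if not (0.0 < self.value < 1.2):
            raise ValueError("scaling factor must lie in (0, 1.2)")


@dataclass
class ObservationSet:
    """Shift observations plus (optionally) a scaling-factor observation."""

    shifts: list = field(default_factory=list)
    scaling: ScalingObservation | None = None

    def __post_init__(self) -> None:
        if not self.shifts and self.scaling is None:
            raise ValueError("observation set is empty")


@dataclass
class WeightedEnsemble:
    """A pool with refined weights and refinement diagnostics."""

    pool: ConformerPool
    weights: np.ndarray
    nu_trajectory: np.ndarray
    loglik: float
    converged: bool
    status: str = "ok"

    def __post_init__(self) -> None:
        s = float(self.weights.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {s})")

    @property
    def mean_nu(self) -> float:
        return float(self.weights @ self.pool.nu)


def ensemble_average(values, weights) -> float:
    """Weighted ensemble average sum_k w_k * value_k (weights normalized)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    return float(weights @ values)


def shift_loglik(obs: ShiftObservation, predicted: float) -> float:
    """Log Gaussian density of one shift observation at the ensemble value."""
    var = obs.variance
    r = obs.value - predicted
    return float(-0.5 * np.log(2.0 * np.pi * var) - r * r / (2.0 * var))


def nu_loglik(obs: ScalingObservation, predicted: float) -> float:
    """Log Gaussian density of the scaling-factor observation."""
    var = obs.eps**2
    r = obs.value - predicted
    return float(-0.5 * np.log(2.0 * np.pi * var) - r * r / (2.0 * var))


def pool_shift_matrix(pool: ConformerPool, shift_obs: list) -> np.ndarray:
    """(n_conformers, n_obs) matrix of predicted shifts for observed keys."""
    keys = [(o.residue_index, o.atom) for o in shift_obs]
    mat = np.empty((len(pool), len(keys)))
    for i, conf in enumerate(pool.conformers):
        table = predict_shifts(conf)
        lut = {(int(r), a): s for r, a, s in
               zip(table["residue_index"], table["atom"], table["shift"])}
        for k, key in enumerate(keys):
            if key not in lut:
                raise KeyError(f"no predicted shift for residue/atom {key}")
            mat[i, k] = lut[key]
    return mat


def joint_loglik(
    obs: ObservationSet,
    pool: ConformerPool,
    weights,
    shift_matrix: np.ndarray | None = None,
) -> float:
    """Joint log-likelihood: scaling term plus the sum over all shift terms.

    All terms are evaluated at ensemble averages.  ``shift_matrix`` may
    be passed to avoid recomputing per-conformer predictions.
    """
    weights = np.asarray(weights, dtype=float)
    total = 0.0
    if obs.scaling is not None:
        total += nu_loglik(obs.scaling, ensemble_average(pool.nu, weights))
    if obs.shifts:
        if shift_matrix is None:
            shift_matrix = pool_shift_matrix(pool, obs.shifts)
        avg = weights @ shift_matrix
        for o, a in zip(obs.shifts, avg):
            total += shift_loglik(o, float(a))
    return total


def _warped_grid(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed grid on [0, 1] densified toward both ends (smoothstep warp).

    Returns (nodes, trapezium weights).  End densification resolves the
    simplex-conditional prior (1-x)^(n-2), whose mass sits at x ~ 1/n.
    """
    u = np.linspace(0.0, 1.0, n_points)
    x = u * u * (3.0 - 2.0 * u)
    tw = np.empty_like(x)
    tw[1:-1] = (x[2:] - x[:-2]) / 2.0
    tw[0] = (x[1] - x[0]) / 2.0
    tw[-1] = (x[-1] - x[-2]) / 2.0
    return x, tw


def refine(
    pool: ConformerPool,
    obs: ObservationSet,
    iterations: int = 15_000,
    grid_points: int = 201,
    seed: int = 0,
    convergence_window: int = 100,
    convergence_tol: float = 1e-4,
    shift_matrix: np.ndarray | None = None,
) -> WeightedEnsemble:
    """Iterative Bayesian refinement of the pool weights.

    One iteration is a full sweep over all conformers in seeded shuffled
    order (the seed governs only the visit order; every density
    evaluation is deterministic).  The trajectory records the
    ensemble-average scaling factor after every iteration; the converged
    flag is set when its change over the trailing ``convergence_window``
    iterations falls below ``convergence_tol``.
    """
    n = len(pool)
    if n == 0:
        raise ValueError("empty pool")
    nu = pool.nu
    has_nu = obs.scaling is not None
    K = len(obs.shifts)
    if K:
        if shift_matrix is None:
            shift_matrix = pool_shift_matrix(pool, obs.shifts)
        P = np.asarray(shift_matrix, dtype=float)
        m_cs = np.array([o.value for o in obs.shifts])
        var_cs = np.array([o.variance for o in obs.shifts])
    else:
        P = np.zeros((n, 0))
        m_cs = np.zeros(0)
        var_cs = np.ones(0)

    spread = 0.0
    if has_nu:
        spread = max(spread, float(np.ptp(nu)))
    if K:
        spread = max(spread, float(np.ptp(P, axis=0).max()))
    if spread < 1e-12:
        return WeightedEnsemble(
            pool,
            np.full(n, 1.0 / n),
            np.full(max(iterations, 1), float(np.mean(nu))),
            joint_loglik(obs, pool, np.full(n, 1.0 / n), shift_matrix=P if K else None),
            converged=True,
            status="degenerate-pool: all conformer observables identical; weights left uniform",
        )

    if n == 1:
        w = np.ones(1)
        return WeightedEnsemble(
            pool, w, np.full(max(iterations, 1), float(nu[0])),
            joint_loglik(obs, pool, w, shift_matrix=P if K else None),
            converged=True,
        )

    x, tw = _warped_grid(grid_points)
    rng = np.random.default_rng(seed)
    # persistent per-conformer log prior over its weight coordinate
    log_prior = np.tile((n - 2) * np.log1p(-np.clip(x, 0.0, 1.0 - 1e-15)), (n, 1))
    log_prior[:, -1] = -np.inf if n > 2 else 0.0

    # weights kept as v * G so proportional renormalization is O(1)
    v = np.full(n, 1.0 / n)
    G = 1.0
    S_nu = float(np.mean(nu)) if has_nu else 0.0
    A = (np.full(n, 1.0 / n) @ P) if K else np.zeros(0)

    traj = np.empty(iterations)
    for it in range(iterations):
        order = rng.permutation(n)
        for j in order:
            a = v[j] * G
            rest = 1.0 - a
            if rest <= 1e-12:
                # conformer holds essentially all mass; x-grid still valid
                rest = 1e-12
            # ensemble averages as linear functions of x
            logL = np.zeros_like(x)
            if has_nu:
                base = (S_nu - a * nu[j]) / rest
                lin = base + (nu[j] - base) * x
                logL -= (lin - obs.scaling.value) ** 2 / (2.0 * obs.scaling.eps**2)
            if K:
                baseA = (A - a * P[j]) / rest
                linA = baseA[None, :] + (P[j] - baseA)[None, :] * x[:, None]
                logL -= np.sum((linA - m_cs[None, :]) ** 2 / (2.0 * var_cs[None, :]), axis=1)
            lp = log_prior[j] + logL
            lp -= lp.max()
            log_prior[j] = lp
            f = np.exp(lp)
            Z = float(tw @ f)
            b = float(tw @ (x * f)) / Z
            b = min(max(b, 0.0), 1.0 - 1e-9)
            c = (1.0 - b) / rest
            if has_nu:
                S_nu = b * nu[j] + c * (S_nu - a * nu[j])
            if K:
                A = b * P[j] + c * (A - a * P[j])
            G *= c
            v[j] = b / G
        # per-sweep renormalization guards against scale drift
        w = v * G
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        v, G = w, 1.0
        if has_nu:
            S_nu = float(w @ nu)
        if K:
            A = w @ P
        traj[it] = float(w @ nu)

    w = v * G
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    converged = False
    if iterations > convergence_window:
        window = traj[-convergence_window:]
        converged = float(np.ptp(window)) < convergence_tol
    ll = joint_loglik(obs, pool, w, shift_matrix=P if K else None)
    return WeightedEnsemble(pool, w, traj, ll, converged)


def select_top(ensemble: WeightedEnsemble, k: int = 160) -> WeightedEnsemble:
    """Keep the k most probable conformers (ties broken by index).

    Weights of the selected conformers are renormalized.
    """
    n = len(ensemble.pool)
    k = min(k, n)
    # stable sort on -weight -> ties resolved by conformer index
    order = np.argsort(-ensemble.weights, kind="stable")[:k]
    order = np.sort(order)
    w = ensemble.weights[order]
    w = w / w.sum() if w.sum() > 0 else np.full(k, 1.0 / k)
    return WeightedEnsemble(
        ensemble.pool.subset(order),
        w,
        ensemble.nu_trajectory,
        ensemble.loglik,
        ensemble.converged,
        status=f"top-{k} selection of a {n}-conformer refinement",
    )


def compare_ensembles(
    a: WeightedEnsemble,
    b: WeightedEnsemble,
    p_threshold: float = 0.05,
    exact_max: int = 25,
):
    """Two-sided rank-sum test on the final per-conformer weights.

    For small tie-free samples (both sizes <= ``exact_max``) the exact
    permutation null of the rank-sum statistic is used (via the
    equivalent Mann-Whitney U); larger or tied samples fall back to the
    normal approximation.  Returns (statistic, p_value, verdict):
    verdict is "degenerate" when p >= threshold, else the name of the
    higher-median ensemble ("A" or "B").
    """
    wa, wb = np.asarray(a.weights), np.asarray(b.weights)
    pooled = np.concatenate([wa, wb])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and wa.size <= exact_max and wb.size <= exact_max:
        from scipy.stats import mannwhitneyu

        res = mannwhitneyu(wa, wb, alternative="two-sided", method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = ranksums(wa, wb)
    if p >= p_threshold:
        verdict = "degenerate"
    else:
        verdict = "A" if np.median(wa) > np.median(wb) else "B"
    return float(stat), float(p), verdict
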