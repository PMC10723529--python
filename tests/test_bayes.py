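"""Bayesian ensemble refinement: likelihoods, updates, selection, comparison."""

import numpy as np
import pytest
from itertools import combinations

from mesokit.bayes import (
    ObservationSet,
    ScalingObservation,
    ShiftObservation,
    compare_ensembles,
    ensemble_average,
    joint_loglik,
    nu_loglik,
    pool_shift_matrix,
    refine,
    select_top,
    shift_loglik,
    WeightedEnsemble,
)


class NuPool:
    """Minimal pool stub carrying only per-conformer scaling factors."""

    def __init__(self, nu):
        self._nu = np.asarray(nu, float)
        self.conformers = [None] * len(self._nu)

    def __len__(self):
        return len(self._nu)

    @property
    def nu(self):
        return self._nu

    def subset(self, idx):
        return NuPool(self._nu[list(idx)])


class TestEnsembleAverage:
    def test_uniform_over_identical_values(self):
        assert ensemble_average([3.0, 3.0, 3.0], [1 / 3] * 3) == pytest.approx(3.0)

    def test_delta_weight_selects_one(self):
        assert ensemble_average([1.0, 2.0, 3.0], [0, 1, 0]) == 2.0

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=30)
        w = rng.dirichlet(np.ones(30))
        oracle = sum(wi * vi for wi, vi in zip(w, v))
        assert abs(ensemble_average(v, w) - oracle) < 1e-12

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([1.0, 2.0], [0.5, 0.6])


class TestLikelihoods:
    def test_shift_loglik_at_mode(self):
        obs = ShiftObservation(1, "CA", 50.0, eps=0.3, alpha=0.4)
        var = 0.3**2 + 0.4**2
        assert shift_loglik(obs, 50.0) == pytest.approx(-0.5 * np.log(2 * np.pi * var))

    def test_shift_loglik_one_sd_off(self):
        obs = ShiftObservation(1, "CA", 50.0, eps=0.3, alpha=0.4)
        sd = np.sqrt(0.3**2 + 0.4**2)
        assert shift_loglik(obs, 50.0 + sd) == pytest.approx(shift_loglik(obs, 50.0) - 0.5)

    def test_shift_density_matches_transcription(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            eps, alpha = rng.uniform(0.05, 1.0, 2)
            m, pred = rng.normal(50, 3, 2)
            obs = ShiftObservation(1, "CA", m, eps=eps, alpha=alpha)
            literal = (2 * np.pi * (eps**2 + alpha**2)) ** -0.5 * np.exp(
                -((m - pred) ** 2) / (2 * (eps**2 + alpha**2))
            )
            assert np.exp(shift_loglik(obs, pred)) == pytest.approx(literal, rel=1e-12)

    def test_nu_density_matches_transcription(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            eps = rng.uniform(0.01, 0.4)
            m, pred = rng.uniform(0.3, 0.9, 2)
            obs = ScalingObservation(m, eps)
            literal = (2 * np.pi * eps**2) ** -0.5 * np.exp(-((m - pred) ** 2) / (2 * eps**2))
            assert np.exp(nu_loglik(obs, pred)) == pytest.approx(literal, rel=1e-12)

    def test_joint_is_sum_of_terms(self):
        pool = NuPool([0.5, 0.6, 0.7])
        w = np.array([0.2, 0.3, 0.5])
        scaling = ScalingObservation(0.6, 0.05)
        only_nu = ObservationSet(scaling=scaling)
        assert joint_loglik(only_nu, pool, w) == pytest.approx(
            nu_loglik(scaling, ensemble_average(pool.nu, w))
        )

    def test_joint_matches_product_of_densities(self, coil_pool):
        sub = coil_pool.subset(range(4))
        obs = ObservationSet(
            shifts=[
                ShiftObservation(2, "CA", 53.0, eps=0.2),
                ShiftObservation(5, "CB", 40.0, eps=0.3),
            ],
            scaling=ScalingObservation(0.6, 0.05),
        )
        w = np.array([0.1, 0.2, 0.3, 0.4])
        mat = pool_shift_matrix(sub, obs.shifts)
        product = nu_loglik(obs.scaling, float(w @ sub.nu))
        for o, col in zip(obs.shifts, mat.T):
            product += shift_loglik(o, float(w @ col))
        assert joint_loglik(obs, sub, w) == pytest.approx(product, rel=1e-12)


def _grid_posterior_mean(nu_vals, shift_mat, obs, g=200):
    """Dense 2-simplex oracle: posterior-mean weights for 3 conformers
    under a uniform simplex prior and a single application of the joint
    likelihood (brute-force grid quadrature)."""
    w1 = np.linspace(0, 1, g + 1)
    W1, W2 = np.meshgrid(w1, w1, indexing="ij")
    mask = W1 + W2 <= 1.0
    W3 = np.clip(1.0 - W1 - W2, 0, 1)
    logL = np.zeros_like(W1)
    if obs.scaling is not None:
        avg = W1 * nu_vals[0] + W2 * nu_vals[1] + W3 * nu_vals[2]
        logL -= (avg - obs.scaling.value) ** 2 / (2 * obs.scaling.eps**2)
    for k, o in enumerate(obs.shifts):
        avg = W1 * shift_mat[0, k] + W2 * shift_mat[1, k] + W3 * shift_mat[2, k]
        logL -= (avg - o.value) ** 2 / (2 * o.variance)
    L = np.where(mask, np.exp(logL - logL[mask].max()), 0.0)
    Z = L.sum()
    return np.array([(W1 * L).sum(), (W2 * L).sum(), (W3 * L).sum()]) / Z


class ThreeConfPool(NuPool):
    def __init__(self, nu, shift_mat):
        super().__init__(nu)
        self.shift_mat = shift_mat


class TestRefine:
    def test_matching_conformer_takes_all_weight(self):
        pool = NuPool([0.66, 0.76])
        obs = ObservationSet(scaling=ScalingObservation(0.66, 0.01))
        ens = refine(pool, obs, iterations=200, seed=1)
        assert ens.weights[0] > 0.99
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_truth_keeps_uniform_weights(self):
        """Observations generated as the uniform-ensemble average leave
        the weights at 1/n (likelihood optimum in every update direction)."""
        rng = np.random.default_rng(4)
        nu = rng.uniform(0.5, 0.8, 50)
        pool = NuPool(nu)
        obs = ObservationSet(scaling=ScalingObservation(float(nu.mean()), 0.296))
        ens = refine(pool, obs, iterations=150, seed=2)
        assert np.max(np.abs(ens.weights - 1 / 50)) < 1e-3

    def test_three_conformer_simplex_grid_oracle(self):
        """Coordinate-update posterior agrees with the brute-force dense
        simplex-grid posterior mean on a 3-conformer pool."""
        nu = np.array([0.55, 0.66, 0.75])
        shift_mat = np.array([[52.0, 39.0], [54.5, 41.0], [53.0, 43.0]])
        truth = np.array([0.25, 0.45, 0.30])
        obs = ObservationSet(
            shifts=[
                ShiftObservation(1, "CA", float(truth @ shift_mat[:, 0]), eps=0.18, alpha=0.05),
                ShiftObservation(2, "CA", float(truth @ shift_mat[:, 1]), eps=0.18, alpha=0.05),
            ],
            scaling=ScalingObservation(float(truth @ nu), 0.05),
        )
        oracle = _grid_posterior_mean(nu, shift_mat, obs)
        pool = ThreeConfPool(nu, shift_mat)
        ens = refine(pool, obs, iterations=30, seed=0, shift_matrix=shift_mat)
        assert np.max(np.abs(ens.weights - oracle)) < 0.02

    def test_refined_loglik_beats_uniform(self):
        rng = np.random.default_rng(6)
        nu = rng.uniform(0.45, 0.85, 40)
        pool = NuPool(nu)
        obs = ObservationSet(scaling=ScalingObservation(0.70, 0.02))
        ens = refine(pool, obs, iterations=100, seed=3)
        uniform_ll = joint_loglik(obs, pool, np.full(40, 1 / 40))
        assert ens.loglik >= uniform_ll

    def test_planted_two_population_recovery(self):
        """With populations at nu ~ 0.5 and ~ 0.66 and an observation at
        the second population's mean, the refined average lands within
        2 eps_v of the observation."""
        rng = np.random.default_rng(7)
        nu = np.concatenate([rng.normal(0.5, 0.01, 30), rng.normal(0.66, 0.01, 30)])
        eps_v = 0.02
        obs = ObservationSet(scaling=ScalingObservation(0.66, eps_v))
        ens = refine(NuPool(nu), obs, iterations=300, seed=4)
        assert abs(ens.mean_nu - 0.66) < 2 * eps_v

    def test_degenerate_pool_returns_uniform_with_warning(self):
        pool = NuPool([0.6, 0.6, 0.6])
        obs = ObservationSet(scaling=ScalingObservation(0.66, 0.05))
        ens = refine(pool, obs, iterations=10, seed=0)
        assert np.allclose(ens.weights, 1 / 3)
        assert "degenerate" in ens.status

    def test_weights_normalized_after_refinement(self):
        rng = np.random.default_rng(9)
        pool = NuPool(rng.uniform(0.5, 0.8, 25))
        obs = ObservationSet(scaling=ScalingObservation(0.65, 0.05))
        ens = refine(pool, obs, iterations=50, seed=1)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(ens.weights >= 0)
        assert len(ens.nu_trajectory) == 50


class TestSelection:
    def _ensemble(self, weights):
        w = np.asarray(weights, float)
        pool = NuPool(np.linspace(0.5, 0.8, len(w)))
        return WeightedEnsemble(pool, w / w.sum(), np.zeros(1), 0.0, True)

    def test_default_top_k(self):
        import inspect

        assert inspect.signature(select_top).parameters["k"].default == 160

    def test_identity_when_k_equals_pool(self):
        ens = self._ensemble([0.1, 0.4, 0.5])
        top = select_top(ens, k=3)
        assert len(top.pool) == 3
        assert np.allclose(top.weights, ens.weights)

    def test_selects_k_largest_against_sort_oracle(self):
        rng = np.random.default_rng(11)
        w = rng.dirichlet(np.ones(30))
        ens = self._ensemble(w)
        top = select_top(ens, k=10)
        oracle = np.sort(np.argsort(-w)[:10])
        kept_nu = top.pool.nu
        assert np.allclose(kept_nu, ens.pool.nu[oracle])
        assert top.weights.sum() == pytest.approx(1.0)


class TestEnsembleComparison:
    def _ens(self, weights):
        w = np.asarray(weights, float)
        return WeightedEnsemble(NuPool(np.ones(len(w)) * 0.6), w / w.sum(), np.zeros(1), 0.0, True)

    def test_self_comparison_is_degenerate(self):
        a = self._ens(np.linspace(1, 2, 20))
        stat, p, verdict = compare_ensembles(a, a)
        assert p == pytest.approx(1.0)
        assert verdict == "degenerate"

    def test_disjoint_distributions_decide_winner(self):
        # a compact 12-conformer ensemble vs a diffuse 120-conformer one:
        # every weight of A exceeds every weight of B
        a = self._ens(np.linspace(1.0, 1.1, 12))
        b = self._ens(np.linspace(1.0, 1.1, 120))
        assert a.weights.min() > b.weights.max()
        stat, p, verdict = compare_ensembles(a, b)
        assert p < 1e-4
        assert verdict == "A"

    def test_against_exhaustive_permutation_oracle(self):
        """Rank-sum p-value agrees with full permutation enumeration at n=6+6."""
        a_raw = np.array([0.30, 0.18, 0.12, 0.10, 0.08, 0.22])
        b_raw = np.array([0.21, 0.15, 0.11, 0.09, 0.25, 0.19])
        a, b = a_raw / a_raw.sum(), b_raw / b_raw.sum()
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1.0
        observed = ranks[:6].sum()
        total = 0
        extreme = 0
        mean_w = ranks.sum() * 6 / 12
        for idx in combinations(range(12), 6):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
                extreme += 1
        p_oracle = extreme / total
        ens_a, ens_b = self._ens(a_raw), self._ens(b_raw)
        stat, p, verdict = compare_ensembles(ens_a, ens_b)
        assert p == pytest.approx(p_oracle, abs=0.01)
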