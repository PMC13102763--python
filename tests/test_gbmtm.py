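"""Mixture-model correctness: EM ascent, diagnostics formulas, selection,
order elimination, and recovery of a known latent structure."""

import numpy as np
import pytest

from traj2targets import gbmtm
from traj2targets.gbmtm import (
    TrajectoryModelSpec,
    assign,
    avepp,
    backward_eliminate_orders,
    count_params,
    diagnostics,
    fit_em,
    information_criteria,
    observed_loglik,
    occ,
    permutation_accuracy,
    relative_entropy,
    select_num_groups,
)


def _random_grids(rng, n=25, v=2, t=12, groups=None):
    if groups is None:
        return rng.normal(size=(n, v, t))
    Y = np.empty((n, v, t))
    h = np.arange(t) - gbmtm.TIME_CENTER
    labels = rng.integers(0, len(groups), n)
    for i in range(n):
        for ch in range(v):
            Y[i, ch] = np.polyval(groups[labels[i]][ch][::-1], h) + rng.normal(0, 0.5, t)
    return Y, labels + 1


class TestEM:
    def test_k1_equals_pooled_ols(self):
        rng = np.random.default_rng(0)
        Y = _random_grids(rng, n=40, v=3)
        fit = fit_em(Y, TrajectoryModelSpec(K=1, orders=3, seed=1))
        assert fit.pi[0] == pytest.approx(1.0)
        h = np.arange(12) - gbmtm.TIME_CENTER
        X = np.vander(h, 4, increasing=True)
        for v in range(3):
            pooled = Y[:, v, :].mean(axis=0)
            beta_ols = np.linalg.lstsq(X, pooled, rcond=None)[0]
            assert np.allclose(fit.beta[0][v], beta_ols, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_loglik_trace_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        Y = _random_grids(rng, n=20, v=2)
        K = int(rng.integers(1, 4))
        fit = fit_em(Y, TrajectoryModelSpec(K=K, orders=2, seed=seed, max_iter=60))
        assert (np.diff(fit.trace) > -1e-8).all()

    def test_posterior_rows_sum_to_one(self, fit600):
        assert np.abs(fit600.W.sum(axis=1) - 1.0).max() < 1e-10
        assert fit600.pi.sum() == pytest.approx(1.0)
        assert (fit600.sigma > 0).all()

    def test_too_few_subjects_rejected(self):
        Y = np.zeros((2, 1, 12))
        with pytest.raises(gbmtm.InputError):
            fit_em(Y, TrajectoryModelSpec(K=3))

    def test_em_beats_random_parameter_draws(self):
        """Brute-force sanity oracle: on a tiny problem the EM solution's
        observed-data likelihood dominates 1,000 random parameter draws."""
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(6, 1, 12))
        Y[:3] += 2.0
        fit = fit_em(Y, TrajectoryModelSpec(K=2, orders=1, n_starts=3, seed=0))
        best_random = -np.inf
        for _ in range(1000):
            pi1 = rng.uniform(0.05, 0.95)
            beta = [[rng.normal(0, 2, 2)], [rng.normal(0, 2, 2)]]
            sigma = rng.uniform(0.2, 3.0, (2, 1))
            ll = observed_loglik(Y, np.array([pi1, 1 - pi1]), beta, sigma)
            best_random = max(best_random, ll)
        assert fit.loglik >= best_random

    def test_label_switching_invariance(self, preprocessed600, fit600):
        """Permuting group indices leaves loglik, entropy and criteria unchanged."""
        perm = [2, 0, 1]
        Y = preprocessed600["result"].grids.values
        ll_perm = observed_loglik(
            Y,
            fit600.pi[perm],
            [fit600.beta[g] for g in perm],
            fit600.sigma[perm],
        )
        assert ll_perm == pytest.approx(fit600.loglik, abs=1e-6)
        assert relative_entropy(fit600.W[:, perm]) == pytest.approx(
            relative_entropy(fit600.W), abs=1e-12
        )


class TestCountsAndCriteria:
    @pytest.mark.parametrize(
        "K,V,order,expected",
        [(1, 6, 3, 30), (3, 6, 3, 92), (2, 1, 1, 7)],
    )
    def test_free_parameter_count(self, K, V, order, expected):
        orders = np.full((K, V), order)
        assert count_params(K, orders) == expected

    def test_information_criteria_values(self):
        bic, aic = information_criteria(-100.0, 10, 50)
        assert aic == pytest.approx(220.0)
        assert bic == pytest.approx(200.0 + 10 * np.log(50))

    def test_zero_params_degenerate(self):
        bic, aic = information_criteria(-5.0, 0, 10)
        assert bic == aic == 10.0

    def test_bic_exceeds_aic_for_n_at_least_8(self):
        bic, aic = information_criteria(-50.0, 4, 8)
        assert bic > aic


class TestEntropy:
    def test_one_hot_is_one(self):
        W = np.eye(3)[np.array([0, 1, 2, 0])]
        assert relative_entropy(W) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        W = np.full((5, 4), 0.25)
        assert relative_entropy(W) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        W = np.array([[0.8, 0.2], [0.6, 0.4]])
        assert relative_entropy(W) == pytest.approx(0.1536, abs=5e-5)

    def test_k1_convention(self):
        assert relative_entropy(np.ones((4, 1))) == 1.0

    def test_bad_rows_rejected(self):
        with pytest.raises(gbmtm.InputError):
            relative_entropy(np.array([[0.5, 0.4]]))


class TestAveppOcc:
    def test_one_hot_avepp_is_one(self):
        W = np.eye(2)[np.array([0, 1, 0])]
        assert np.allclose(avepp(W, assign(W)), 1.0)

    def test_arithmetic_mean(self):
        W = np.array([[0.9, 0.1], [0.7, 0.3], [0.2, 0.8]])
        ap = avepp(W, assign(W))
        assert ap[0] == pytest.approx(0.8)

    def test_modal_bound(self):
        rng = np.random.default_rng(4)
        W = rng.dirichlet(np.ones(3), size=50)
        ap = avepp(W, assign(W))
        assert np.nanmin(ap) >= 1 / 3

    def test_occ_values(self):
        assert occ(0.3, 0.3) == pytest.approx(1.0)
        assert occ(0.9, 0.3) == pytest.approx(21.0)
        assert occ(1.0, 0.3) == np.inf

    def test_occ_input_validation(self):
        with pytest.raises(gbmtm.InputError):
            occ(0.9, 1.0)
        with pytest.raises(gbmtm.InputError):
            occ(0.0, 0.5)


class TestAssign:
    def test_modal_and_tie_rule(self):
        W = np.array([[0.2, 0.5, 0.3], [0.5, 0.5, 0.0]])
        labels = assign(W)
        assert labels[0] == 2
        assert labels[1] == 1  # exact tie -> lowest index


class TestRecovery:
    def test_default_scenario_recovery(self, preprocessed600, fit600):
        labels = assign(fit600.W)
        acc = permutation_accuracy(preprocessed600["true_labels"], labels)
        assert acc >= 0.95
        assert np.allclose(np.sort(fit600.pi), np.sort([0.24, 0.35, 0.41]), atol=0.05)
        d = diagnostics(fit600)
        assert d.entropy > 0.7
        assert np.nanmin(d.avepp) > 0.7
        assert np.nanmin(d.occ) > 5
        assert d.group_sizes.min() >= 0.05

    def test_group_curves_match_truth(self, scenario600, preprocessed600, fit600):
        """Inverse-standardized fitted curves within 0.25 channel-SD of the
        generating polynomials at every hour."""
        from traj2targets.config import CHANNELS

        cfg = scenario600["config"]
        params = preprocessed600["result"].params
        labels = assign(fit600.W)
        true = preprocessed600["true_labels"]
        # align fitted groups to truth by majority vote
        mapping = {}
        for g in range(3):
            members = labels == g + 1
            mapping[g] = np.bincount(true[members]).argmax() - 1
        hours = np.arange(12)
        for g in range(3):
            tg = mapping[g]
            for ci, ch in enumerate(CHANNELS):
                fitted = params.inverse(fit600.group_curve(g, ci, hours), ci)
                truth_curve = cfg.mean_trajectory(tg, ch, hours)
                tol = 0.25 * cfg.noise_sd[tg, ci]
                assert np.abs(fitted - truth_curve).max() < max(tol, 0.25)


class TestSelection:
    def test_selection_rule_predicate(self):
        d = gbmtm.FitDiagnostics(
            bic=0.0,
            aic=0.0,
            entropy=0.96,
            group_sizes=np.array([0.2399, 0.3536, 0.4065]),
            avepp=np.array([0.9, 0.9, 0.9]),
            occ=np.array([10.0, 10.0, 10.0]),
        )
        assert d.eligible()
        d2 = gbmtm.FitDiagnostics(
            bic=0.0, aic=0.0, entropy=0.6,
            group_sizes=np.array([0.5, 0.5]),
            avepp=np.array([0.8, 0.8]), occ=np.array([6.0, 6.0]),
        )
        assert not d2.eligible()

    def test_single_population_prefers_k1(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Y = 0.2 * rng.normal(size=(80, 2, 12))
            _, chosen, _ = select_num_groups(
                Y, k_range=(1, 3),
                template=TrajectoryModelSpec(K=1, seed=seed, n_starts=1, max_iter=80),
            )
            hits += chosen == 1
        assert hits >= 4

    def test_three_groups_chosen_on_separated_data(self, preprocessed600):
        table, chosen, _ = select_num_groups(
            preprocessed600["result"].grids,
            k_range=(1, 4),
            template=TrajectoryModelSpec(K=1, seed=5, n_starts=2),
        )
        assert chosen == 3
        assert set(table.columns) >= {"K", "bic", "entropy", "min_share", "eligible"}


class TestBackwardElimination:
    def test_linear_truth_prunes_to_order_one(self):
        """Pruning at test level 0.01: per-slot spurious retention is ~2%,
        so nearly every slot must come back linear."""
        slots_linear, slots_total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            groups = [
                [np.array([-1.0, 0.3, 0.0, 0.0]), np.array([0.5, -0.2, 0.0, 0.0])],
                [np.array([2.0, -0.3, 0.0, 0.0]), np.array([-2.0, 0.25, 0.0, 0.0])],
            ]
            Y, _ = _random_grids(rng, n=150, v=2, groups=groups)
            spec, fit = backward_eliminate_orders(
                Y, K=2, alpha=0.01,
                template=TrajectoryModelSpec(K=2, seed=seed, n_starts=1),
            )
            slots_linear += (fit.orders == 1).sum()
            slots_total += fit.orders.size
        assert slots_linear / slots_total >= 0.9

    def test_strong_cubic_retained(self):
        rng = np.random.default_rng(9)
        groups = [
            [np.array([0.0, 0.1, 0.0, 0.02])],
            [np.array([3.0, -0.1, 0.0, -0.02])],
        ]
        Y, _ = _random_grids(rng, n=200, v=1, groups=groups)
        _, fit = backward_eliminate_orders(
            Y, K=2, template=TrajectoryModelSpec(K=2, seed=1, n_starts=1)
        )
        assert (fit.orders == 3).all()

    def test_orders_never_below_one(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(60, 2, 12))  # pure noise: everything insignificant
        _, fit = backward_eliminate_orders(
            Y, K=2, template=TrajectoryModelSpec(K=2, seed=2, n_starts=1)
        )
        assert (fit.orders >= 1).all()
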