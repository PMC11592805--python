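"""Adaptive budget allocation and the private skeleton loop."""

import math

import numpy as np
import pytest

from conftest import reference_pc_skeleton
from curate.ci_tests import KendallTauStatistic
from curate.curate_constraint import (
    BudgetExhaustedError,
    BudgetPlan,
    ConstraintConfig,
    dp_ci_decision,
    error_bound_q,
    opt_allocate,
    run_curate_constraint,
    run_skeleton,
    surrogate_objective,
    uniform_feasible_epsilon,
    _leakage,
)
from curate.curate_constraint import test_count_bound as count_bound
from curate.dp_mechanisms import PrivacyParams
from curate.synthetic_data import forward_sample, random_cpts, random_dag


def make_cfg(eps_total=1.0, **kw):
    return ConstraintConfig(privacy=PrivacyParams(eps_total=eps_total), **kw)


class TestTestCountBound:
    @pytest.mark.parametrize(
        "e,i,d,expected",
        [(0, 1, 6, 0), (28, 0, 8, 28), (10, 2, 8, 150)],
    )
    def test_values(self, e, i, d, expected):
        assert count_bound(e, i, d) == expected

    def test_rejects_out_of_range_order(self):
        with pytest.raises(ValueError):
            count_bound(3, 7, 8)


class TestErrorBound:
    def test_zero_margin_gives_half_plus_half_c(self):
        assert error_bound_q(1.0, 0.05, 0.0, 0.01, 0.5) == pytest.approx(0.75)

    def test_noise_free_limit_is_half_c(self):
        assert error_bound_q(1e12, 0.05, 0.5, 0.01, 0.5) == pytest.approx(0.25)
        assert error_bound_q(1.0, 0.05, 0.5, 0.0, 0.5) == pytest.approx(0.25)

    def test_worked_value(self):
        q = error_bound_q(2.0, 0.05, 0.5, 0.01, 0.5)
        assert q == pytest.approx(0.25 + 0.5 * math.exp(-5), abs=1e-9)


class TestSurrogateObjective:
    def test_single_order_is_q1_plus_q2(self):
        cfg = make_cfg()
        delta1 = 0.01
        expected = error_bound_q(0.3, cfg.T, cfg.beta1, delta1, cfg.c1) + (
            error_bound_q(0.3, cfg.T, cfg.beta2, delta1, cfg.c2)
        )
        assert surrogate_objective(np.array([0.3]), cfg, delta1) == pytest.approx(
            expected
        )

    def test_noise_free_limit_form(self):
        cfg = make_cfg()
        m = 3
        val = surrogate_objective(np.full(m, 1e12), cfg, 0.01)
        c = 0.5
        assert val == pytest.approx((c / 2) ** m + 1 - (1 - c / 2) ** m, abs=1e-6)

    def test_rejects_empty_vector(self):
        with pytest.raises(ValueError):
            surrogate_objective(np.array([]), make_cfg(), 0.01)


class TestOptAllocate:
    def test_single_order_matches_quadratic_root(self):
        cfg = make_cfg(eps_total=2.0)
        d, i, e = 5, 3, 4  # final order: one epsilon remains
        plan = opt_allocate(2.0, e, i, cfg, 0.01, d)
        t = count_bound(e, i, d)
        ln_inv = math.log(1.0 / cfg.privacy.delta_prime)
        b = math.sqrt(2 * t * ln_inv)
        root = (-b + math.sqrt(b * b + 4 * t * 2.0)) / (2 * t)
        assert plan.eps_by_order.shape == (1,)
        assert plan.eps_by_order[0] == pytest.approx(root, abs=1e-6)

    def test_plan_feasible_and_monotone(self, rng):
        for _ in range(25):
            d = int(rng.integers(4, 9))
            i = int(rng.integers(0, d - 2))
            e = int(rng.integers(1, d * (d - 1) // 2 + 1))
            eps_remaining = float(rng.uniform(0.2, 20.0))
            cfg = make_cfg(eps_total=eps_remaining)
            plan = opt_allocate(eps_remaining, e, i, cfg, 0.005, d)
            eps = plan.eps_by_order
            assert np.all(eps >= cfg.eps_floor - 1e-12)
            assert np.all(np.diff(eps) <= 1e-12)
            assert plan.projected_leakage(cfg.privacy.delta_prime) <= (
                eps_remaining + 1e-9
            )

    def test_beats_uniform_baseline(self, rng):
        cfg = make_cfg(eps_total=2.0)
        plan = opt_allocate(2.0, 6, 0, cfg, 0.003, 5)
        t = plan.t_estimates
        ln_inv = math.log(1e12)
        a = t.sum()
        b = np.sqrt(2 * t * ln_inv).sum()
        root = (-b + math.sqrt(b * b + 4 * a * 2.0)) / (2 * a)
        uniform = np.full(len(t), root)
        assert surrogate_objective(plan.eps_by_order, cfg, 0.003) <= (
            surrogate_objective(uniform, cfg, 0.003) + 1e-12
        )

    def test_budget_exhaustion_signalled(self):
        cfg = make_cfg(eps_total=1.0, eps_floor=1e-4)
        with pytest.raises(BudgetExhaustedError):
            opt_allocate(1e-8, 10, 0, cfg, 0.01, 8)
        with pytest.raises(BudgetExhaustedError):
            opt_allocate(0.0, 10, 0, cfg, 0.01, 8)


class TestDpCiDecision:
    def test_delete_and_keep_regions(self, rng):
        cfg = make_cfg(beta1=0.2, beta2=0.2)
        assert dp_ci_decision(0.061, cfg, rng) == "delete"
        assert dp_ci_decision(0.039, cfg, rng) == "keep"

    def test_coin_region_is_fair(self):
        cfg = make_cfg(beta1=0.1, beta2=0.1)
        rng = np.random.default_rng(5)
        keeps = sum(
            dp_ci_decision(cfg.T, cfg, rng) == "keep" for _ in range(10**4)
        )
        assert keeps / 10**4 == pytest.approx(0.5, abs=0.02)


def _binary_network_data(seed, d=6, n=2000, degree=1.8):
    rng = np.random.default_rng(seed)
    dag = random_dag(d, degree, rng)
    bn = random_cpts(dag, [2] * d, concentration=0.5, rng=rng)
    return dag, forward_sample(bn, n, rng), rng


class TestRunSkeleton:
    def test_two_node_run_has_single_order0_test(self):
        _, data, rng = _binary_network_data(1, d=2, n=200, degree=1.0)
        cfg = make_cfg(eps_total=5.0)
        skel, ledger, _ = run_skeleton(data, cfg, rng)
        assert len(ledger.entries) == 1
        assert ledger.entries[0].t == 1
        assert ledger.entries[0].label == "order-0"

    def test_noise_free_limit_matches_reference_pc(self):
        """With per-test budgets >= 1e6 and zero margins the private
        skeleton equals the canonical PC run, edge for edge and sepset for
        sepset."""
        for seed in range(3):
            _, data, rng = _binary_network_data(seed)
            cfg = ConstraintConfig(
                privacy=PrivacyParams(eps_total=1e30),
                fixed_eps=1e9,
                beta1=0.0,
                beta2=0.0,
            )
            skel, _, _ = run_skeleton(data, cfg, rng)
            ref = reference_pc_skeleton(data, cfg.statistic, T=cfg.T)
            assert skel.edges() == ref.edges()
            assert skel.sepsets == ref.sepsets

    def test_budget_never_exceeded_and_plans_monotone(self, rng):
        for _ in range(10):
            d = int(rng.integers(4, 8))
            n = int(rng.integers(300, 2000))
            seed = int(rng.integers(0, 2**31))
            _, data, run_rng = _binary_network_data(seed, d=d, n=n)
            eps_total = float(rng.uniform(0.5, 10))
            cfg = make_cfg(eps_total=eps_total)
            _, ledger, history = run_skeleton(data, cfg, run_rng)
            assert ledger.spent_eps <= eps_total + 1e-9
            for plan in history:
                assert np.all(np.diff(plan.eps_by_order) <= 1e-12)

    def test_uniform_mode_uses_shared_epsilon(self):
        _, data, rng = _binary_network_data(2)
        cfg = make_cfg(eps_total=1.0, uniform=True)
        _, ledger, history = run_skeleton(data, cfg, rng)
        eps_values = {e.eps_each for e in ledger.entries}
        assert len(eps_values) == 1
        expected = uniform_feasible_epsilon(1.0, data.d, cfg.privacy.delta_prime)
        assert eps_values.pop() == pytest.approx(expected)
        assert ledger.spent_eps <= 1.0 + 1e-9


class TestFullConstraintRun:
    def test_orientation_spends_no_budget(self):
        _, data, rng = _binary_network_data(3)
        cfg = make_cfg(eps_total=2.0)
        rng2 = np.random.default_rng(99)
        skel, ledger_skel, _ = run_skeleton(data, cfg, rng2)
        rng3 = np.random.default_rng(99)
        _, ledger_full = run_curate_constraint(data, cfg, rng3)
        assert ledger_full.spent_eps == ledger_skel.spent_eps
        assert len(ledger_full.entries) == len(ledger_skel.entries)

    def test_collider_recovered_in_noise_free_limit(self):
        rng = np.random.default_rng(2)
        n = 5000
        a = rng.integers(0, 2, n)
        c = rng.integers(0, 2, n)
        b = ((a | c) ^ (rng.random(n) < 0.05)).astype(int)
        from curate.ci_tests import Dataset
        from curate.graph_core import VariableMeta

        data = Dataset(
            np.column_stack([a, b, c]), VariableMeta.discrete("abc", (2, 2, 2))
        )
        cfg = ConstraintConfig(
            privacy=PrivacyParams(eps_total=1e30),
            fixed_eps=1e9,
            beta1=0.0,
            beta2=0.0,
        )
        cpdag, _ = run_curate_constraint(data, cfg, rng)
        assert (0, 1) in cpdag.directed and (2, 1) in cpdag.directed

    def test_independent_pair_yields_empty_graph(self):
        rng = np.random.default_rng(11)
        from curate.ci_tests import Dataset
        from curate.graph_core import VariableMeta

        data = Dataset(
            rng.integers(0, 2, size=(5000, 2)),
            VariableMeta.discrete(("u", "v"), (2, 2)),
        )
        cfg = ConstraintConfig(
            privacy=PrivacyParams(eps_total=1e30),
            fixed_eps=1e9,
            beta1=0.0,
            beta2=0.0,
        )
        cpdag, _ = run_curate_constraint(data, cfg, rng)
        assert cpdag.directed == set() and cpdag.undirected == set()


def test_lemma1_bound_holds_at_worst_case_boundary():
    """Monte-Carlo check of the relative type-I/II error bounds with the
    true statistic at the threshold, on cells where the coin-region mass
    is absorbed by the slack constant."""
    T, delta1 = 0.05, 0.01
    rng = np.random.default_rng(12)
    n_draws = 10**4
    for eps in (0.25, 0.5, 1.0):
        for beta in (0.05, 0.1):
            cfg = ConstraintConfig(
                privacy=PrivacyParams(eps_total=1.0), T=T, beta1=beta, beta2=beta
            )
            noise = rng.laplace(0.0, delta1 / eps, size=n_draws)
            f_hat = T + noise
            keeps = np.where(
                f_hat < T * (1 - beta),
                True,
                np.where(
                    f_hat > T * (1 + beta), False, rng.random(n_draws) < 0.5
                ),
            )
            rate_I = keeps.mean()  # edge kept although the clean test deletes
            rate_II = 1 - rate_I
            q1 = error_bound_q(eps, T, beta, delta1, cfg.c1)
            q2 = error_bound_q(eps, T, beta, delta1, cfg.c2)
            se = math.sqrt(0.25 / n_draws)
            assert rate_I <= q1 + 3 * se
            assert rate_II <= q2 + 3 * se


def test_leakage_helper_matches_manual_sum():
    eps = np.array([0.2, 0.1])
    t = np.array([3.0, 5.0])
    ln_inv = math.log(1e12)
    manual = (
        3 * 0.04 + 0.2 * math.sqrt(6 * ln_inv) + 5 * 0.01 + 0.1 * math.sqrt(10 * ln_inv)
    )
    assert _leakage(eps, t, 1e-12) == pytest.approx(manual)
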