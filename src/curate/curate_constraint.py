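"""Constraint-based learner with adaptive per-order privacy budgets.

The skeleton phase runs PC-style order-increasing conditional-independence
tests, each privatized with Laplace noise.  Before each order ``i`` the
remaining total budget ``ε_Total(i)`` is split across the future orders
``i … d-2`` by minimizing a surrogate error probability — the product
bound on relative type-I errors plus the complement-product bound on
relative type-II errors — subject to the composed-leakage constraint
(advanced composition within an order, basic composition across orders)
and monotonically nonincreasing per-order budgets.  Only the order about
to run is executed with its allocated budget; the optimizer re-solves at
the next order with the observed edge count, so projections of future
test counts are self-correcting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .ci_tests import CiStatistic, Dataset, KendallTauStatistic
from .dp_mechanisms import (
    AccountantLedger,
    PrivacyParams,
    advanced_composition,
    laplace_perturb,
)
from .graph_core import Cpdag, Skeleton, complete_skeleton, orient_cpdag

__all__ = [
    "ConstraintConfig",
    "BudgetPlan",
    "BudgetExhaustedError",
    "test_count_bound",
    "error_bound_q",
    "surrogate_objective",
    "uniform_feasible_epsilon",
    "opt_allocate",
    "dp_ci_decision",
    "run_skeleton",
    "run_curate_constraint",
]


class BudgetExhaustedError(RuntimeError):
    """No feasible per-test budget remains above the floor."""


@dataclass
class ConstraintConfig:
    """Knobs of the private skeleton phase.

    T
        independence-scale test threshold (an edge is deleted when the
        noisy statistic exceeds it); 0.05 by default.
    beta1, beta2
        keep/delete margins around T: the decision is randomized only in
        the band ``[T(1-β1), T(1+β2)]``.
    c1, c2
        slack constants of the error bounds, in (0, 1); they absorb the
        coin-region contribution.
    eps_floor
        minimum per-test budget the optimizer may assign to any order.
    fixed_eps
        bypass the optimizer and run every test at this budget (used for
        the noise-free limit and for external schedules).
    uniform
        uniform-budget ablation: one shared ε for all orders solving the
        total-leakage equation with worst-case test-count bounds.
    """

    privacy: PrivacyParams
    T: float = 0.05
    beta1: float = 0.1
    beta2: float = 0.1
    c1: float = 0.5
    c2: float = 0.5
    statistic: CiStatistic = field(default_factory=KendallTauStatistic)
    eps_floor: float = 1e-4
    max_order: int | None = None
    fixed_eps: float | None = None
    uniform: bool = False
    slsqp_max_iter: int = 500

    def __post_init__(self) -> None:
        if not (0 < self.T < 1):
            raise ValueError("T must be in (0, 1)")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("margins must be nonnegative")
        if self.T * (1 + self.beta2) >= 1:
            raise ValueError("T(1+beta2) must stay below 1")
        if not (0 < self.c1 < 1 and 0 < self.c2 < 1):
            raise ValueError("c1, c2 must lie in (0, 1)")
        if self.eps_floor <= 0:
            raise ValueError("eps_floor must be positive")


@dataclass
class BudgetPlan:
    """Per-order budgets chosen at the start of order ``order_index``."""

    order_index: int
    eps_by_order: np.ndarray  # (ε_i, …, ε_{d-2})
    t_estimates: np.ndarray
    eps_remaining: float
    fallback: bool = False

    def projected_leakage(self, delta_prime: float) -> float:
        return _leakage(self.eps_by_order, self.t_estimates, delta_prime)


def test_count_bound(e_i: int, i: int, d: int) -> int:
    """Upper bound ``e_i · C(d-2, i)`` on the number of order-``i`` tests
    given ``e_i`` surviving edges."""
    if not (0 <= i <= d - 2):
        raise ValueError(f"order {i} out of range for d={d}")
    if e_i < 0:
        raise ValueError("edge count must be nonnegative")
    return e_i * math.comb(d - 2, i)


def error_bound_q(eps: float, T: float, beta: float, delta1: float, c: float) -> float:
    """Relative-error bound ``c/2 + (1/2) exp(-T β ε / Δ)`` of one noisy
    CI decision.  Zero sensitivity is the noise-free limit ``c/2``."""
    if eps <= 0 or T <= 0 or c <= 0:
        raise ValueError("eps, T, c must be positive")
    if beta < 0 or delta1 < 0:
        raise ValueError("beta and delta1 must be nonnegative")
    if delta1 == 0:
        return c / 2.0
    return c / 2.0 + 0.5 * math.exp(-T * beta * eps / delta1)


def surrogate_objective(
    eps_vec: np.ndarray, cfg: ConstraintConfig, delta1: float
) -> float:
    """Surrogate error probability ``Π q^(1) + 1 - Π (1 - q^(2))`` of a
    per-order budget vector."""
    eps_vec = np.asarray(eps_vec, dtype=float)
    if eps_vec.size == 0:
        raise ValueError("empty budget vector")
    q1 = [error_bound_q(e, cfg.T, cfg.beta1, delta1, cfg.c1) for e in eps_vec]
    q2 = [error_bound_q(e, cfg.T, cfg.beta2, delta1, cfg.c2) for e in eps_vec]
    return float(np.prod(q1) + 1.0 - np.prod([1.0 - q for q in q2]))


def _leakage(eps_vec: np.ndarray, t_vec: np.ndarray, delta_prime: float) -> float:
    """Basic-across, advanced-within composed leakage of a budget plan."""
    ln_inv = math.log(1.0 / delta_prime)
    eps_vec = np.asarray(eps_vec, dtype=float)
    t_vec = np.asarray(t_vec, dtype=float)
    return float(
        np.sum(t_vec * eps_vec**2 + eps_vec * np.sqrt(2.0 * t_vec * ln_inv))
    )


def _uniform_root(t_vec: np.ndarray, budget: float, delta_prime: float) -> float:
    """Single shared ε saturating the total-leakage equation: the positive
    root of ``(Σ t_j) ε² + (Σ sqrt(2 t_j ln 1/δ′)) ε = budget``."""
    ln_inv = math.log(1.0 / delta_prime)
    a = float(np.sum(t_vec))
    b = float(np.sum(np.sqrt(2.0 * np.asarray(t_vec, float) * ln_inv)))
    if a <= 0:
        raise ValueError("need at least one projected test")
    return (-b + math.sqrt(b * b + 4.0 * a * budget)) / (2.0 * a)


def uniform_feasible_epsilon(
    eps_total: float, d: int, delta_prime: float, e0: int | None = None
) -> float:
    """Shared per-test budget of the uniform ablation: one ε for all
    orders, sized against the worst-case test-count bounds of the complete
    graph."""
    if e0 is None:
        e0 = math.comb(d, 2)
    t = np.array([test_count_bound(e0, j, d) for j in range(d - 1)], dtype=float)
    return _uniform_root(t, eps_total, delta_prime)


def opt_allocate(
    eps_remaining: float,
    e_i: int,
    i: int,
    cfg: ConstraintConfig,
    delta1: float,
    d: int,
) -> BudgetPlan:
    """Minimize the surrogate error over the future per-order budgets
    ``(ε_i, …, ε_{d-2})``.

    Constraints: composed leakage of the plan stays within
    ``eps_remaining``; budgets are nonincreasing in the order and at least
    ``eps_floor``.  Unseen future edge counts are projected as the current
    ``e_i``.  Solved with SLSQP from the uniform feasible point; on solver
    failure the uniform plan is returned, flagged.
    """
    if eps_remaining <= 0:
        raise BudgetExhaustedError("no budget remains")
    if e_i < 1:
        raise ValueError("need at least one edge")
    orders = np.arange(i, d - 1)
    t_vec = np.array([test_count_bound(e_i, j, d) for j in orders], dtype=float)
    root = _uniform_root(t_vec, eps_remaining, cfg.privacy.delta_prime)
    if root < cfg.eps_floor:
        raise BudgetExhaustedError(
            f"uniform feasible budget {root:.3g} below floor {cfg.eps_floor:.3g}"
        )
    m = len(orders)
    x0 = np.full(m, root)
    if m == 1:
        return BudgetPlan(i, x0, t_vec, eps_remaining)

    dp = cfg.privacy.delta_prime
    cons = [
        {
            "type": "ineq",
            "fun": lambda x: eps_remaining - _leakage(x, t_vec, dp),
        }
    ]
    for j in range(m - 1):
        cons.append({"type": "ineq", "fun": lambda x, j=j: x[j] - x[j + 1]})
    res = minimize(
        surrogate_objective,
        x0,
        args=(cfg, delta1),
        method="SLSQP",
        bounds=[(cfg.eps_floor, None)] * m,
        constraints=cons,
        options={"maxiter": cfg.slsqp_max_iter, "ftol": 1e-12},
    )
    eps = np.asarray(res.x, dtype=float)
    # repair tiny numerical violations before accepting the solve
    eps = np.maximum(eps, cfg.eps_floor)
    eps = np.minimum.accumulate(eps)
    ok = res.success and _leakage(eps, t_vec, dp) <= eps_remaining + 1e-9
    if ok and surrogate_objective(eps, cfg, delta1) <= surrogate_objective(
        x0, cfg, delta1
    ) + 1e-12:
        return BudgetPlan(i, eps, t_vec, eps_remaining)
    return BudgetPlan(i, x0, t_vec, eps_remaining, fallback=True)


def dp_ci_decision(
    f_noisy: float, cfg: ConstraintConfig, rng: np.random.Generator
) -> str:
    """Margin-based decision on a noisy independence score.

    Delete above ``T(1+β2)``, keep below ``T(1-β1)``, fair coin in the
    band between.
    """
    if f_noisy > cfg.T * (1.0 + cfg.beta2):
        return "delete"
    if f_noisy < cfg.T * (1.0 - cfg.beta1):
        return "keep"
    return "keep" if rng.random() < 0.5 else "delete"


def run_skeleton(
    D: Dataset,
    cfg: ConstraintConfig,
    rng: np.random.Generator,
    seed: int | None = None,
) -> tuple[Skeleton, AccountantLedger, list[BudgetPlan]]:
    """Private PC-style skeleton phase with adaptive per-order budgets.

    For each order ``i`` the budget optimizer is re-solved on the current
    edge count, every surviving ordered pair is tested against each
    size-``i`` subset of ``Adj(a) \\ {b}`` (lexicographic), and a pair is
    removed — with its separation set recorded — at its first delete
    decision.  The ledger is charged with the number of tests actually
    performed; untestable pairs (no usable stratum) keep their edge and
    cost nothing.
    """
    d = D.d
    skel = complete_skeleton(d)
    ledger = AccountantLedger(cfg.privacy, seed=seed)
    delta1 = cfg.statistic.sensitivity(D.n)
    delta_test = cfg.privacy.delta_test
    history: list[BudgetPlan] = []
    max_order = d - 2 if cfg.max_order is None else min(cfg.max_order, d - 2)
    uniform_eps: float | None = None

    for i in range(max_order + 1):
        e_i = skel.n_edges
        if e_i == 0:
            break
        testable = any(
            len(skel.neighbors(a) - {b}) >= i
            for a in range(d)
            for b in skel.neighbors(a)
        )
        if not testable:
            break

        if cfg.fixed_eps is not None:
            eps_i = cfg.fixed_eps
            plan = BudgetPlan(
                i,
                np.full(d - 1 - i, eps_i),
                np.array(
                    [test_count_bound(e_i, j, d) for j in range(i, d - 1)], float
                ),
                ledger.remaining_eps,
            )
        elif cfg.uniform:
            if uniform_eps is None:
                uniform_eps = uniform_feasible_epsilon(
                    cfg.privacy.eps_total, d, cfg.privacy.delta_prime
                )
            eps_i = uniform_eps
            plan = BudgetPlan(
                i,
                np.full(d - 1 - i, eps_i),
                np.array(
                    [test_count_bound(e_i, j, d) for j in range(i, d - 1)], float
                ),
                ledger.remaining_eps,
            )
        else:
            try:
                plan = opt_allocate(ledger.remaining_eps, e_i, i, cfg, delta1, d)
            except BudgetExhaustedError:
                ledger.flag(f"budget exhausted before order {i}")
                break
            eps_i = float(plan.eps_by_order[0])
        history.append(plan)

        tests = 0
        truncated = False
        for a in range(d):
            if truncated:
                break
            for b in sorted(skel.neighbors(a)):
                if truncated:
                    break
                nbrs = sorted(skel.neighbors(a) - {b})
                if len(nbrs) < i:
                    continue
                for S in combinations(nbrs, i):
                    if not skel.has_edge(a, b):
                        break
                    f, m_eff = cfg.statistic.evaluate(D, a, b, S)
                    if m_eff == 0:
                        ledger.flag(f"untestable pair {(a, b)} | {S} at order {i}")
                        continue
                    next_cost, _ = advanced_composition(
                        tests + 1, eps_i, delta_test, cfg.privacy.delta_prime
                    )
                    if next_cost > ledger.remaining_eps + 1e-9:
                        ledger.flag("truncated")
                        truncated = True
                        break
                    tests += 1
                    f_hat = laplace_perturb(f, delta1, eps_i, rng)
                    if dp_ci_decision(f_hat, cfg, rng) == "delete":
                        skel.remove_edge(a, b, S)
                        break
        if tests > 0:
            ledger.spend(f"order-{i}", tests, eps_i, delta_test, order=i)
        if truncated:
            break
    return skel, ledger, history


def run_curate_constraint(
    D: Dataset,
    cfg: ConstraintConfig,
    rng: np.random.Generator,
    seed: int | None = None,
) -> tuple[Cpdag, AccountantLedger]:
    """Full constraint-based run: private skeleton phase, then the
    (budget-free, postprocessing) orientation phase."""
    skel, ledger, _ = run_skeleton(D, cfg, rng, seed=seed)
    return orient_cpdag(skel), ledger
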