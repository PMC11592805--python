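"""Evaluation metrics and the privacy-utility experiment driver.

The headline metric is the F1-score of the recovered edge set against the
ground truth (precision ``|E∩E*|/|E|``, recall ``|E∩E*|/|E*|``), computed
on skeletons by default with a directed mode available.  The sweep driver
repeats simulate → learn → evaluate over a grid of total budgets and
seeds, mirroring the mean-and-standard-deviation protocol of
privacy-utility studies at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .curate_constraint import ConstraintConfig, run_skeleton
from .curate_score import ScoreConfig, run_curate_score
from .dp_mechanisms import AccountantLedger, PrivacyParams
from .graph_core import Cpdag, Skeleton
from .synthetic_data import (
    forward_sample,
    random_cpts,
    random_dag,
    random_linear_sem,
    sample_linear_sem,
)

__all__ = [
    "EvalReport",
    "skeleton_f1",
    "count_ci_tests",
    "privacy_utility_sweep",
]


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    shd: int
    n_ci_tests: int | None = None
    ledger_summary: dict | None = None


def _edge_set(graph, directed: bool) -> set[tuple[int, int]]:
    if isinstance(graph, Skeleton):
        edges = [(a, b) for a, b in graph.edges()]
        if directed:
            raise ValueError("a skeleton has no directed reading")
    elif isinstance(graph, Cpdag):
        if directed:
            # undirected CPDAG edges count as both orientations
            edges = list(graph.directed) + [
                e for a, b in graph.undirected for e in ((a, b), (b, a))
            ]
        else:
            edges = list(graph.skeleton_edges())
    elif isinstance(graph, nx.DiGraph):
        edges = list(graph.edges())
    elif isinstance(graph, nx.Graph):
        edges = list(graph.edges())
    else:
        edges = list(graph)
    if directed:
        return {(int(a), int(b)) for a, b in edges}
    return {tuple(sorted((int(a), int(b)))) for a, b in edges}


def skeleton_f1(
    G,
    Gstar,
    directed: bool = False,
    ledger: AccountantLedger | None = None,
) -> EvalReport:
    """Precision/recall/F1 of estimated vs true edges.

    Edges compare as unordered pairs unless ``directed=True``.
    Conventions: both edge sets empty → all metrics 1; estimated empty with
    nonempty truth → all 0.  SHD is the size of the symmetric difference.
    """
    E = _edge_set(G, directed)
    Estar = _edge_set(Gstar, directed)
    inter = len(E & Estar)
    shd = len(E ^ Estar)
    if not E and not Estar:
        p = r = f1 = 1.0
    else:
        p = inter / len(E) if E else 0.0
        r = inter / len(Estar) if Estar else 0.0
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    report = EvalReport(precision=p, recall=r, f1=f1, shd=shd)
    if ledger is not None:
        report.n_ci_tests = count_ci_tests(ledger)
        report.ledger_summary = {
            "spent_eps": ledger.spent_eps,
            "spent_delta": ledger.spent_delta,
            "eps_total": ledger.params.eps_total,
        }
    return report


def count_ci_tests(ledger: AccountantLedger) -> int:
    """Total CI tests charged to a constraint-path ledger (sum of actual
    per-order counts); on a score-path ledger this counts iterations."""
    return sum(e.t for e in ledger.entries)


def _one_constraint_run(d, n, eps_total, uniform, seed, expected_degree, delta_prime):
    rng = np.random.default_rng(seed)
    dag = random_dag(d, expected_degree, rng)
    bn = random_cpts(dag, [2] * d, concentration=0.5, rng=rng)
    data = forward_sample(bn, n, rng)
    cfg = ConstraintConfig(
        privacy=PrivacyParams(eps_total=eps_total, delta_prime=delta_prime),
        uniform=uniform,
    )
    skel, ledger, _ = run_skeleton(data, cfg, rng, seed=seed)
    rep = skeleton_f1(skel, dag, ledger=ledger)
    return rep, ledger


def _one_score_run(d, n, eps_total, seed, expected_degree, eps0):
    rng = np.random.default_rng(seed)
    sem = random_linear_sem(d, expected_degree, rng)
    data = sample_linear_sem(sem, n, rng)
    from .curate_score import BudgetSchedule

    cfg = ScoreConfig(
        privacy=PrivacyParams(eps_total=eps_total, delta_test=1e-9),
        schedule=BudgetSchedule(eps0=eps0),
    )
    dag_est, ledger = run_curate_score(data, cfg, rng, seed=seed)
    rep = skeleton_f1(dag_est, sem.dag, ledger=ledger)
    return rep, ledger


def privacy_utility_sweep(
    learner: str,
    eps_grid: Sequence[float],
    seeds: Iterable[int],
    d: int = 6,
    n: int = 2000,
    expected_degree: float = 1.8,
    uniform: bool = False,
    eps0: float = 0.1,
    delta_prime: float = 1e-12,
) -> pd.DataFrame:
    """Privacy-utility sweep: simulate → learn → evaluate per (ε, seed).

    Returns one row per total budget with the mean and standard deviation
    of F1, the mean CI-test (or iteration) count, and the mean spent
    leakage.  Failed runs are recorded in the ``failures`` column rather
    than silently dropped.
    """
    if learner not in ("constraint", "score"):
        raise ValueError("learner must be 'constraint' or 'score'")
    if len(eps_grid) == 0:
        raise ValueError("empty budget grid")
    seeds = list(seeds)
    rows = []
    for eps_total in eps_grid:
        f1s, tests, spent = [], [], []
        failures = 0
        for seed in seeds:
            try:
                if learner == "constraint":
                    rep, ledger = _one_constraint_run(
                        d, n, eps_total, uniform, seed, expected_degree, delta_prime
                    )
                else:
                    rep, ledger = _one_score_run(
                        d, n, eps_total, seed, expected_degree, eps0
                    )
            except Exception:
                failures += 1
                continue
            f1s.append(rep.f1)
            tests.append(rep.n_ci_tests)
            spent.append(ledger.spent_eps)
        rows.append(
            {
                "eps_total": eps_total,
                "learner": learner + ("-uniform" if uniform else ""),
                "seed_count": len(seeds),
                "f1_mean": float(np.mean(f1s)) if f1s else np.nan,
                "f1_sd": float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
                "ci_tests_mean": float(np.mean(tests)) if tests else np.nan,
                "eps_spent_mean": float(np.mean(spent)) if spent else np.nan,
                "failures": failures,
            }
        )
    return pd.DataFrame(rows)
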