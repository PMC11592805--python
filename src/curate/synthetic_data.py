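"""Generators for the study conditions both learners assume.

Discrete Bayesian networks with forward sampling feed the constraint-based
path; linear structural equation models (SEMs) feed the score-based path.
Scales mirror small public causal-discovery benchmarks (5-20 nodes,
binary-to-small-arity variables, edge density around 1-2 per node).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .ci_tests import Dataset
from .graph_core import VariableMeta

__all__ = [
    "BayesNet",
    "LinearSem",
    "random_dag",
    "random_cpts",
    "random_linear_sem",
    "forward_sample",
    "sample_linear_sem",
    "benchmark_suite",
]


@dataclass
class BayesNet:
    """Discrete Bayesian network: DAG + per-variable CPTs.

    ``cpts[v]`` has one row per joint parent configuration (parents in
    ascending index order, row index via ``np.ravel_multi_index``) and one
    column per level of ``v``; every row sums to one.
    """

    dag: nx.DiGraph
    arities: tuple[int, ...]
    cpts: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("structure must be acyclic")
        for v in self.dag.nodes:
            table = self.cpts[v]
            n_cfg = int(np.prod([self.arities[p] for p in self.parents(v)] or [1]))
            if table.shape != (n_cfg, self.arities[v]):
                raise ValueError(f"CPT shape mismatch at node {v}")
            if np.any(table < 0) or np.any(np.abs(table.sum(axis=1) - 1) > 1e-12):
                raise ValueError(f"CPT rows at node {v} must be distributions")

    @property
    def d(self) -> int:
        return self.dag.number_of_nodes()

    def parents(self, v: int) -> list[int]:
        return sorted(self.dag.predecessors(v))


@dataclass
class LinearSem:
    """Linear SEM ``F = Wᵀ F + Z`` with acyclic support.

    ``W_true[i, j]`` is the weight of edge i→j; nonzero weights are kept
    away from zero so pruning thresholds are meaningful.
    """

    W_true: np.ndarray
    noise_kind: str = "gaussian"
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        g = nx.DiGraph(np.abs(self.W_true) > 0)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("SEM support must be acyclic")
        if self.noise_kind not in ("gaussian", "uniform"):
            raise ValueError("noise_kind must be gaussian or uniform")

    @property
    def d(self) -> int:
        return self.W_true.shape[0]

    @property
    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.d))
        g.add_edges_from(zip(*np.nonzero(self.W_true)))
        return g


def random_dag(d: int, expected_degree: float, rng: np.random.Generator) -> nx.DiGraph:
    """Erdős–Rényi DAG: random topological order, each forward pair kept
    independently with probability ``expected_degree / (d - 1)``."""
    if d < 2:
        raise ValueError("need d >= 2")
    p = expected_degree / (d - 1)
    if not (0 <= p <= 1):
        raise ValueError("expected_degree out of range")
    order = rng.permutation(d)
    g = nx.DiGraph()
    g.add_nodes_from(range(d))
    for i in range(d):
        for j in range(i + 1, d):
            if rng.random() < p:
                g.add_edge(int(order[i]), int(order[j]))
    return g


def random_cpts(
    dag: nx.DiGraph,
    arities: Sequence[int],
    concentration: float,
    rng: np.random.Generator,
) -> BayesNet:
    """Fill a DAG with CPT rows drawn from a symmetric Dirichlet."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    arities = tuple(int(a) for a in arities)
    cpts: dict[int, np.ndarray] = {}
    for v in sorted(dag.nodes):
        parents = sorted(dag.predecessors(v))
        n_cfg = int(np.prod([arities[p] for p in parents] or [1]))
        rows = rng.dirichlet([concentration] * arities[v], size=n_cfg)
        rows = rows / rows.sum(axis=1, keepdims=True)
        cpts[v] = rows
    return BayesNet(dag, arities, cpts)


def random_linear_sem(
    d: int,
    expected_degree: float,
    rng: np.random.Generator,
    weight_range: tuple[float, float] = (0.5, 2.0),
    noise_kind: str = "gaussian",
    noise_scale: float = 1.0,
) -> LinearSem:
    """Random-DAG linear SEM with weights uniform on ±[w_lo, w_hi]."""
    dag = random_dag(d, expected_degree, rng)
    W = np.zeros((d, d))
    lo, hi = weight_range
    for i, j in dag.edges:
        w = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
        W[i, j] = w
    return LinearSem(W, noise_kind=noise_kind, noise_scale=noise_scale)


def forward_sample(bn: BayesNet, n: int, rng: np.random.Generator) -> Dataset:
    """Ancestral sampling: draw variables in topological order from their
    CPT rows."""
    if n < 1:
        raise ValueError("n must be positive")
    d = bn.d
    values = np.zeros((n, d), dtype=np.int64)
    for v in nx.topological_sort(bn.dag):
        parents = bn.parents(v)
        if parents:
            shape = [bn.arities[p] for p in parents]
            cfg = np.ravel_multi_index(
                tuple(values[:, p] for p in parents), dims=shape
            )
        else:
            cfg = np.zeros(n, dtype=np.int64)
        rows = bn.cpts[v][cfg]  # (n, arity)
        u = rng.random(n)
        values[:, v] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
    names = [f"V{i}" for i in range(d)]
    meta = VariableMeta.discrete(names, bn.arities)
    return Dataset(values, meta)


def sample_linear_sem(sem: LinearSem, n: int, rng: np.random.Generator) -> Dataset:
    """Draw n rows of the linear SEM: ``D = Z (I - W)^{-1}``."""
    if n < 1:
        raise ValueError("n must be positive")
    d = sem.d
    if sem.noise_kind == "gaussian":
        Z = rng.normal(0.0, sem.noise_scale, size=(n, d))
    else:
        Z = rng.uniform(-sem.noise_scale, sem.noise_scale, size=(n, d))
    M = np.eye(d) - sem.W_true
    # acyclic support => I - W invertible (det = 1 under topological order)
    D = np.linalg.solve(M.T, Z.T).T
    names = [f"X{i}" for i in range(d)]
    return Dataset(D, VariableMeta.continuous(names))


_BENCHMARKS = {
    # name: (d, expected_degree, kind, seed)
    "tiny5": (5, 1.6, "bn", 515),
    "medium8": (8, 1.8, "bn", 808),
    "wide11": (11, 2.0, "bn", 1111),
}


def benchmark_suite(name: str, rng: np.random.Generator | None = None):
    """Canonical seeded fixtures at small public-benchmark scales.

    Returns ``(model, truth_dag)``.  The fixture graphs are regenerated
    deterministically (fixed internal seed) and are always acyclic and
    weakly connected; ``rng`` is accepted for interface symmetry but the
    fixtures do not depend on it.
    """
    if name not in _BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}")
    d, deg, kind, seed = _BENCHMARKS[name]
    fixture_rng = np.random.default_rng(seed)
    for _ in range(1000):
        dag = random_dag(d, deg, fixture_rng)
        if nx.is_weakly_connected(dag):
            break
    else:  # pragma: no cover - generator parameters make this unreachable
        raise RuntimeError("failed to draw a connected fixture graph")
    if kind == "bn":
        model = random_cpts(dag, [2] * d, concentration=0.5, rng=fixture_rng)
        return model, dag
    sem = random_linear_sem(d, deg, fixture_rng)
    return sem, sem.dag
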