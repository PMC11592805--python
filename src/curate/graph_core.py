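"""Graph containers shared by the constraint-based and score-based learners.

The constraint path manipulates an undirected :class:`Skeleton` with
separation-set records and finishes with a partially directed
:class:`Cpdag`; the score path works on a real weighted adjacency matrix
whose distance from acyclicity is measured by the smooth functional
``h(W) = tr(exp(W∘W)) - d`` (zero exactly when the support of ``W`` is a
DAG).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.linalg import expm

__all__ = [
    "VariableMeta",
    "Skeleton",
    "Cpdag",
    "complete_skeleton",
    "h_acyclicity",
    "grad_h",
    "threshold_to_dag",
    "orient_cpdag",
    "write_edge_list",
    "read_edge_list",
    "write_gml",
]


@dataclass(frozen=True)
class VariableMeta:
    """Names and kinds of the observed variables.

    ``kinds[i]`` is either the string ``"continuous"`` or an integer arity
    (>= 2) for a discrete variable.
    """

    names: tuple[str, ...]
    kinds: tuple[object, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValueError("need at least two variables")
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        if len(self.kinds) != len(self.names):
            raise ValueError("kinds and names must align")
        for k in self.kinds:
            if k != "continuous" and (not isinstance(k, (int, np.integer)) or k < 2):
                raise ValueError(f"invalid variable kind {k!r}")

    @property
    def d(self) -> int:
        return len(self.names)

    def is_discrete(self, i: int) -> bool:
        return self.kinds[i] != "continuous"

    def arity(self, i: int) -> int:
        if not self.is_discrete(i):
            raise ValueError(f"variable {self.names[i]} is continuous")
        return int(self.kinds[i])

    @classmethod
    def discrete(cls, names: Iterable[str], arities: Iterable[int]) -> "VariableMeta":
        return cls(tuple(names), tuple(int(a) for a in arities))

    @classmethod
    def continuous(cls, names: Iterable[str]) -> "VariableMeta":
        names = tuple(names)
        return cls(names, ("continuous",) * len(names))


class Skeleton:
    """Mutable undirected graph with separation-set records.

    Vertices are 0-based indices.  Deleting an edge requires recording the
    conditioning set that rendered the pair independent; the orientation
    phase consumes those records.
    """

    def __init__(self, d: int) -> None:
        if d < 2:
            raise ValueError("skeleton needs at least 2 vertices")
        self.d = d
        self._adj: list[set[int]] = [set() for _ in range(d)]
        self.sepsets: dict[tuple[int, int], frozenset[int]] = {}

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        self._adj[a].add(b)
        self._adj[b].add(a)

    def has_edge(self, a: int, b: int) -> bool:
        return b in self._adj[a]

    def remove_edge(self, a: int, b: int, sepset: Iterable[int]) -> None:
        if not self.has_edge(a, b):
            raise KeyError(f"no edge {(a, b)}")
        s = frozenset(sepset)
        if a in s or b in s:
            raise ValueError("separation set may not contain the pair itself")
        self._adj[a].discard(b)
        self._adj[b].discard(a)
        self.sepsets[self._key(a, b)] = s

    def neighbors(self, a: int) -> set[int]:
        return set(self._adj[a])

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (a, b) for a in range(self.d) for b in self._adj[a] if a < b
        )

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj) // 2

    def sepset(self, a: int, b: int) -> frozenset[int]:
        return self.sepsets[self._key(a, b)]

    def copy(self) -> "Skeleton":
        out = Skeleton(self.d)
        for a, b in self.edges():
            out.add_edge(a, b)
        out.sepsets = dict(self.sepsets)
        return out


@dataclass
class Cpdag:
    """Partially directed graph: output of the orientation phase."""

    d: int
    directed: set[tuple[int, int]] = field(default_factory=set)
    undirected: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        und = {tuple(sorted(e)) for e in self.undirected}
        dir_pairs = {tuple(sorted(e)) for e in self.directed}
        if und & dir_pairs:
            raise ValueError("an edge cannot be both directed and undirected")
        self.undirected = und
        g = nx.DiGraph(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part of a CPDAG must be acyclic")

    def skeleton_edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.directed} | set(self.undirected)

    def all_edges(self) -> list[tuple[int, int, str]]:
        out = [(a, b, "directed") for a, b in sorted(self.directed)]
        out += [(a, b, "undirected") for a, b in sorted(self.undirected)]
        return out


def complete_skeleton(d: int) -> Skeleton:
    """Fully connected skeleton on ``d`` vertices — the starting point of
    constraint-based discovery."""
    skel = Skeleton(d)
    for a in range(d):
        for b in range(a + 1, d):
            skel.add_edge(a, b)
    return skel


def _as_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    return W


def h_acyclicity(W: np.ndarray) -> float:
    """Smooth acyclicity functional ``tr(exp(W∘W)) - d``.

    Nonnegative everywhere and zero exactly when the nonzero pattern of
    ``W`` contains no directed cycle.  The matrix exponential is evaluated
    with SciPy's scaling-and-squaring Padé routine.
    """
    W = _as_matrix(W)
    d = W.shape[0]
    return float(np.trace(expm(W * W)) - d)


def grad_h(W: np.ndarray) -> np.ndarray:
    """Gradient of :func:`h_acyclicity`: ``exp(W∘W)ᵀ ∘ 2W``."""
    W = _as_matrix(W)
    return expm(W * W).T * (2.0 * W)


def threshold_to_dag(W: np.ndarray, omega: float) -> nx.DiGraph:
    """Prune a weighted adjacency to a DAG.

    Keeps entries with ``|w_ij| > omega``; if the surviving support still
    contains a cycle, the smallest-|w| edge participating in a cycle is
    removed, repeatedly, until acyclic.
    """
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    W = _as_matrix(W)
    d = W.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(d))
    for i in range(d):
        for j in range(d):
            if i != j and abs(W[i, j]) > omega:
                g.add_edge(i, j, weight=float(W[i, j]))
    while not nx.is_directed_acyclic_graph(g):
        # edges inside a nontrivial strongly connected component lie on cycles
        cyc_edges = []
        for comp in nx.strongly_connected_components(g):
            if len(comp) < 2:
                continue
            sub = g.subgraph(comp)
            cyc_edges.extend(sub.edges(data="weight"))
        u, v, _ = min(cyc_edges, key=lambda e: (abs(e[2]), e[0], e[1]))
        g.remove_edge(u, v)
    return g


def _would_cycle(directed: set[tuple[int, int]], u: int, v: int) -> bool:
    g = nx.DiGraph(directed)
    g.add_edge(u, v)
    return not nx.is_directed_acyclic_graph(g)


def orient_cpdag(skel: Skeleton) -> Cpdag:
    """Orient a pruned skeleton into a CPDAG.

    Stage one finds v-structures: for every unshielded triple ``a - b - c``
    (``a, c`` non-adjacent) whose recorded separation set excludes ``b``,
    orient ``a→b←c``.  Conflicting claims are resolved first-applied-wins
    in lexicographic triple order.  Stage two closes under Meek rules
    R1–R3.  An orientation that would create a directed cycle is skipped,
    so the directed part is acyclic by construction.
    """
    directed: set[tuple[int, int]] = set()
    und: set[tuple[int, int]] = set(skel.edges())

    def is_und(a: int, b: int) -> bool:
        return tuple(sorted((a, b))) in und

    def orient(u: int, v: int) -> bool:
        """Turn undirected u-v into u→v if legal; returns True on change."""
        if not is_und(u, v):
            return False
        if (v, u) in directed or _would_cycle(directed, u, v):
            return False
        und.discard(tuple(sorted((u, v))))
        directed.add((u, v))
        return True

    d = skel.d
    # v-structures, lexicographic (a, b, c) with a < c
    for b in range(d):
        nb = sorted(skel.neighbors(b))
        for ai in range(len(nb)):
            for ci in range(ai + 1, len(nb)):
                a, c = nb[ai], nb[ci]
                if skel.has_edge(a, c):
                    continue
                key = (a, c) if a < c else (c, a)
                if key not in skel.sepsets:
                    raise KeyError(
                        f"missing separation set for tested pair {key}"
                    )
                if b not in skel.sepsets[key]:
                    orient(a, b)
                    orient(c, b)

    # Meek rules R1-R3 to closure
    changed = True
    while changed:
        changed = False
        for a, b in list(directed):
            # R1: a→b, b-c, a and c non-adjacent  =>  b→c
            for c in sorted(skel.neighbors(b)):
                if c != a and is_und(b, c) and not skel.has_edge(a, c):
                    changed |= orient(b, c)
            # R2: a→b→c with a-c undirected  =>  a→c
            for c in sorted(skel.neighbors(b)):
                if (b, c) in directed and is_und(a, c):
                    changed |= orient(a, c)
        # R3: a-b, a-c, a-d, c→b, d→b, c and d non-adjacent  =>  a→b
        for a, b in [e for p in sorted(und) for e in (p, p[::-1])]:
            parents = [c for c in skel.neighbors(b) if (c, b) in directed]
            hit = False
            for i in range(len(parents)):
                for j in range(i + 1, len(parents)):
                    c, dd = parents[i], parents[j]
                    if (
                        is_und(a, c)
                        and is_und(a, dd)
                        and not skel.has_edge(c, dd)
                    ):
                        hit = True
            if hit:
                changed |= orient(a, b)
    return Cpdag(d, directed=directed, undirected=und)


# ---------------------------------------------------------------------------
# edge-list / GML writers and readers


def write_edge_list(
    path,
    names: Iterable[str],
    directed: Iterable[tuple[int, int]] = (),
    undirected: Iterable[tuple[int, int]] = (),
    weights: Mapping[tuple[int, int], float] | None = None,
) -> None:
    """Plain-text edge list: one ``src<TAB>dst<TAB>kind[<TAB>weight]`` line
    per edge, using variable names."""
    names = list(names)
    with open(path, "w") as fh:
        for kind, pairs in (("directed", directed), ("undirected", undirected)):
            for a, b in sorted(pairs):
                line = f"{names[a]}\t{names[b]}\t{kind}"
                if weights is not None and (a, b) in weights:
                    line += f"\t{weights[(a, b)]:.6g}"
                fh.write(line + "\n")


def read_edge_list(path, names: Iterable[str] | None = None):
    """Read the edge-list dialect written by :func:`write_edge_list`.

    Returns ``(names, directed, undirected, weights)`` with edges as index
    pairs.  If ``names`` is not given the vertex set is inferred from the
    file in order of first appearance.
    """
    raw = []
    seen: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed edge-list line: {line!r}")
            src, dst, kind = parts[:3]
            w = float(parts[3]) if len(parts) > 3 else None
            raw.append((src, dst, kind, w))
            for v in (src, dst):
                if v not in seen:
                    seen.append(v)
    if names is None:
        names = seen
    names = list(names)
    index = {v: i for i, v in enumerate(names)}
    directed, undirected, weights = [], [], {}
    for src, dst, kind, w in raw:
        e = (index[src], index[dst])
        if kind == "directed":
            directed.append(e)
        elif kind == "undirected":
            undirected.append(tuple(sorted(e)))
        else:
            raise ValueError(f"unknown edge kind {kind!r}")
        if w is not None:
            weights[e] = w
    return names, directed, undirected, weights


def write_gml(path, names: Iterable[str], cpdag: Cpdag) -> None:
    g = nx.DiGraph()
    names = list(names)
    g.add_nodes_from(names)
    for a, b in cpdag.directed:
        g.add_edge(names[a], names[b], kind="directed")
    for a, b in cpdag.undirected:
        g.add_edge(names[a], names[b], kind="undirected")
    nx.write_gml(g, path)
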