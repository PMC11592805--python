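"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from curate.ci_tests import Dataset
from curate.graph_core import Skeleton, complete_skeleton


def kendall_tau_bruteforce(x, y) -> float:
    """O(n²) pair-enumeration tau-b: the independent oracle for the
    library statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    npairs = n * (n - 1) // 2
    denom = np.sqrt((npairs - tx) * (npairs - ty))
    if denom == 0:
        return 0.0
    return (nc - nd) / denom


def reference_pc_skeleton(D: Dataset, statistic, T: float = 0.05) -> Skeleton:
    """Plain non-private PC skeleton phase: delete when the statistic
    exceeds T, same pair/subset ordering as the private learner but with
    no noise, margins, budgets or coin.  Written independently as the
    noise-free oracle."""
    d = D.d
    skel = complete_skeleton(d)
    for order in range(d - 1):
        if skel.n_edges == 0:
            break
        if not any(
            len(skel.neighbors(a) - {b}) >= order
            for a in range(d)
            for b in skel.neighbors(a)
        ):
            break
        for a in range(d):
            for b in sorted(skel.neighbors(a)):
                nbrs = sorted(skel.neighbors(a) - {b})
                if len(nbrs) < order:
                    continue
                for S in combinations(nbrs, order):
                    if not skel.has_edge(a, b):
                        break
                    f, m_eff = statistic.evaluate(D, a, b, S)
                    if m_eff == 0:
                        continue
                    if f > T:
                        skel.remove_edge(a, b, S)
                        break
    return skel


@pytest.fixture
def rng():
    return np.random.default_rng(20240946)
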