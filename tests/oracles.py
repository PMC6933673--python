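"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation — and shares no code with the package's own
computation paths.
"""

from __future__ import annotations

import itertools
from math import comb

from tfmodminer.io import ConfidenceNetwork


def exact_steiner_cost(net: ConfidenceNetwork, terminals: set[str]) -> float:
    """Optimal Steiner cost by brute force over all node supersets.

    For every subset of nodes containing the terminals, if the induced
    subgraph is connected, its MST cost is a candidate; the minimum over
    all candidates is the exact Steiner optimum.
    """
    nodes = sorted(net.nodes)
    extra = [n for n in nodes if n not in terminals]
    best = float("inf")
    for r in range(len(extra) + 1):
        for combo in itertools.combinations(extra, r):
            subset = set(terminals) | set(combo)
            cost = _mst_cost_if_connected(net, subset)
            if cost is not None:
                best = min(best, cost)
    return best


def _mst_cost_if_connected(net: ConfidenceNetwork, subset: set[str]) -> float | None:
    """Prim's algorithm on the induced subgraph; None when disconnected."""
    nodes = sorted(subset)
    if len(nodes) == 1:
        return 0.0
    in_tree = {nodes[0]}
    cost = 0.0
    while len(in_tree) < len(nodes):
        best = None
        for a in in_tree:
            for b in net.neighbors(a):
                if b in subset and b not in in_tree:
                    w = net.weight(a, b)
                    if best is None or w < best[0]:
                        best = (w, b)
        if best is None:
            return None
        cost += best[0]
        in_tree.add(best[1])
    return cost


def exact_mannwhitney_greater(x: list[float], y: list[float]) -> float:
    """One-sided (x greater) Mann-Whitney p by exhaustive enumeration.

    Enumerates every way of choosing |x| positions among the pooled
    sample and counts placements whose U statistic is at least the
    observed one.  Ties are handled through the U definition itself
    (each tied cross-pair contributes 1/2).
    """

    def u_stat(xs: list[float], ys: list[float]) -> float:
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    observed = u_stat(x, y)
    pooled = sorted(x + y)
    n = len(x)
    total = 0
    at_least = 0
    for positions in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in positions]
        ys = [pooled[i] for i in range(len(pooled)) if i not in positions]
        total += 1
        if u_stat(xs, ys) >= observed - 1e-12:
            at_least += 1
    return at_least / total


def exact_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct tail summation."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return total / denom


def bh_qvalues(pvalues: list[float]) -> list[float]:
    """Hand-coded Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q
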