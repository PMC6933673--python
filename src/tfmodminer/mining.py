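"""Stage 2: minimal-cost connected module extraction (approximate Steiner).

For each candidate TF set the miner looks for the most confident,
minimal-sized connected subgraph of the interaction network containing
all candidate TFs, where the cost of a subgraph is the sum of its edge
weights (1 - confidence).  Finding the optimum is the NP-hard Steiner
tree problem, so the Kou-Markowsky-Berman 2-approximation is used:

1. metric closure over the terminals (pairwise shortest paths),
2. minimum spanning tree of the closure,
3. expansion of the MST edges into their shortest paths,
4. MST of the expanded subgraph,
5. repeated pruning of non-terminal leaves.

The returned tree costs at most twice the optimum, and steps 4-5 shrink
the number of participating proteins where possible.  All ties (equal
path weights, equal MST edge weights) break lexicographically on node
identifiers, so results are identical across runs and platforms.
Non-terminal nodes recruited into the tree are the module's mediator
proteins.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

from .io import CandidateSet, ConfidenceNetwork, TFModule

log = logging.getLogger(__name__)


class DisconnectedTerminalsError(ValueError):
    """Some candidate TFs cannot be connected in the network."""


def _lexicographic_dijkstra(
    net: ConfidenceNetwork, source: str
) -> tuple[dict[str, float], dict[str, str | None]]:
    """Single-source shortest paths over weight = 1 - confidence.

    Among equal-cost paths the one whose reversed predecessor chain is
    lexicographically smallest wins, which pins down a unique path for
    every (source, target) pair.
    """
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, str | None] = {source: None}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in sorted(net.neighbors(u)):
            nd = d + net.weight(u, v)
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
            elif v not in done and abs(nd - dist[v]) <= 1e-15 and u < pred[v]:  # type: ignore[operator]
                pred[v] = u
    return dist, pred


def _path_to(pred: dict[str, str | None], target: str) -> list[str]:
    path = [target]
    while pred[path[-1]] is not None:
        path.append(pred[path[-1]])  # type: ignore[arg-type]
    return path[::-1]


@dataclass
class MetricClosure:
    """Pairwise shortest-path distances (and the realising paths) between
    the terminal TFs of one candidate set."""

    terminals: frozenset[str]
    distances: dict[tuple[str, str], float]  # keys endpoint-sorted
    paths: dict[tuple[str, str], list[str]]

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.distances[(a, b) if a <= b else (b, a)]

    def path(self, a: str, b: str) -> list[str]:
        key = (a, b) if a <= b else (b, a)
        p = self.paths[key]
        return p if p[0] == a else p[::-1]


def metric_closure(net: ConfidenceNetwork, terminals: frozenset[str] | set[str]) -> MetricClosure:
    """Dijkstra from each terminal; errors name any terminal that is absent
    from the network or unreachable from the others."""
    terminals = frozenset(terminals)
    missing = sorted(t for t in terminals if t not in net)
    if missing:
        raise DisconnectedTerminalsError(f"terminals not in network: {missing}")
    distances: dict[tuple[str, str], float] = {}
    paths: dict[tuple[str, str], list[str]] = {}
    ts = sorted(terminals)
    for i, a in enumerate(ts):
        dist, pred = _lexicographic_dijkstra(net, a)
        for b in ts[i + 1 :]:
            if b not in dist:
                raise DisconnectedTerminalsError(
                    f"terminal {b!r} unreachable from terminal {a!r}"
                )
            distances[(a, b)] = dist[b]
            paths[(a, b)] = _path_to(pred, b)
    return MetricClosure(terminals=terminals, distances=distances, paths=paths)


def _kruskal(
    nodes: set[str], edges: list[tuple[float, str, str]]
) -> list[tuple[str, str]]:
    """MST by Kruskal; edges sorted by (weight, endpoints) for determinism."""
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[tuple[str, str]] = []
    for w, a, b in sorted(edges):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.append((a, b))
    return mst


def approximate_steiner_module(
    net: ConfidenceNetwork, candidate: CandidateSet
) -> TFModule:
    """Kou-Markowsky-Berman Steiner approximation for one candidate set.

    Raises :class:`DisconnectedTerminalsError` when the terminals cannot
    all be connected; callers mining many candidates catch this and skip.
    """
    terminals = frozenset(candidate.tfs)
    closure = metric_closure(net, terminals)
    ts = sorted(terminals)

    if len(ts) == 1:
        return TFModule(
            gene=candidate.gene,
            terminals=terminals,
            mediators=frozenset(),
            edges=frozenset(),
            cost=0.0,
        )

    # MST of the metric closure, expanded back into network paths
    closure_edges = [
        (closure.distances[(a, b)], a, b) for (a, b) in closure.distances
    ]
    sub_nodes: set[str] = set()
    sub_edges: set[tuple[str, str]] = set()
    for a, b in _kruskal(set(ts), closure_edges):
        path = closure.path(a, b)
        sub_nodes.update(path)
        for u, v in zip(path, path[1:]):
            sub_edges.add((u, v) if u <= v else (v, u))

    # MST of the expanded subgraph, then prune non-terminal leaves
    tree_edges = _kruskal(
        sub_nodes, [(net.weight(a, b), a, b) for a, b in sorted(sub_edges)]
    )
    adj: dict[str, set[str]] = {n: set() for n in sub_nodes}
    for a, b in tree_edges:
        adj[a].add(b)
        adj[b].add(a)
    changed = True
    while changed:
        changed = False
        for n in sorted(adj):
            if n not in terminals and len(adj[n]) <= 1:
                for nb in adj.pop(n):
                    adj[nb].discard(n)
                changed = True

    edges = frozenset(
        (a, b, net.confidence(a, b))
        for a in adj
        for b in adj[a]
        if a < b
    )
    cost = sum(1.0 - c for _, _, c in edges)
    return TFModule(
        gene=candidate.gene,
        terminals=terminals,
        mediators=frozenset(adj) - terminals,
        edges=edges,
        cost=cost,
    )


def mine_all_modules(
    net: ConfidenceNetwork, candidates: dict[str, list[CandidateSet]]
) -> list[TFModule]:
    """One module attempt per candidate set.

    Candidate sets whose TFs cannot be connected are logged and skipped;
    duplicate modules (same gene, identical node set) are merged.
    """
    modules: list[TFModule] = []
    seen: set[tuple[str, frozenset[str]]] = set()
    for gene in sorted(candidates):
        for cand in candidates[gene]:
            try:
                mod = approximate_steiner_module(net, cand)
            except DisconnectedTerminalsError as exc:
                log.info("gene %s: candidate %s skipped (%s)", gene, sorted(cand.tfs), exc)
                continue
            key = (gene, mod.nodes)
            if key in seen:
                continue
            seen.add(key)
            modules.append(mod)
    return modules
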