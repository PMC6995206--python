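"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from pdnet.config import AnalysisConfig
from pdnet.cooccur import PhiEdge
from pdnet.network import DiseaseNetwork


def make_edge(a: str, b: str, phi: float, significant: bool = True, p: float = 0.01) -> PhiEdge:
    """PhiEdge with plausible filler counts, for graph-topology tests."""
    a, b = sorted((a, b))
    return PhiEdge(a, b, n11=10, n_a=20, n_b=20, phi=phi, t_stat=0.0,
                   p_value=p if significant else 0.5, significant=significant)


def network_from_edges(
    weighted_edges: list[tuple[str, str, float]], cohort: str = "case"
) -> DiseaseNetwork:
    """Build a DiseaseNetwork directly from (a, b, phi) triples."""
    edges = [make_edge(a, b, w) for a, b, w in weighted_edges]
    nodes = sorted({v for a, b, _ in weighted_edges for v in (a, b)})
    return DiseaseNetwork(
        cohort=cohort,
        nodes=nodes,
        edges=sorted(edges, key=lambda e: (e.code_a, e.code_b)),
        prevalence={v: 0.05 for v in nodes},
    )


def brute_force_betweenness(nodes: list[str], lengths: dict[tuple[str, str], float]) -> dict[str, float]:
    """Exhaustive betweenness: enumerate all simple paths per pair, count
    shortest ones fractionally.  Only for tiny graphs (<= 14 nodes)."""
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for (a, b) in lengths:
        adj[a].append(b)
        adj[b].append(a)

    def all_paths(s: str, t: str):
        stack = [(s, [s], 0.0)]
        while stack:
            v, path, dist = stack.pop()
            if v == t:
                yield path, dist
                continue
            for w in adj[v]:
                if w not in path:
                    key = (v, w) if (v, w) in lengths else (w, v)
                    stack.append((w, path + [w], dist + lengths[key]))

    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = list(all_paths(s, t))
            if not paths:
                continue
            best = min(d for _, d in paths)
            shortest = [p for p, d in paths if d <= best + 1e-9]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def set_partitions(items: list):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def newman_modularity(blocks: list[list[str]], weights: dict[tuple[str, str], float]) -> float:
    """Independent weighted-modularity evaluation from an edge dict."""
    total = sum(weights.values())
    strength: dict[str, float] = {}
    for (a, b), w in weights.items():
        strength[a] = strength.get(a, 0.0) + w
        strength[b] = strength.get(b, 0.0) + w
    q = 0.0
    for block in blocks:
        members = set(block)
        intra = sum(w for (a, b), w in weights.items() if a in members and b in members)
        s = sum(strength.get(v, 0.0) for v in members)
        q += intra / total - (s / (2 * total)) ** 2
    return q


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
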