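"""Walktrap community detection (Pons-Latapy) on weighted disease networks.

Short random walks on a graph tend to stay trapped inside densely connected
regions, so the t-step walk probability profile of a node characterizes its
community.  This module implements the exact (deterministic) form of the
algorithm: probability vectors are computed by matrix power rather than by
sampling walks, which makes runs reproducible.

With non-negative edge weights w_ij (phi values clipped at 0), node strength
d_i = sum_j w_ij, and row-stochastic transition matrix P_ij = w_ij / d_i,
the distance between nodes i and j after t steps is

    r_ij(t)^2 = sum_k (P^t_ik - P^t_jk)^2 / d_k.

Starting from singleton communities, the algorithm repeatedly merges the
*adjacent* pair of communities minimizing the Ward-style merge cost

    dsigma(C1, C2) = (1/n) * |C1||C2| / (|C1| + |C2|) * r_{C1,C2}^2,

updating community probability vectors as size-weighted means, and finally
cuts the merge dendrogram at the level maximizing weighted Newman
modularity.  Connected components are clustered independently (walk
distances across components are undefined); ties in the merge cost are
broken by the lexicographically smallest community pair so that identical
inputs always give identical dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DiseaseNetwork

__all__ = ["Partition", "transition_matrix", "walktrap", "modularity"]


@dataclass
class Partition:
    """Node -> cluster assignment with merge history and modularity."""

    assignment: dict[str, int]
    merges: list[tuple[str, str, float]] = field(default_factory=list)
    modularity: float = 0.0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(members) for cid, members in out.items()}


def _clipped_weights(network: DiseaseNetwork) -> tuple[list[str], np.ndarray]:
    """Node order and symmetric weight matrix with negative phi clipped to 0."""
    nodes = sorted(network.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for e in network.edges:
        val = max(e.phi, 0.0)
        i, j = idx[e.code_a], idx[e.code_b]
        w[i, j] = w[j, i] = val
    return nodes, w


def transition_matrix(network: DiseaseNetwork) -> tuple[list[str], np.ndarray]:
    """Row-stochastic walk matrix P_ij = w_ij / strength(i).

    Raises if any node has zero strength after clipping (no walk can leave
    it); the >=2-significant-edge filter normally precludes this.
    """
    nodes, w = _clipped_weights(network)
    if not nodes:
        raise ValueError("network is empty")
    strength = w.sum(axis=1)
    dead = [nodes[i] for i in np.flatnonzero(strength == 0)]
    if dead:
        raise ValueError(f"zero-strength node(s) after clipping: {dead}")
    return nodes, w / strength[:, None]


def modularity(network: DiseaseNetwork, assignment: dict[str, int]) -> float:
    """Weighted Newman modularity Q of a partition.

    Q = sum_c [ W_c / W - (S_c / 2W)^2 ] with W the total edge weight,
    W_c the intra-cluster weight and S_c the summed strength of cluster c,
    on the same clipped (non-negative) weights the walk uses.
    """
    missing = set(network.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)}")
    nodes, w = _clipped_weights(network)
    idx = {v: i for i, v in enumerate(nodes)}
    total_w = w.sum() / 2.0
    if total_w == 0:
        return 0.0
    strength = w.sum(axis=1)
    q = 0.0
    for members in _group_by_cluster(assignment, nodes).values():
        rows = [idx[v] for v in members]
        intra = w[np.ix_(rows, rows)].sum() / 2.0
        s_c = strength[rows].sum()
        q += intra / total_w - (s_c / (2.0 * total_w)) ** 2
    return float(q)


def _group_by_cluster(assignment: dict[str, int], nodes: list[str]) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for v in nodes:
        out.setdefault(assignment[v], []).append(v)
    return out


def _components(nodes: list[str], w: np.ndarray) -> list[list[int]]:
    n = len(nodes)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(w[i] > 0):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        comps.append(sorted(comp))
    return comps


class _Agglomerator:
    """Walktrap agglomeration within one connected component."""

    def __init__(self, labels: list[str], w: np.ndarray, t: int):
        self.labels = labels
        n = len(labels)
        self.n = n
        self.d = w.sum(axis=1)
        if np.any(self.d == 0) and n > 1:
            raise ValueError("zero-strength node inside a component")
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(self.d[:, None] > 0, w / self.d[:, None], 0.0)
        self.pt = np.linalg.matrix_power(p, t)
        self.inv_d = np.where(self.d > 0, 1.0 / self.d, 0.0)
        # live communities: id -> (member row indices, vector, size)
        self.members: dict[int, list[int]] = {i: [i] for i in range(n)}
        self.vectors: dict[int, np.ndarray] = {i: self.pt[i].copy() for i in range(n)}
        self.adj: dict[int, set[int]] = {
            i: set(int(j) for j in np.flatnonzero(w[i] > 0) if j != i) for i in range(n)
        }
        self.next_id = n
        self.merge_levels: list[tuple[int, int, int, float]] = []  # (c1, c2, new, dsigma)

    def _rep(self, cid: int) -> str:
        return min(self.labels[i] for i in self.members[cid])

    def _dsigma(self, c1: int, c2: int) -> float:
        diff = self.vectors[c1] - self.vectors[c2]
        r2 = float(np.sum(diff * diff * self.inv_d))
        s1, s2 = len(self.members[c1]), len(self.members[c2])
        return (s1 * s2) / (s1 + s2) / self.n * r2

    def run(self) -> list[list[set[int]]]:
        """Merge to a single community; return member-sets at every level."""
        levels = [self._snapshot()]
        while len(self.members) > 1:
            best = None
            for c1 in self.members:
                for c2 in self.adj[c1]:
                    if c2 <= c1:
                        continue
                    ds = self._dsigma(c1, c2)
                    key = (ds, min(self._rep(c1), self._rep(c2)),
                           max(self._rep(c1), self._rep(c2)))
                    if best is None or key < best[0]:
                        best = (key, c1, c2)
            if best is None:  # disconnected inside component: cannot happen
                break
            key, c1, c2 = best
            self._merge(c1, c2, key[0])
            levels.append(self._snapshot())
        return levels

    def _snapshot(self) -> list[set[int]]:
        return [set(m) for m in self.members.values()]

    def _merge(self, c1: int, c2: int, dsigma: float) -> None:
        new = self.next_id
        self.next_id += 1
        s1, s2 = len(self.members[c1]), len(self.members[c2])
        self.merge_levels.append((c1, c2, new, dsigma))
        self.vectors[new] = (s1 * self.vectors[c1] + s2 * self.vectors[c2]) / (s1 + s2)
        self.members[new] = self.members[c1] + self.members[c2]
        self.adj[new] = (self.adj[c1] | self.adj[c2]) - {c1, c2}
        for other in self.adj[new]:
            self.adj[other] -= {c1, c2}
            self.adj[other].add(new)
        for dead in (c1, c2):
            del self.members[dead], self.vectors[dead], self.adj[dead]


def walktrap(network: DiseaseNetwork, t: int = 4) -> Partition:
    """Cluster the PDN with exact Walktrap and a max-modularity cut.

    Components are agglomerated independently; within each, the merge
    sequence is swept and the level maximizing that component's modularity
    contribution (relative to the global total weight) is kept.  Modularity
    is additive over components, so per-component cuts maximize global Q.
    """
    if t < 1:
        raise ValueError("walk length must be >= 1")
    if not network.nodes:
        return Partition(assignment={}, merges=[], modularity=0.0)
    nodes, w = _clipped_weights(network)
    total_w = w.sum() / 2.0
    strength = w.sum(axis=1)
    assignment: dict[str, int] = {}
    merges: list[tuple[str, str, float]] = []
    cluster_id = 0
    for comp in _components(nodes, w):
        labels = [nodes[i] for i in comp]
        if len(comp) == 1 or total_w == 0:
            assignment[labels[0]] = cluster_id
            cluster_id += 1
            continue
        sub_w = w[np.ix_(comp, comp)]
        agg = _Agglomerator(labels, sub_w, t)
        levels = agg.run()
        # merge audit trail, communities named by their smallest member code
        merges.extend(_named_merges(agg, labels))
        best_level, best_q = _best_cut(levels, comp, w, strength, total_w)
        for member_set in best_level:
            for row in sorted(member_set):
                assignment[labels[row]] = cluster_id
            cluster_id += 1
    q = modularity(network, assignment)
    return Partition(assignment=assignment, merges=merges, modularity=q)


def _named_merges(agg: _Agglomerator, labels: list[str]) -> list[tuple[str, str, float]]:
    members: dict[int, list[int]] = {i: [i] for i in range(len(labels))}
    named = []
    for c1, c2, new, ds in agg.merge_levels:
        rep1 = min(labels[i] for i in members[c1])
        rep2 = min(labels[i] for i in members[c2])
        named.append((min(rep1, rep2), max(rep1, rep2), ds))
        members[new] = members[c1] + members[c2]
    return named


def _best_cut(
    levels: list[list[set[int]]],
    comp: list[int],
    w: np.ndarray,
    strength: np.ndarray,
    total_w: float,
) -> tuple[list[set[int]], float]:
    """Sweep merge levels; keep the first level attaining max Q contribution."""
    best_level, best_q = levels[0], -np.inf
    for level in levels:
        q = 0.0
        for member_set in level:
            rows = [comp[i] for i in member_set]
            intra = w[np.ix_(rows, rows)].sum() / 2.0
            s_c = strength[rows].sum()
            q += intra / total_w - (s_c / (2.0 * total_w)) ** 2
        if q > best_q + 1e-12:
            best_q = q
            best_level = level
    return best_level, best_q
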