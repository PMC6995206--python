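"""Walktrap clustering: transition matrix, merges, modularity cut."""

import igraph as ig
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import network_from_edges, newman_modularity, set_partitions
from pdnet.walktrap import modularity, transition_matrix, walktrap


def triangle(prefix: str, w: float = 0.1):
    a, b, c = f"{prefix}1", f"{prefix}2", f"{prefix}3"
    return [(a, b, w), (b, c, w), (a, c, w)]


class TestTransitionMatrix:
    def test_equal_triangle_rows(self):
        net = network_from_edges(triangle("A0"))
        nodes, p = transition_matrix(net)
        off = p[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_star_rows(self):
        net = network_from_edges(
            [("S00", "L01", 0.1), ("S00", "L02", 0.1), ("S00", "L03", 0.1)]
        )
        nodes, p = transition_matrix(net)
        center = nodes.index("S00")
        assert np.allclose(np.delete(p[center], center), 1 / 3)
        for i, v in enumerate(nodes):
            if v != "S00":
                assert p[i, center] == pytest.approx(1.0)

    def test_weighted_normalization(self):
        net = network_from_edges(
            [("A00", "B00", 0.3), ("A00", "C00", 0.1), ("B00", "C00", 0.2), ("C00", "D00", 0.4)]
        )
        nodes, p = transition_matrix(net)
        i = {v: k for k, v in enumerate(nodes)}
        assert p[i["A00"], i["B00"]] == pytest.approx(0.3 / 0.4)
        assert p[i["C00"], i["D00"]] == pytest.approx(0.4 / 0.7)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_negative_only_node_rejected(self):
        net = network_from_edges(
            [("A00", "B00", -0.1), ("B00", "C00", 0.2), ("B00", "D00", 0.2), ("C00", "D00", 0.2)]
        )
        with pytest.raises(ValueError, match="A00"):
            transition_matrix(net)


class TestModularity:
    def test_single_cluster_is_zero(self):
        net = network_from_edges(triangle("A0") + [("A01", "B01", 0.1)] + triangle("B0"))
        assignment = {v: 0 for v in net.nodes}
        assert modularity(net, assignment) == pytest.approx(0.0)

    def test_two_disjoint_k3(self):
        net = network_from_edges(triangle("A0", 1.0) + triangle("B0", 1.0))
        assignment = {v: (0 if v.startswith("A") else 1) for v in net.nodes}
        assert modularity(net, assignment) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bounds_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"N{i:02d}" for i in range(10)]
        weights = {}
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.4:
                    weights[(nodes[i], nodes[j])] = float(rng.uniform(0.05, 0.5))
        net = network_from_edges([(a, b, w) for (a, b), w in weights.items()])
        for _ in range(5):
            assignment = {v: int(rng.integers(0, 3)) for v in net.nodes}
            q = modularity(net, assignment)
            assert -0.5 <= q <= 1.0
            blocks = {}
            for v, c in assignment.items():
                blocks.setdefault(c, []).append(v)
            assert q == pytest.approx(newman_modularity(list(blocks.values()), weights), abs=1e-12)


class TestWalktrap:
    @pytest.mark.parametrize("t", [2, 3, 4, 5, 6])
    def test_disjoint_triangles_recovered(self, t):
        net = network_from_edges(triangle("A0") + triangle("B0"))
        part = walktrap(net, t=t)
        clusters = part.clusters()
        assert sorted(map(sorted, clusters.values())) == [
            ["A01", "A02", "A03"],
            ["B01", "B02", "B03"],
        ]

    def test_barbell_matches_exhaustive_modularity_oracle(self):
        left = ["A01", "A02", "A03", "A04"]
        right = ["B01", "B02", "B03", "B04"]
        weights = {}
        for group in (left, right):
            for i in range(4):
                for j in range(i + 1, 4):
                    weights[(group[i], group[j])] = 1.0
        weights[("A04", "B01")] = 1.0
        net = network_from_edges([(a, b, w) for (a, b), w in weights.items()])
        part = walktrap(net, t=4)
        ours = sorted(map(sorted, part.clusters().values()))
        best_q, best_blocks = -np.inf, None
        for blocks in set_partitions(left + right):
            q = newman_modularity(blocks, weights)
            if q > best_q:
                best_q, best_blocks = q, blocks
        assert ours == sorted(map(sorted, best_blocks))
        assert part.modularity == pytest.approx(best_q, abs=1e-12)

    def test_deterministic_and_permutation_equivariant(self, rng):
        edges = []
        nodes = [f"N{i:02d}" for i in range(18)]
        for i in range(18):
            for j in range(i + 1, 18):
                if (i // 6 == j // 6 and rng.random() < 0.8) or rng.random() < 0.1:
                    edges.append((nodes[i], nodes[j], float(rng.uniform(0.05, 0.3))))
        net = network_from_edges(edges)
        p1 = walktrap(net, t=4)
        p2 = walktrap(net, t=4)
        assert p1.assignment == p2.assignment and p1.merges == p2.merges
        # relabel nodes; clusters must transport along the relabeling
        mapping = {v: f"Z{len(nodes) - 1 - i:02d}" for i, v in enumerate(nodes)}
        relabeled = network_from_edges([(mapping[a], mapping[b], w) for a, b, w in edges])
        p3 = walktrap(relabeled, t=4)
        orig = sorted(sorted(mapping[v] for v in c) for c in p1.clusters().values())
        new = sorted(map(sorted, p3.clusters().values()))
        assert orig == new

    def test_no_cluster_spans_components(self, rng):
        edges = triangle("A0") + triangle("B0") + triangle("C0", 0.3)
        part = walktrap(network_from_edges(edges), t=4)
        for members in part.clusters().values():
            assert len({m[0] for m in members}) == 1

    def test_empty_network(self):
        from pdnet.network import DiseaseNetwork

        part = walktrap(DiseaseNetwork("case", [], [], {}), t=4)
        assert part.assignment == {} and part.n_clusters == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agreement_with_igraph_reference(self, seed):
        """Modularity of our max-modularity cut tracks igraph's Walktrap."""
        rng = np.random.default_rng(seed)
        for _ in range(7):
            n = int(rng.integers(12, 60))
            k = max(2, n // 10)
            labels = [f"N{i:02d}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    same = i % k == j % k
                    if rng.random() < (0.6 if same else 0.06):
                        edges.append((labels[i], labels[j], float(rng.uniform(0.05, 0.4))))
            net = network_from_edges(edges)
            g = net.to_networkx()
            if g.number_of_edges() == 0:
                continue
            import networkx as nx

            if not nx.is_connected(g):
                continue
            part = walktrap(net, t=4)
            idx = {v: i for i, v in enumerate(sorted(net.nodes))}
            igr = ig.Graph(
                n=len(idx),
                edges=[(idx[a], idx[b]) for a, b, _ in edges],
                edge_attrs={"weight": [w for _, _, w in edges]},
            )
            ref = igr.community_walktrap(weights="weight", steps=4).as_clustering()
            ref_assignment = {
                v: ref.membership[idx[v]] for v in net.nodes
            }
            q_ref = modularity(net, ref_assignment)
            assert abs(part.modularity - q_ref) <= 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_partition_recovery(self, seed):
        """3 blocks x 8 nodes, p_in=0.8, p_out=0.05: ARI >= 0.9 vs truth."""
        rng = np.random.default_rng(seed)
        labels = [f"N{i:02d}" for i in range(24)]
        truth = [i // 8 for i in range(24)]
        edges = []
        for i in range(24):
            for j in range(i + 1, 24):
                p = 0.8 if truth[i] == truth[j] else 0.05
                if rng.random() < p:
                    edges.append((labels[i], labels[j], float(rng.uniform(0.1, 0.3))))
        net = network_from_edges(edges)
        part = walktrap(net, t=4)
        pred = [part.assignment[v] for v in labels]
        assert adjusted_rand_score(truth, pred) >= 0.9
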