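"""Per-code centrality profiles of a disease network.

Four measures per diagnosis code, as used to compare connectivity patterns
between cohorts:

* degree — number of incident significant phi correlations;
* strength — sum of (non-negative) phi over incident edges;
* betweenness — Brandes shortest-path load, edge length 1/phi, so stronger
  correlations are shorter;
* closeness — within each connected component, (size-1) / sum of shortest
  path distances to same-component nodes.

Z-scored columns standardize each measure within its network so the two
cohorts' profiles are comparable on one axis.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .network import DiseaseNetwork

__all__ = ["degree", "strength", "betweenness", "closeness", "centrality_table", "zscores"]

logger = logging.getLogger(__name__)


def _length_graph(network: DiseaseNetwork) -> nx.Graph:
    """Graph with clipped phi weights and path length = 1/phi.

    Zero-weight (clipped) edges get infinite length, i.e. are unusable for
    shortest paths, matching their exclusion from the walk.
    """
    g = network.to_networkx(weight="phi_clipped")
    for _u, _v, data in g.edges(data=True):
        data["length"] = 1.0 / data["weight"] if data["weight"] > 0 else float("inf")
    return g


def degree(network: DiseaseNetwork, node: str) -> int:
    """Count of significant edges incident to ``node``."""
    if node not in network.nodes:
        raise KeyError(node)
    return network.degree[node]


def strength(network: DiseaseNetwork, node: str) -> float:
    """Sum of clipped phi over edges incident to ``node``."""
    if node not in network.nodes:
        raise KeyError(node)
    return float(
        sum(max(e.phi, 0.0) for e in network.edges if node in (e.code_a, e.code_b))
    )


def betweenness(network: DiseaseNetwork) -> dict[str, float]:
    """Unnormalized weighted betweenness (Brandes), ties counted fractionally."""
    g = _length_graph(network)
    return dict(nx.betweenness_centrality(g, weight="length", normalized=False))


def closeness(network: DiseaseNetwork) -> dict[str, float]:
    """Per-component closeness: (component size - 1) / sum of distances."""
    g = _length_graph(network)
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            node = next(iter(comp))
            out[node] = 0.0
            logger.info("singleton component %s: closeness set to 0", node)
            continue
        sub = g.subgraph(comp)
        out.update(nx.closeness_centrality(sub, distance="length", wf_improved=False))
    return out


def centrality_table(network: DiseaseNetwork) -> pd.DataFrame:
    """All four measures plus z-scored columns, one row per code."""
    nodes = network.nodes
    deg = network.degree
    btw = betweenness(network)
    clo = closeness(network)
    table = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "strength": [strength(network, v) for v in nodes],
        },
        index=pd.Index(nodes, name="code"),
    )
    return zscores(table)


def zscores(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``<measure>_z`` columns: (x - mean) / sample sd per measure.

    A constant measure yields all-zero z-scores (flagged via log) rather
    than NaN.
    """
    out = table.copy()
    base = [c for c in table.columns if not c.endswith("_z")]
    for col in base:
        x = table[col].astype(float)
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd == 0 or np.isnan(sd):
            logger.info("measure %r is constant; z-scores set to 0", col)
            out[col + "_z"] = 0.0
        else:
            out[col + "_z"] = (x - x.mean()) / sd
    return out
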