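"""Node filtering and assembly of the phenotypic disease network (PDN).

A PDN keeps diagnosis codes inside a prevalence window (default 2.5-20%,
both bounds inclusive) and, among those, only codes with at least two
significant phi correlations.  The degree floor is applied iteratively to a
fixed point: removing a node can drop a neighbour below the floor, so
pruning repeats until stable.  Retained edges are exactly the significant
ones (any sign); the 0.04 phi threshold is visualization metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .config import AnalysisConfig
from .cooccur import PhiEdge

__all__ = [
    "DiseaseNetwork",
    "select_codes",
    "build_network",
    "high_prevalence_report",
    "export_graphml",
    "read_graphml",
]


@dataclass
class DiseaseNetwork:
    """Filtered significant-correlation network for one cohort."""

    cohort: str
    nodes: list[str]
    edges: list[PhiEdge]
    prevalence: dict[str, float]
    removed: list[str] = field(default_factory=list)

    @property
    def degree(self) -> dict[str, int]:
        d = {v: 0 for v in self.nodes}
        for e in self.edges:
            d[e.code_a] += 1
            d[e.code_b] += 1
        return d

    def to_networkx(self, weight: str = "phi_clipped") -> nx.Graph:
        """Weighted graph view; negative phi clipped to 0 for walk/strength use."""
        g = nx.Graph()
        for v in self.nodes:
            g.add_node(v, prevalence=self.prevalence.get(v, float("nan")))
        for e in self.edges:
            w = max(e.phi, 0.0) if weight == "phi_clipped" else e.phi
            g.add_edge(e.code_a, e.code_b, weight=w, phi=e.phi, p=e.p_value)
        return g


def select_codes(prev: pd.DataFrame, config: AnalysisConfig) -> list[str]:
    """Codes whose prevalence lies in [min_prev, max_prev], sorted."""
    mask = (prev["prevalence"] >= config.min_prev) & (prev["prevalence"] <= config.max_prev)
    return sorted(prev.index[mask])


def build_network(
    edges: list[PhiEdge],
    selected: list[str],
    config: AnalysisConfig,
    cohort: str = "case",
    prevalence: dict[str, float] | None = None,
) -> DiseaseNetwork:
    """Iteratively prune nodes below the significant-degree floor.

    Starts from the selected codes and their significant edges, removes any
    node with fewer than ``min_significant_edges`` incident significant
    edges, and repeats until no node falls below the floor (a removal can
    drop neighbours below it).  Output is independent of edge ordering.
    """
    selected_set = set(selected)
    sig = [
        e
        for e in edges
        if e.significant and e.code_a in selected_set and e.code_b in selected_set
    ]
    alive = set(selected_set)
    while True:
        deg: dict[str, int] = {v: 0 for v in alive}
        for e in sig:
            if e.code_a in alive and e.code_b in alive:
                deg[e.code_a] += 1
                deg[e.code_b] += 1
        drop = {v for v, d in deg.items() if d < config.min_significant_edges}
        if not drop:
            break
        alive -= drop
    kept_edges = sorted(
        (e for e in sig if e.code_a in alive and e.code_b in alive),
        key=lambda e: (e.code_a, e.code_b),
    )
    prevalence = prevalence or {}
    return DiseaseNetwork(
        cohort=cohort,
        nodes=sorted(alive),
        edges=kept_edges,
        prevalence={v: prevalence.get(v, float("nan")) for v in sorted(alive)},
        removed=sorted(selected_set - alive),
    )


def high_prevalence_report(
    prev_case: pd.DataFrame,
    prev_control: pd.DataFrame,
    config: AnalysisConfig,
    n_case: int,
    n_control: int,
) -> pd.DataFrame:
    """Codes strictly above the prevalence ceiling in cases, with both
    cohorts' prevalences, fold change and chi-squared test.

    These high-prevalence morbidities are excluded from the network (they
    would dominate cluster formation) but assessed separately.
    """
    from .compare import chi_square_prevalence, fold_change

    rows = []
    for code, row in prev_case.iterrows():
        if row["prevalence"] <= config.max_prev:
            continue
        if code in prev_control.index:
            c_count = int(prev_control.loc[code, "count"])
            c_prev = float(prev_control.loc[code, "prevalence"])
        else:
            c_count, c_prev = 0, 0.0
        fc = fold_change(row["prevalence"], c_prev) if c_prev > 0 else float("nan")
        stat, p = chi_square_prevalence(
            int(row["count"]), n_case, c_count, n_control, correction=config.chi2_correction
        )
        rows.append(
            {
                "code": code,
                "prev_case": float(row["prevalence"]),
                "prev_control": c_prev,
                "fold_change": fc,
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["code", "prev_case", "prev_control", "fold_change", "chi2", "p"]).set_index("code") if rows else pd.DataFrame(
        columns=["prev_case", "prev_control", "fold_change", "chi2", "p"],
        index=pd.Index([], name="code"),
    )


def export_graphml(
    network: DiseaseNetwork,
    partition,
    path,
    viz_threshold: float = 0.04,
) -> None:
    """Write the PDN as GraphML with cluster and visualization metadata.

    All significant edges are written; ``above_viz_threshold`` flags the
    strictly-above-threshold subset used for drawing (placement uses all).
    """
    g = nx.Graph()
    assignment = getattr(partition, "assignment", partition or {})
    for v in network.nodes:
        g.add_node(
            v,
            code=v,
            prevalence=float(network.prevalence.get(v, float("nan"))),
            cluster=str(assignment.get(v, "")),
        )
    for e in network.edges:
        g.add_edge(
            e.code_a,
            e.code_b,
            phi=float(e.phi),
            p=float(e.p_value),
            above_viz_threshold=bool(e.phi > viz_threshold),
        )
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    """Round-trip reader (standard GraphML, attribute types preserved)."""
    return nx.read_graphml(path)
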