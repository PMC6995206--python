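"""Model/Results facade over the phenotypic-disease-network pipeline.

``PDNModel`` holds the two cohort incidence matrices and the analysis
configuration; ``fit()`` runs the full pipeline — prevalence filtering,
all-pairs phi correlation with significance, iterative network pruning,
Walktrap clustering, centrality profiles and every cross-cohort statistic —
and returns a ``PDNResults`` carrying the estimates, their tests and a
``summary()`` table.  ``PDNResults.save()`` writes the standard output tree
(edge/centrality/cluster TSVs, GraphML, summary JSON, run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .centrality import centrality_table
from .config import AnalysisConfig
from .compare import (
    DegreeRegression,
    block_enrichment,
    degree_regression,
    diagnosis_count_summary,
    mean_shift_outliers,
    per_code_comparison,
)
from .cooccur import PhiEdge, all_pairs, edges_to_frame, prevalence
from .network import DiseaseNetwork, build_network, export_graphml, high_prevalence_report, select_codes
from .records import CASE, CONTROL, BlockMap, CohortMatrix, build_matrix, read_records
from .walktrap import Partition, walktrap

__all__ = ["PDNModel", "PDNResults"]

logger = logging.getLogger(__name__)


@dataclass
class CohortFit:
    """Everything fitted for one cohort."""

    matrix: CohortMatrix
    prevalence: pd.DataFrame
    selected_codes: list[str]
    edges: list[PhiEdge]
    network: DiseaseNetwork
    partition: Partition
    centrality: pd.DataFrame

    @property
    def n_significant_edges(self) -> int:
        return sum(e.significant for e in self.edges)


class PDNModel:
    """Phenotypic disease network model for a matched case/control design.

    Parameters
    ----------
    case, control : CohortMatrix
        Binary patient x code incidence matrices (equal enrolment by the
        matched design, though this is not enforced).
    config : AnalysisConfig, optional
        Filtering thresholds and algorithm settings.
    blocks : BlockMap, optional
        ICD-10 block table for block-level enrichment; packaged WHO-style
        table by default.
    """

    def __init__(
        self,
        case: CohortMatrix,
        control: CohortMatrix,
        config: AnalysisConfig | None = None,
        blocks: BlockMap | None = None,
    ):
        if case.cohort != CASE or control.cohort != CONTROL:
            raise ValueError("matrices must be labelled case / control")
        self.case = case
        self.control = control
        self.config = config or AnalysisConfig()
        self.blocks = blocks or BlockMap.default()
        self.input_digests: dict[str, str] = {}

    @classmethod
    def from_records(
        cls,
        records_case,
        records_control,
        roster_case=None,
        roster_control=None,
        config: AnalysisConfig | None = None,
        blocks: BlockMap | None = None,
    ) -> "PDNModel":
        roster_case = roster_case or sorted({r.patient_id for r in records_case})
        roster_control = roster_control or sorted({r.patient_id for r in records_control})
        return cls(
            build_matrix(records_case, CASE, roster_case),
            build_matrix(records_control, CONTROL, roster_control),
            config=config,
            blocks=blocks,
        )

    @classmethod
    def from_csv(
        cls,
        case_path,
        control_path,
        config: AnalysisConfig | None = None,
        blocks: BlockMap | None = None,
    ) -> "PDNModel":
        records_case, _ = read_records(case_path)
        records_control, _ = read_records(control_path)
        model = cls.from_records(
            [r for r in records_case if r.cohort == CASE],
            [r for r in records_control if r.cohort == CONTROL],
            config=config,
            blocks=blocks,
        )
        model.input_digests = {
            str(case_path): _sha256(case_path),
            str(control_path): _sha256(control_path),
        }
        return model

    def _fit_cohort(self, matrix: CohortMatrix, selected: list[str]) -> CohortFit:
        prev = prevalence(matrix)
        edges = all_pairs(matrix, selected, alpha=self.config.alpha)
        net = build_network(
            edges,
            selected,
            self.config,
            cohort=matrix.cohort,
            prevalence=prev["prevalence"].to_dict(),
        )
        part = (
            walktrap(net, t=self.config.walk_length)
            if net.nodes
            else Partition(assignment={})
        )
        cent = centrality_table(net) if net.nodes else pd.DataFrame()
        return CohortFit(matrix, prev, selected, edges, net, part, cent)

    def fit(self) -> "PDNResults":
        prev_case = prevalence(self.case)
        prev_control = prevalence(self.control)
        selected_case = select_codes(prev_case, self.config)
        if self.config.control_selection == "own":
            selected_control = select_codes(prev_control, self.config)
        else:  # restrict controls to the case-selected candidates
            selected_control = sorted(set(selected_case) & set(self.control.codes))
        fit_case = self._fit_cohort(self.case, selected_case)
        fit_control = self._fit_cohort(self.control, selected_control)

        reg, reg_outliers = self._degree_regression(fit_case, fit_control)
        comparison = per_code_comparison(
            prev_case.loc[prev_case.index.isin(selected_case)],
            prev_control,
            self.case.n,
            self.control.n,
            correction=self.config.chi2_correction,
        )
        high_prev = high_prevalence_report(
            prev_case, prev_control, self.config, self.case.n, self.control.n
        )
        blocks_table = block_enrichment(self.case, self.control, self.blocks, self.config)
        counts_case = diagnosis_count_summary(self.case)
        counts_control = diagnosis_count_summary(self.control)
        return PDNResults(
            model=self,
            case=fit_case,
            control=fit_control,
            regression=reg,
            comparison=comparison,
            high_prevalence=high_prev,
            blocks=blocks_table,
            counts_case=counts_case,
            counts_control=counts_control,
        )

    def _degree_regression(
        self, fit_case: CohortFit, fit_control: CohortFit
    ) -> tuple[DegreeRegression | None, list[str]]:
        deg_case = fit_case.network.degree
        deg_control = fit_control.network.degree
        if self.config.regression_codes == "intersection":
            codes = sorted(set(deg_case) & set(deg_control))
        else:
            codes = sorted(set(deg_case) | set(deg_control))
        if len(codes) < 3:
            logger.warning("too few shared PDN codes for the degree regression")
            return None, []
        pre_case = _prefilter_degree(fit_case.edges)
        pre_control = _prefilter_degree(fit_control.edges)
        table = pd.DataFrame(
            {
                "control": [deg_control.get(c, pre_control.get(c, 0)) for c in codes],
                "case": [deg_case.get(c, pre_case.get(c, 0)) for c in codes],
            },
            index=pd.Index(codes, name="code"),
        )
        try:
            reg, ols_fit = degree_regression(table)
        except ValueError as err:
            logger.warning("degree regression skipped: %s", err)
            return None, []
        outliers = mean_shift_outliers(ols_fit, reg, level=self.config.alpha)
        return reg, outliers


def _prefilter_degree(edges: list[PhiEdge]) -> dict[str, int]:
    """Significant-edge counts before the >=2-edge pruning."""
    deg: dict[str, int] = {}
    for e in edges:
        if e.significant:
            deg[e.code_a] = deg.get(e.code_a, 0) + 1
            deg[e.code_b] = deg.get(e.code_b, 0) + 1
    return deg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PDNResults:
    """Fitted phenotypic disease networks and all cross-cohort statistics."""

    model: PDNModel
    case: CohortFit
    control: CohortFit
    regression: DegreeRegression | None
    comparison: pd.DataFrame
    high_prevalence: pd.DataFrame
    blocks: pd.DataFrame
    counts_case: dict
    counts_control: dict

    def headline(self) -> dict:
        """Scalar summary: network sizes, clusters, modularity, regression."""
        mean_control = self.counts_control["mean"]
        out = {
            "n_case": self.case.matrix.n,
            "n_control": self.control.matrix.n,
            "n_codes_total": len(set(self.case.matrix.codes) | set(self.control.matrix.codes)),
            "candidate_codes_case": len(self.case.selected_codes),
            "candidate_codes_control": len(self.control.selected_codes),
            "pdn_nodes_case": len(self.case.network.nodes),
            "pdn_nodes_control": len(self.control.network.nodes),
            "significant_edges_case": self.case.n_significant_edges,
            "significant_edges_control": self.control.n_significant_edges,
            "clusters_case": self.case.partition.n_clusters,
            "clusters_control": self.control.partition.n_clusters,
            "modularity_case": self.case.partition.modularity,
            "modularity_control": self.control.partition.modularity,
            "median_diagnoses_case": self.counts_case["median"],
            "median_diagnoses_control": self.counts_control["median"],
            "monodiagnosis_case": self.counts_case["monodiagnosis_fraction"],
            "monodiagnosis_control": self.counts_control["monodiagnosis_fraction"],
            "mean_diagnosis_fold": (
                self.counts_case["mean"] / mean_control if mean_control > 0 else float("nan")
            ),
            "enriched_blocks": int(self.blocks["enriched"].sum()) if len(self.blocks) else 0,
        }
        if self.regression is not None:
            out.update(
                {
                    "degree_slope": self.regression.slope,
                    "degree_intercept": self.regression.intercept,
                    "degree_r_squared": self.regression.r_squared,
                    "degree_outliers": list(self.regression.outliers),
                }
            )
        return out

    def summary(self) -> str:
        """Human-readable fit summary."""
        h = self.headline()
        lines = [
            "Phenotypic disease network fit",
            "=" * 46,
            f"{'cohort size (case / control)':38s} {h['n_case']} / {h['n_control']}",
            f"{'distinct 3-char codes':38s} {h['n_codes_total']}",
            f"{'candidate codes (prevalence window)':38s} "
            f"{h['candidate_codes_case']} / {h['candidate_codes_control']}",
            f"{'PDN nodes (>=2 significant edges)':38s} "
            f"{h['pdn_nodes_case']} / {h['pdn_nodes_control']}",
            f"{'significant phi correlations':38s} "
            f"{h['significant_edges_case']} / {h['significant_edges_control']}",
            f"{'Walktrap clusters':38s} {h['clusters_case']} / {h['clusters_control']}",
            f"{'modularity Q':38s} "
            f"{h['modularity_case']:.3f} / {h['modularity_control']:.3f}",
            f"{'median diagnoses per patient':38s} "
            f"{h['median_diagnoses_case']:.0f} / {h['median_diagnoses_control']:.0f}",
            f"{'monodiagnosis fraction':38s} "
            f"{h['monodiagnosis_case']:.1%} / {h['monodiagnosis_control']:.1%}",
            f"{'mean diagnosis-count fold change':38s} {h['mean_diagnosis_fold']:.2f}",
            f"{'enriched ICD-10 blocks':38s} {h['enriched_blocks']}",
        ]
        if self.regression is not None:
            lines += [
                f"{'degree regression slope':38s} {h['degree_slope']:.2f}",
                f"{'degree regression intercept':38s} {h['degree_intercept']:.2f}",
                f"{'degree regression R-squared':38s} {h['degree_r_squared']:.1%}",
                f"{'mean-shift outliers':38s} "
                + (", ".join(h["degree_outliers"]) or "none"),
            ]
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        """Write the full output tree; returns the output directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fit in (("case", self.case), ("control", self.control)):
            edges_to_frame(fit.edges).to_csv(out / f"edges_{name}.tsv", sep="\t", index=False)
            fit.prevalence.to_csv(out / f"prevalence_{name}.tsv", sep="\t")
            if len(fit.centrality):
                fit.centrality.to_csv(out / f"centrality_{name}.tsv", sep="\t")
            _write_partition(fit.partition, out / f"clusters_{name}.tsv")
            _write_merges(fit.partition, out / f"dendrogram_{name}.tsv")
            pd.Series(fit.network.removed, name="code").to_csv(
                out / f"removed_nodes_{name}.tsv", sep="\t", index=False
            )
            if fit.network.nodes:
                export_graphml(
                    fit.network,
                    fit.partition,
                    out / f"pdn_{name}.graphml",
                    viz_threshold=self.model.config.viz_phi_threshold,
                )
        self.comparison.to_csv(out / "comparison_per_code.tsv", sep="\t")
        self.high_prevalence.to_csv(out / "high_prevalence.tsv", sep="\t")
        self.blocks.to_csv(out / "block_enrichment.tsv", sep="\t")
        if self.regression is not None:
            self.regression.residuals.to_csv(out / "degree_regression.tsv", sep="\t")
        for name, counts in (("case", self.counts_case), ("control", self.counts_control)):
            counts["histogram"].rename("patients").to_csv(
                out / f"diagnosis_counts_{name}.tsv", sep="\t", index_label="n_diagnoses"
            )
        with open(out / "summary.json", "w") as fh:
            json.dump(self.headline(), fh, indent=2, default=float)
        with open(out / "manifest.json", "w") as fh:
            json.dump(
                {
                    "version": __version__,
                    "config": self.model.config.to_dict(),
                    "inputs": self.model.input_digests,
                    "counts": {
                        "records_case": int(self.case.matrix.incidence.sum()),
                        "records_control": int(self.control.matrix.incidence.sum()),
                        "pdn_nodes_case": len(self.case.network.nodes),
                        "pdn_nodes_control": len(self.control.network.nodes),
                        "pdn_edges_case": len(self.case.network.edges),
                        "pdn_edges_control": len(self.control.network.edges),
                    },
                },
                fh,
                indent=2,
            )
        return out


def _write_partition(partition: Partition, path) -> None:
    clusters = partition.clusters()
    rows = [
        {"code": code, "cluster_id": cid, "cluster_size": len(members)}
        for cid, members in sorted(clusters.items())
        for code in members
    ]
    pd.DataFrame(rows, columns=["code", "cluster_id", "cluster_size"]).to_csv(
        path, sep="\t", index=False
    )


def _write_merges(partition: Partition, path) -> None:
    pd.DataFrame(
        partition.merges, columns=["community_a", "community_b", "dsigma"]
    ).to_csv(path, sep="\t", index=False)
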