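"""Analysis configuration: every filtering threshold in one place.

Defaults follow the study conditions: nodes kept at 2.5-20% prevalence,
pairwise significance level 0.05, at least two significant correlations per
retained code, random-walk length 4, 0.04 phi threshold for visualization
flagging, and block-level reporting above 2% prevalence with >=1.5-fold
enrichment.  Nothing is hard-coded elsewhere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    min_prev: float = 0.025          # inclusive lower prevalence bound
    max_prev: float = 0.20           # inclusive upper bound; > max_prev reported separately
    alpha: float = 0.05              # pairwise phi significance level
    min_significant_edges: int = 2   # iterative degree floor for retained nodes
    viz_phi_threshold: float = 0.04  # metadata flag only; edges above it marked for drawing
    walk_length: int = 4             # random-walk steps in Walktrap
    block_min_prev: float = 0.02     # strict > floor for block enrichment
    block_min_fold: float = 1.5      # inclusive >= fold for block enrichment
    chi2_correction: bool = True     # Yates continuity correction on 2x2 tables
    control_selection: str = "own"   # "own": control window on control prevalences;
                                     # "case": restrict controls to case-selected codes
    regression_codes: str = "intersection"  # or "union"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_prev < self.max_prev <= 1):
            raise ValueError("need 0 < min_prev < max_prev <= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_significant_edges < 0:
            raise ValueError("min_significant_edges must be >= 0")
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.control_selection not in ("own", "case"):
            raise ValueError("control_selection must be 'own' or 'case'")
        if self.regression_codes not in ("intersection", "union"):
            raise ValueError("regression_codes must be 'intersection' or 'union'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = cls.__dataclass_fields__.keys()
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
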