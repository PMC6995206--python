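"""Synthetic matched case/control cohorts with planted comorbidity structure.

Real occupational-healthcare diagnosis data are access-restricted, so this
generator provides ground truth for every pipeline stage.  It emulates the
shape of such data: two equal-size cohorts, a long right tail of rare codes
that never reach the analysis prevalence floor, latent diagnosis modules
that induce positive within-module phi correlations, and a global
case-cohort prevalence inflation.

The model is independent-activation: each patient activates each latent
module c with probability pi_c (z_c ~ Bernoulli); a code d belonging to
module c is then present with probability

    clip(base_prev_d * rho_cohort + beta * z_c)

where rho is the case-cohort marginal inflation (rho_control = 1) and beta
the within-module boost.  Noise codes are independent Bernoulli at
base_prev * rho; rare-tail codes sit below the prevalence floor.  All
marginals and fold changes are therefore available in closed form for test
assertions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .records import CASE, CONTROL, CohortMatrix, DiagnosisRecord

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "truth_report", "write_records"]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults mirror the study conditions
    (17,623 patients per cohort, 1337 distinct codes, nine latent modules,
    ~1.5x case prevalence inflation)."""

    n_per_cohort: int = 17_623
    n_codes: int = 1337
    n_clusters: int = 9
    codes_per_cluster: int = 12
    base_prev: tuple[float, float] = (0.03, 0.12)   # module-code marginals (control)
    cluster_activation: float = 0.30                # pi: P(module active in a patient)
    within_boost: float = 0.15                      # beta: added P(code | module active)
    case_inflation: float = 1.5                     # rho: case marginal multiplier
    n_noise_codes: int = 80
    noise_prev: tuple[float, float] = (0.03, 0.15)  # independent mid-prevalence codes
    rare_tail_prev: tuple[float, float] = (0.0005, 0.012)  # below the 2.5% floor
    seed: int = 0

    @property
    def n_module_codes(self) -> int:
        return self.n_clusters * self.codes_per_cluster

    @property
    def n_rare_codes(self) -> int:
        return self.n_codes - self.n_module_codes - self.n_noise_codes

    def __post_init__(self) -> None:
        if self.n_rare_codes < 0:
            raise ValueError("n_codes too small for modules + noise codes")
        for name in ("cluster_activation", "within_boost"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.case_inflation <= 0:
            raise ValueError("case_inflation must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the records."""

    config: SyntheticConfig
    codes: list[str]
    module: dict[str, str]                 # code -> "M1".."MK" | "NONE" | "RARE"
    base_prev: dict[str, float]
    expected_prev_case: dict[str, float]
    expected_prev_control: dict[str, float]

    def expected_fold(self, code: str) -> float:
        ctrl = self.expected_prev_control[code]
        return self.expected_prev_case[code] / ctrl if ctrl > 0 else float("nan")


def _code_labels(n: int) -> list[str]:
    """Synthetic ICD-10-shaped labels: A00, A01, ..., B00, ..."""
    if n > 2600:
        raise ValueError("at most 2600 synthetic codes")
    return [f"{chr(ord('A') + i // 100)}{i % 100:02d}" for i in range(n)]


def _expected_prev(p: float, rho: float, beta: float, pi: float, in_module: bool) -> float:
    base = min(1.0, p * rho)
    if not in_module:
        return base
    return (1 - pi) * base + pi * min(1.0, p * rho + beta)


def generate(
    config: SyntheticConfig,
) -> tuple[list[DiagnosisRecord], list[DiagnosisRecord], SyntheticTruth]:
    """Draw both cohorts; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    codes = _code_labels(config.n_codes)
    k, cpc = config.n_clusters, config.codes_per_cluster
    module: dict[str, str] = {}
    base: dict[str, float] = {}
    for i, code in enumerate(codes):
        if i < k * cpc:
            module[code] = f"M{i // cpc + 1}"
            base[code] = float(rng.uniform(*config.base_prev))
        elif i < k * cpc + config.n_noise_codes:
            module[code] = "NONE"
            base[code] = float(rng.uniform(*config.noise_prev))
        else:
            module[code] = "RARE"
            base[code] = float(rng.uniform(*config.rare_tail_prev))
    base_arr = np.array([base[c] for c in codes])
    module_idx = np.array(
        [int(module[c][1:]) - 1 if module[c].startswith("M") else -1 for c in codes]
    )

    def draw(n: int, rho: float) -> np.ndarray:
        marg = np.minimum(1.0, base_arr * rho)
        if (base_arr * rho > 1).any():
            import warnings

            warnings.warn("composed probability > 1 clipped", stacklevel=2)
        z = rng.random((n, k)) < config.cluster_activation  # module activations
        prob = np.tile(marg, (n, 1))
        in_module = module_idx >= 0
        boost = np.where(in_module, config.within_boost, 0.0)
        active = np.zeros((n, len(codes)), dtype=bool)
        active[:, in_module] = z[:, module_idx[in_module]]
        prob = np.minimum(1.0, prob + boost * active)
        return (rng.random((n, len(codes))) < prob).astype(np.uint8)

    inc_case = draw(config.n_per_cohort, config.case_inflation)
    inc_control = draw(config.n_per_cohort, 1.0)

    def to_records(inc: np.ndarray, cohort: str, prefix: str) -> list[DiagnosisRecord]:
        recs = []
        rows, cols = np.nonzero(inc)
        for r, c in zip(rows.tolist(), cols.tolist()):
            recs.append(DiagnosisRecord(f"{prefix}{r:05d}", cohort, codes[c]))
        return recs

    records_case = to_records(inc_case, CASE, "M")
    records_control = to_records(inc_control, CONTROL, "C")
    pi = config.cluster_activation
    truth = SyntheticTruth(
        config=config,
        codes=codes,
        module=module,
        base_prev=base,
        expected_prev_case={
            c: _expected_prev(base[c], config.case_inflation, config.within_boost, pi, module[c].startswith("M"))
            for c in codes
        },
        expected_prev_control={
            c: _expected_prev(base[c], 1.0, config.within_boost, pi, module[c].startswith("M"))
            for c in codes
        },
    )
    return records_case, records_control, truth


def rosters(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Enrolment rosters matching the generated patient ids."""
    return (
        [f"M{i:05d}" for i in range(config.n_per_cohort)],
        [f"C{i:05d}" for i in range(config.n_per_cohort)],
    )


def matrices(
    records_case: list[DiagnosisRecord],
    records_control: list[DiagnosisRecord],
    config: SyntheticConfig,
) -> tuple[CohortMatrix, CohortMatrix]:
    """Convenience: pivot generated records into the two incidence matrices."""
    from .records import build_matrix

    roster_case, roster_control = rosters(config)
    return (
        build_matrix(records_case, CASE, roster_case),
        build_matrix(records_control, CONTROL, roster_control),
    )


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Machine-readable per-code ground truth for test assertions."""
    rows = []
    for code in truth.codes:
        rows.append(
            {
                "code": code,
                "module": truth.module[code],
                "base_prev": truth.base_prev[code],
                "expected_prev_case": truth.expected_prev_case[code],
                "expected_prev_control": truth.expected_prev_control[code],
                "expected_fold": truth.expected_fold(code),
            }
        )
    return pd.DataFrame(rows).set_index("code")


def write_records(records: list[DiagnosisRecord], path) -> None:
    """Write records in the CSV dialect ``records.read_records`` consumes."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id,cohort,icd10,date\n")
        for r in records:
            fh.write(f"{r.patient_id},{r.cohort},{r.code},{r.date.isoformat() if r.date else ''}\n")


def write_truth(truth: SyntheticTruth, tsv_path, json_path) -> None:
    truth_report(truth).to_csv(tsv_path, sep="\t")
    payload = asdict(truth.config) | {"n_module_codes": truth.config.n_module_codes}
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
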