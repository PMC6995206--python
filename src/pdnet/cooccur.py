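"""Prevalences, pairwise phi coefficients and their significance.

The phi coefficient is the Pearson product-moment correlation of two binary
indicators, computable from the 2x2 co-occurrence table.  With marginal
counts n_a, n_b, joint count n11 and cohort size n:

    phi = (n * n11 - n_a * n_b) / sqrt(n_a * n_b * (n - n_a) * (n - n_b))

Significance follows the usual correlation t-transform,
t = phi * sqrt(n - 2) / sqrt(1 - phi^2), two-sided against Student-t with
n - 2 degrees of freedom.  No multiple-testing correction is applied to the
pairwise tests; a flat significance level (default 0.05) is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import CohortMatrix

__all__ = ["PhiEdge", "prevalence", "phi", "phi_significance", "all_pairs", "edges_to_frame"]


@dataclass(frozen=True)
class PhiEdge:
    """An unordered diagnosis-code pair with its phi coefficient and test."""

    code_a: str
    code_b: str
    n11: int
    n_a: int
    n_b: int
    phi: float
    t_stat: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.code_a >= self.code_b:
            raise ValueError("edge codes must satisfy code_a < code_b")


def prevalence(matrix: CohortMatrix) -> pd.DataFrame:
    """Per-code patient counts and prevalences (fractions of cohort n)."""
    if matrix.n < 1:
        raise ValueError("cohort must contain at least one patient")
    counts = matrix.incidence.sum(axis=0).astype(int)
    return pd.DataFrame(
        {"count": counts, "prevalence": counts / matrix.n},
        index=pd.Index(matrix.codes, name="code"),
    )


def phi(n11: int, n_a: int, n_b: int, n: int) -> float:
    """Phi coefficient from the 2x2 table margins.

    Returns ``nan`` when either marginal is 0 or n (undefined denominator);
    such pairs are excluded downstream.
    """
    if not (0 <= n11 <= min(n_a, n_b)) or n_a > n or n_b > n:
        raise ValueError(f"inconsistent table: n11={n11}, n_a={n_a}, n_b={n_b}, n={n}")
    if n_a in (0, n) or n_b in (0, n):
        return float("nan")
    num = n * n11 - n_a * n_b
    den = np.sqrt(float(n_a) * n_b * (n - n_a) * (n - n_b))
    return num / den


def phi_significance(
    phi_value: float, n: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """t statistic, two-sided p and significance flag for a phi value.

    Uses t = phi * sqrt(n-2) / sqrt(1 - phi^2) with n-2 df.  |phi| = 1 is a
    degenerate limit: p = 0, significant.
    """
    if n < 3:
        raise ValueError("need n >= 3 for the t test")
    if abs(phi_value) >= 1.0:
        return float(np.sign(phi_value)) * np.inf, 0.0, True
    t = phi_value * np.sqrt(n - 2) / np.sqrt(1.0 - phi_value**2)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(p), bool(p < alpha)


def all_pairs(
    matrix: CohortMatrix,
    codes: list[str] | None = None,
    alpha: float = 0.05,
) -> list[PhiEdge]:
    """Phi edges for every unordered pair of the selected codes.

    Pairs where either code's marginal is 0 or n (phi undefined) are
    dropped.  Output order is lexicographic by (code_a, code_b).
    """
    if codes is None:
        codes = list(matrix.codes)
    unknown = set(codes) - set(matrix.codes)
    if unknown:
        raise ValueError(f"codes not in matrix: {sorted(unknown)}")
    codes = sorted(codes)
    n = matrix.n
    col = {c: j for j, c in enumerate(matrix.codes)}
    sub = matrix.incidence[:, [col[c] for c in codes]].astype(np.int64)
    marg = sub.sum(axis=0)
    # joint counts in one matmul; D is a few hundred at most
    joint = sub.T @ sub
    edges: list[PhiEdge] = []
    for i, a in enumerate(codes):
        if marg[i] in (0, n):
            continue
        for j in range(i + 1, len(codes)):
            if marg[j] in (0, n):
                continue
            b = codes[j]
            ph = phi(int(joint[i, j]), int(marg[i]), int(marg[j]), n)
            t, p, sig = phi_significance(ph, n, alpha)
            edges.append(
                PhiEdge(a, b, int(joint[i, j]), int(marg[i]), int(marg[j]), ph, t, p, sig)
            )
    return edges


def edges_to_frame(edges: list[PhiEdge]) -> pd.DataFrame:
    """Edge list as a DataFrame (the TSV writer's payload)."""
    return pd.DataFrame(
        [
            {
                "code_a": e.code_a,
                "code_b": e.code_b,
                "n11": e.n11,
                "n_a": e.n_a,
                "n_b": e.n_b,
                "phi": e.phi,
                "t": e.t_stat,
                "p": e.p_value,
                "significant": e.significant,
            }
            for e in edges
        ]
    )
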