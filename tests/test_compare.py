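"""Cross-cohort statistics: fold changes, chi-squared, degree regression,
mean-shift outliers, block enrichment and diagnosis-count summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pdnet.compare import (
    block_enrichment,
    chi_square_prevalence,
    degree_regression,
    diagnosis_count_summary,
    fold_change,
    mean_shift_outliers,
)
from pdnet.config import AnalysisConfig
from pdnet.records import CASE, CONTROL, BlockMap, CohortMatrix


class TestFoldChange:
    @pytest.mark.parametrize(
        "case_prev,control_prev,expected",
        [(18.10, 4.10, 4.41), (19.50, 5.90, 3.31), (5.0, 5.0, 1.00)],
    )
    def test_rounded_examples(self, case_prev, control_prev, expected):
        assert round(fold_change(case_prev, control_prev), 2) == expected

    def test_zero_control_is_nan(self):
        assert np.isnan(fold_change(1.0, 0.0))

    def test_reciprocal_product_is_one(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 30, size=2)
            assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


class TestChiSquare:
    def test_identical_counts_null(self):
        stat, p = chi_square_prevalence(50, 1000, 50, 1000, correction=False)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_table_reconstructed_from_reported_prevalences(self):
        # headache-type code: 18.1% of 17,623 cases vs 4.1% of controls
        stat, p = chi_square_prevalence(3190, 17623, 723, 17623)
        assert p < 0.001

    def test_closed_form_without_correction(self):
        a, b, c, d = 10, 90, 20, 80
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = chi_square_prevalence(10, 100, 20, 100, correction=False)
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_zero_margin_is_nan(self):
        stat, p = chi_square_prevalence(0, 100, 0, 100)
        assert np.isnan(stat) and np.isnan(p)


class TestDegreeRegression:
    def test_identity(self):
        deg = pd.DataFrame({"control": [1, 2, 3, 4.0], "case": [1, 2, 3, 4.0]})
        reg, _ = degree_regression(deg)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_noiseless_line(self):
        x = np.arange(10.0)
        deg = pd.DataFrame({"control": x, "case": 2 * x + 3})
        reg, _ = degree_regression(deg)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(3.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        deg = pd.DataFrame({"control": [2, 2, 2.0], "case": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            degree_regression(deg)


class TestMeanShiftOutliers:
    def _fixture(self, displace: float = 0.0, seed: int = 7, n: int = 30):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 20, n)
        y = 1.5 * x + 2 + rng.normal(0, 1.0, n)
        if displace:
            y[n // 2] += displace
        codes = [f"N{i:02d}" for i in range(n)]
        return pd.DataFrame({"control": x, "case": y}, index=pd.Index(codes, name="code"))

    def test_clean_line_has_no_outliers(self):
        deg = self._fixture()
        reg, fit = degree_regression(deg)
        assert mean_shift_outliers(fit, reg) == []

    def test_displaced_point_flagged(self):
        deg = self._fixture(displace=10.0)
        reg, fit = degree_regression(deg)
        assert mean_shift_outliers(fit, reg) == ["N15"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_dummy_variable_oracle(self, seed):
        """Mean-shift p equals the per-point indicator-coefficient p."""
        deg = self._fixture(displace=5.0, seed=seed)
        reg, fit = degree_regression(deg)
        mean_shift_outliers(fit, reg)
        x = deg["control"].to_numpy()
        y = deg["case"].to_numpy()
        for i, code in enumerate(deg.index):
            dummy = np.zeros(len(deg))
            dummy[i] = 1.0
            design = sm.add_constant(np.column_stack([x, dummy]))
            oracle = sm.OLS(y, design).fit()
            assert reg.residuals.loc[code, "p"] == pytest.approx(oracle.pvalues[2], abs=1e-9)

    def test_bonferroni_multiplier_and_cap(self):
        deg = self._fixture(displace=4.0)
        reg, fit = degree_regression(deg)
        mean_shift_outliers(fit, reg)
        m = len(deg)
        expected = np.minimum(reg.residuals["p"] * m, 1.0)
        assert np.allclose(reg.residuals["p_bonf"], expected)


def tiny_matrix(cohort, columns: dict[str, list[int]], n: int) -> CohortMatrix:
    codes = sorted(columns)
    inc = np.zeros((n, len(codes)), dtype=np.uint8)
    for j, c in enumerate(codes):
        inc[columns[c], j] = 1
    prefix = "M" if cohort == CASE else "C"
    return CohortMatrix(cohort, [f"{prefix}{i}" for i in range(n)], codes, inc)


class TestBlockEnrichment:
    def test_patient_counted_once_per_block(self):
        # H53 and H54 share a block; patient 0 has both
        case = tiny_matrix(CASE, {"H53": [0, 1, 2, 3], "H54": [0, 4, 5]}, 100)
        control = tiny_matrix(CONTROL, {"H53": [0], "H54": [1]}, 100)
        table = block_enrichment(case, control, BlockMap.default(), AnalysisConfig())
        assert table.loc["H53-H54", "prev_case"] == pytest.approx(0.06)
        assert table.loc["H53-H54", "prev_control"] == pytest.approx(0.02)

    def test_enrichment_boundaries(self):
        cfg = AnalysisConfig()
        # case prevalence exactly 2% -> not enriched (strict >)
        case = tiny_matrix(CASE, {"F32": list(range(20))}, 1000)
        control = tiny_matrix(CONTROL, {"F32": list(range(5))}, 1000)
        table = block_enrichment(case, control, BlockMap.default(), cfg)
        assert not bool(table.loc["F30-F39", "enriched"])
        # above floor with fold >= 1.5 and significant -> enriched
        case2 = tiny_matrix(CASE, {"F32": list(range(90))}, 1000)
        control2 = tiny_matrix(CONTROL, {"F32": list(range(30))}, 1000)
        table2 = block_enrichment(case2, control2, BlockMap.default(), cfg)
        row = table2.loc["F30-F39"]
        assert bool(row["enriched"]) and row["fold_change"] == pytest.approx(3.0)

    def test_block_prevalence_bounds(self, rng):
        cols_case = {c: sorted(rng.choice(200, size=rng.integers(5, 40), replace=False).tolist()) for c in ("H53", "H54")}
        case = tiny_matrix(CASE, cols_case, 200)
        control = tiny_matrix(CONTROL, {"H53": [0, 1], "H54": [2]}, 200)
        table = block_enrichment(case, control, BlockMap.default(), AnalysisConfig())
        member_prev = [len(v) / 200 for v in cols_case.values()]
        block_prev = table.loc["H53-H54", "prev_case"]
        assert max(member_prev) <= block_prev <= sum(member_prev) + 1e-12


class TestDiagnosisCounts:
    def test_all_monodiagnosis(self):
        m = tiny_matrix(CASE, {"A00": [0], "B00": [1], "C00": [2]}, 3)
        s = diagnosis_count_summary(m)
        assert s["median"] == 1 and s["monodiagnosis_fraction"] == 1.0

    def test_counts_median(self):
        m = tiny_matrix(
            CASE,
            {f"A{j:02d}": [i for i in range(3) if j < (i + 1) * 2] for j in range(6)},
            3,
        )
        s = diagnosis_count_summary(m)
        assert sorted(s["counts"].tolist()) == [2, 4, 6]
        assert s["median"] == 4 and s["monodiagnosis_fraction"] == 0.0
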