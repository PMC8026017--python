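import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from narragraph.stats import (
    ATTRIBUTE_COLUMNS,
    SYMPTOM_COLUMNS,
    ConstantInputError,
    RankDeficiencyError,
    bonferroni_threshold,
    build_cohort_table,
    correlation_frame,
    correlation_table,
    partial_spearman,
    spearman,
)

from oracles import partial_spearman_inversion


class TestSpearman:
    def test_perfect_monotone(self):
        r, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0)

    def test_perfect_antitone(self):
        r, _ = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_formula_example(self):
        # sum of squared rank differences = 4 -> 1 - 6*4/(5*24) = 0.8
        r, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert r == pytest.approx(0.8)

    def test_matches_scipy(self, rng):
        for _ in range(50):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            r, p = spearman(x, y)
            r_sp, p_sp = sps.spearmanr(x, y)
            assert r == pytest.approx(r_sp, abs=1e-12)
            assert p == pytest.approx(p_sp, abs=1e-10)

    def test_ties_use_midranks(self, rng):
        x = rng.integers(0, 4, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        r, _ = spearman(x, y)
        assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_symmetric(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0])


class TestPartialSpearman:
    def test_identity_with_independent_covariate(self, rng):
        x = rng.normal(size=20)
        z = rng.normal(size=(20, 1))
        r, p, n = partial_spearman(x, x.copy(), z)
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_empty_covariates_equals_spearman(self, rng):
        for _ in range(100):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r0, p0 = spearman(x, y)
            r1, p1, _ = partial_spearman(x, y, None)
            r2, p2, _ = partial_spearman(x, y, np.empty((12, 0)))
            assert (r1, p1) == (r0, p0)
            assert (r2, p2) == (r0, p0)

    def test_fixed_eight_subject_table_vs_inversion_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0]
        z = [[1.0], [4.0], [1.0], [5.0], [9.0], [2.0], [6.0], [5.0]]
        r, p, n = partial_spearman(x, y, z)
        r_o, p_o = partial_spearman_inversion(x, y, z)
        assert r == pytest.approx(r_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)
        assert n == 8

    def test_oracle_agreement_random(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 4))
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            z = rng.normal(size=(20, k))
            r, p, _ = partial_spearman(x, y, z)
            r_o, p_o = partial_spearman_inversion(x, y, z)
            assert r == pytest.approx(r_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)

    def test_removes_injected_confound(self, rng):
        # x and y share only a common driver z; controlling for z kills r
        z = rng.normal(size=200)
        x = z + 0.1 * rng.normal(size=200)
        y = z + 0.1 * rng.normal(size=200)
        r_raw, _ = spearman(x, y)
        r_ctl, _, _ = partial_spearman(x, y, z.reshape(-1, 1))
        assert r_raw > 0.9
        assert abs(r_ctl) < 0.2

    def test_collinear_covariates_raise(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        z1 = rng.normal(size=15)
        z = np.column_stack([z1, z1])
        with pytest.raises(RankDeficiencyError):
            partial_spearman(x, y, z)

    def test_degenerate_control_raises(self, rng):
        z = rng.normal(size=15)
        x = rng.normal(size=15)
        with pytest.raises(ConstantInputError):
            partial_spearman(x, z.copy(), z.reshape(-1, 1))

    def test_insufficient_n_raises(self, rng):
        with pytest.raises(ValueError):
            partial_spearman(
                rng.normal(size=4), rng.normal(size=4), rng.normal(size=(4, 2))
            )


class TestBonferroni:
    def test_paper_threshold(self):
        assert bonferroni_threshold(0.05, 4) == 0.0125

    def test_identity(self):
        assert bonferroni_threshold(0.01, 1) == 0.01

    def test_five_way(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    @pytest.mark.parametrize("alpha,m", [(0.0, 4), (1.0, 4), (0.05, 0), (0.05, -1)])
    def test_validation(self, alpha, m):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, m)


def _toy_cohort(rng, n=24):
    symptoms = np.arange(n) % 19
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "TNW": rng.normal(150, 20, size=n),
            "RE": rng.normal(2, 0.5, size=n),
            "L1": symptoms * 0.5 + 1.0,  # strictly increasing in symptoms
            "LSC": rng.normal(8, 2, size=n),
            "ASP": rng.normal(3, 0.4, size=n),
            "symptoms_total": symptoms.astype(float),
            "symptoms_inattention": rng.integers(0, 10, size=n).astype(float),
            "symptoms_hyperactivity": rng.integers(0, 10, size=n).astype(float),
            "age": rng.normal(26, 5, size=n),
            "iq": rng.normal(110, 10, size=n),
        }
    )
    return df


class TestCorrelationTable:
    def test_grid_shape_and_flags(self, rng):
        results = correlation_table(_toy_cohort(rng))
        assert len(results) == 15
        cells = {(r.attribute, r.scale) for r in results}
        assert cells == {
            (a, s) for a in ATTRIBUTE_COLUMNS for s in SYMPTOM_COLUMNS
        }
        for r in results:
            thr = 0.0125 if r.attribute != "TNW" else 0.05
            assert r.threshold == thr
            assert r.significant_bonferroni == (r.p < thr)

    def test_perfect_monotone_cell(self, rng):
        results = correlation_table(_toy_cohort(rng))
        cell = next(
            r for r in results
            if r.attribute == "L1" and r.scale == "symptoms_total"
        )
        assert cell.r == pytest.approx(1.0)
        assert cell.significant_bonferroni

    def test_partial_route_used_with_covariates(self, rng):
        cohort = _toy_cohort(rng)
        plain = correlation_table(cohort)
        partial = correlation_table(cohort, covariates=("age", "iq"))
        assert all(r.covariates == ("age", "iq") for r in partial)
        # different degrees of freedom => different p for same data
        p0 = next(r.p for r in plain if r.attribute == "RE" and r.scale == "symptoms_total")
        p1 = next(r.p for r in partial if r.attribute == "RE" and r.scale == "symptoms_total")
        assert p0 != p1

    def test_constant_column_names_offender(self, rng):
        cohort = _toy_cohort(rng)
        cohort["symptoms_hyperactivity"] = 3.0
        with pytest.raises(ConstantInputError, match="symptoms_hyperactivity"):
            correlation_table(cohort)

    def test_missing_column_raises(self, rng):
        cohort = _toy_cohort(rng).drop(columns=["ASP"])
        with pytest.raises(ValueError, match="ASP"):
            correlation_table(cohort)

    def test_nan_raises(self, rng):
        cohort = _toy_cohort(rng)
        cohort.loc[0, "RE"] = np.nan
        with pytest.raises(ValueError, match="RE"):
            correlation_table(cohort)

    def test_correlation_frame_columns(self, rng):
        df = correlation_frame(correlation_table(_toy_cohort(rng)))
        assert list(df.columns) == [
            "attribute", "scale", "r", "p", "n", "covariates",
            "threshold", "significant",
        ]
        assert len(df) == 15


class TestBuildCohortTable:
    def test_merge_and_scoring(self, rng):
        profiles = pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3", "s4"],
                "TNW": [100, 120, 140, 160],
                "RE": [1.0, 2.0, 3.0, 4.0],
                "L1": [0.5, 1.5, 2.5, 3.5],
                "LSC": [9, 8, 7, 6],
                "ASP": [3.1, 3.2, 3.3, 3.4],
            }
        )
        meta_rows = []
        for i, sid in enumerate(["s1", "s2", "s3", "s4"]):
            row = {"subject_id": sid, "age": 25 + i, "iq": 100 + i}
            for j in range(1, 19):
                row[f"asrs_{j:02d}"] = 2 if j <= i else 0
            meta_rows.append(row)
        cohort = build_cohort_table(profiles, pd.DataFrame(meta_rows))
        assert list(cohort["symptoms_total"]) == [0, 1, 2, 3]
        assert "age" in cohort.columns
        assert "asrs_01" not in cohort.columns
        assert len(cohort) == 4

    def test_missing_asrs_columns_raise(self):
        profiles = pd.DataFrame({"subject_id": ["s1"], "TNW": [100]})
        meta = pd.DataFrame({"subject_id": ["s1"], "age": [25]})
        with pytest.raises(ValueError, match="asrs"):
            build_cohort_table(profiles, meta)
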