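"""Statistical battery against closed-form and nested-model oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from axotrace import stats as st
from axotrace import phantoms as ph
from axotrace.errors import (
    DegenerateDataError,
    DegenerateDesignError,
    InsufficientDataError,
    PairingError,
    UnknownLevelError,
)


def long_table(cell_values: dict) -> pd.DataFrame:
    """Build a long-format table from {(a_level, b_level): [values]}."""
    rows = []
    for (a, b), vals in cell_values.items():
        for v in vals:
            rows.append({"label": a, "group": b, "value": float(v)})
    return pd.DataFrame(rows)


def balanced_2x2_oracle(cells: dict):
    """Textbook balanced two-way decomposition (equal n per cell)."""
    data = {k: np.asarray(v, float) for k, v in cells.items()}
    a_levels = sorted({k[0] for k in data})
    b_levels = sorted({k[1] for k in data})
    n = len(next(iter(data.values())))
    grand = np.mean([v for vals in data.values() for v in vals])
    a_means = {a: np.mean([data[(a, b)] for b in b_levels]) for a in a_levels}
    b_means = {b: np.mean([data[(a, b)] for a in a_levels]) for b in b_levels}
    ss_a = n * len(b_levels) * sum((a_means[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((b_means[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (data[(a, b)].mean() - a_means[a] - b_means[b] + grand) ** 2
        for a in a_levels for b in b_levels)
    ss_err = sum(((data[(a, b)] - data[(a, b)].mean()) ** 2).sum()
                 for a in a_levels for b in b_levels)
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = len(a_levels) * len(b_levels) * (n - 1)
    mse = ss_err / df_err
    return {
        "label": (ss_a, df_a, (ss_a / df_a) / mse),
        "group": (ss_b, df_b, (ss_b / df_b) / mse),
        "label:group": (ss_ab, df_ab, (ss_ab / df_ab) / mse),
        "residual": (ss_err, df_err),
    }


def type2_nested_model_oracle(table: pd.DataFrame):
    """Type II SS by residual-SS differences between nested OLS fits."""
    y = table["value"].to_numpy(float)

    def dummies(col):
        levels = sorted(table[col].unique())
        return np.column_stack([
            (table[col] == lv).to_numpy(float) for lv in levels[1:]
        ])

    A = dummies("label")
    B = dummies("group")
    AB = np.column_stack([A[:, i] * B[:, j]
                          for i in range(A.shape[1])
                          for j in range(B.shape[1])])
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_ab = rss(np.hstack([ones, A, B]))
    rss_a = rss(np.hstack([ones, A]))
    rss_b = rss(np.hstack([ones, B]))
    rss_full = rss(np.hstack([ones, A, B, AB]))
    ss_a = rss_b - rss_ab          # label after group
    ss_b_ = rss_a - rss_ab         # group after label
    ss_ab = rss_ab - rss_full
    df_full = len(y) - (1 + A.shape[1] + B.shape[1] + AB.shape[1])
    mse = rss_full / df_full
    return {
        "label": (ss_a, A.shape[1], (ss_a / A.shape[1]) / mse),
        "group": (ss_b_, B.shape[1], (ss_b_ / B.shape[1]) / mse),
        "label:group": (ss_ab, AB.shape[1], (ss_ab / AB.shape[1]) / mse),
        "residual": (rss_full, df_full),
    }


class TestFactorialAnova:
    def test_equal_cell_means_give_zero_f(self):
        cells = {(a, b): [10.0 + d for d in (-1, 0, 1)]
                 for a in "XY" for b in "PQ"}
        res = st.factorial_anova(long_table(cells))
        for eff in res.effects.values():
            assert eff.f == pytest.approx(0.0, abs=1e-12)

    def test_balanced_2x2_matches_closed_form(self):
        cells = {("X", "P"): [3, 5, 4], ("X", "Q"): [8, 9, 10],
                 ("Y", "P"): [1, 2, 3], ("Y", "Q"): [6, 5, 7]}
        res = st.factorial_anova(long_table(cells))
        oracle = balanced_2x2_oracle(cells)
        for name in ("label", "group", "label:group"):
            ss, df, f = oracle[name]
            assert res.effects[name].ss == pytest.approx(ss, abs=1e-10)
            assert res.effects[name].df == df
            assert res.effects[name].f == pytest.approx(f, abs=1e-10)
        assert res.residual_ss == pytest.approx(oracle["residual"][0], abs=1e-10)
        assert res.residual_df == oracle["residual"][1]

    def test_unbalanced_type2_matches_nested_models(self, rng):
        cells = {
            ("X", "P"): rng.normal(10, 2, 6), ("X", "Q"): rng.normal(12, 2, 9),
            ("X", "R"): rng.normal(9, 2, 7), ("Y", "P"): rng.normal(11, 2, 8),
            ("Y", "Q"): rng.normal(8, 2, 6), ("Y", "R"): rng.normal(13, 2, 9),
        }
        table = long_table({k: list(v) for k, v in cells.items()})
        res = st.factorial_anova(table)
        oracle = type2_nested_model_oracle(table)
        for name in ("label", "group", "label:group"):
            ss, df, f = oracle[name]
            assert res.effects[name].ss == pytest.approx(ss, abs=1e-10)
            assert res.effects[name].f == pytest.approx(f, abs=1e-10)
            # p from the F distribution at the same dfs
            p = sps.f.sf(f, df, oracle["residual"][1])
            assert res.effects[name].p == pytest.approx(p, abs=1e-10)

    def test_single_level_factor_rejected(self):
        cells = {("X", "P"): [1, 2], ("X", "Q"): [3, 4]}
        with pytest.raises(DegenerateDesignError):
            st.factorial_anova(long_table(cells))

    def test_saturated_design_rejected(self):
        cells = {(a, b): [1.0] for a in "XY" for b in "PQ"}
        with pytest.raises(InsufficientDataError):
            st.factorial_anova(long_table(cells))


class TestFisherLSD:
    @staticmethod
    def _three_group_table():
        cells = {("X", "P"): [10, 11, 12, 9], ("X", "Q"): [10, 11, 12, 9],
                 ("X", "R"): [20, 21, 19, 22],
                 ("Y", "P"): [10, 12, 11, 9], ("Y", "Q"): [10, 12, 11, 9],
                 ("Y", "R"): [21, 20, 22, 19]}
        return long_table(cells)

    def test_identical_groups_give_t0_p1(self):
        table = self._three_group_table()
        anova = st.factorial_anova(table)
        res = st.fisher_lsd(table, anova, "group")
        pq = next(r for r in res if {r.level_a, r.level_b} == {"P", "Q"})
        assert pq.t == pytest.approx(0.0, abs=1e-12)
        assert pq.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula(self):
        table = self._three_group_table()
        anova = st.factorial_anova(table)
        res = st.fisher_lsd(table, anova, "group")
        sub = table.groupby("group")["value"]
        for r in res:
            diff = sub.mean()[r.level_a] - sub.mean()[r.level_b]
            se = np.sqrt(anova.mse * (1 / sub.count()[r.level_a]
                                      + 1 / sub.count()[r.level_b]))
            t = diff / se
            p = 2 * sps.t.sf(abs(t), anova.residual_df)
            assert r.t == pytest.approx(t, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)
            assert r.df == anova.residual_df

    def test_unprotected_when_omnibus_ns(self, rng):
        cells = {(a, b): list(rng.normal(10, 3, 6)) for a in "XY" for b in "PQR"}
        table = long_table(cells)
        anova = st.factorial_anova(table)
        factor = "group"
        if anova.effects[factor].p > 0.5:  # null data: omnibus far from alpha
            res = st.fisher_lsd(table, anova, factor, alpha=0.05)
            assert all(not r.protected for r in res)

    def test_unknown_level_rejected(self):
        table = self._three_group_table()
        anova = st.factorial_anova(table)
        with pytest.raises(UnknownLevelError):
            st.fisher_lsd(table, anova, "group", levels=["P", "ZZZ"])


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = st.paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_zero_mean_difference(self):
        x = np.array([2.0, 1.0, 2.0, 1.0])
        y = np.array([1.0, 2.0, 1.0, 2.0])
        t, _, _ = st.paired_t(x, y)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_formula(self):
        d = np.array([2.0, 3.0, 5.0, 4.0, 1.0])
        t, df, p = st.paired_t(d, np.zeros_like(d))
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 4), abs=1e-12)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(PairingError):
            st.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = st.pearson_r(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        r, _ = st.pearson_r(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        r, p = st.pearson_r(x, y)
        expected = (np.cov(x, y, ddof=1)[0, 1]
                    / (np.std(x, ddof=1) * np.std(y, ddof=1)))
        assert r == pytest.approx(expected, abs=1e-12)
        t = expected * np.sqrt(8 / (1 - expected**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 8), abs=1e-12)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestUnityDeviation:
    def test_all_on_line(self):
        x = np.array([10.0, 50.0, 90.0])
        res = st.unity_deviation(x, x)
        assert np.all(res.deviations == 0.0)
        assert res.n_below == res.n_above == 0
        assert np.isnan(res.sign_test_p)

    def test_single_point_below(self):
        res = st.unity_deviation([80.0], [20.0])
        assert res.deviations[0] == pytest.approx(-60.0)
        assert res.n_below == 1 and res.fraction_below == 1.0

    def test_eight_of_eight_below_exact_binomial(self):
        x = np.full(8, 80.0)
        y = np.full(8, 20.0)
        res = st.unity_deviation(x, y)
        assert res.sign_test_p == pytest.approx(2 * 0.5**8, abs=0)
        assert res.sign_test_p == 0.0078125

    @settings(max_examples=60, derandomize=True)
    @given(hst.lists(
        hst.tuples(hst.floats(0, 100), hst.floats(0, 100)),
        min_size=1, max_size=30))
    def test_sign_test_exchange_symmetric(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        pa = st.unity_deviation(x, y).sign_test_p
        pb = st.unity_deviation(y, x).sign_test_p
        assert (np.isnan(pa) and np.isnan(pb)) or pa == pytest.approx(pb, abs=1e-15)


class TestCohortLong:
    def test_melt_shape_and_values(self):
        cohort = ph.generate_cohort(ph.CohortSpec.default_study(), seed=1)
        long = st.cohort_to_long(cohort)
        assert len(long) == 3 * len(cohort)
        row = cohort.iloc[0]
        got = long[(long.projection_id == row.projection_id)
                   & (long.label == "CTB")].value.iloc[0]
        assert got == row.ctb_intact_pct
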