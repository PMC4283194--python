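"""Test-retest statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cb1tacs.reliability import (ICC_GOOD_THRESHOLD, between_subject_cv,
                                 bland_altman, build_reliability_table,
                                 heterogeneity_ratio, icc_oneway,
                                 interval_correlation, percent_diff)


def icc_anova_oracle(values):
    """Brute-force one-way ANOVA ICC(1,1) with explicit loops."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_bs = 0.0
    ss_ws = 0.0
    for i in range(n):
        m_i = sum(values[i]) / k
        ss_bs += k * (m_i - grand) ** 2
        for j in range(k):
            ss_ws += (values[i][j] - m_i) ** 2
    msbs = ss_bs / (n - 1)
    msws = ss_ws / (n * (k - 1))
    return (msbs - msws) / (msbs + (k - 1) * msws)


class TestPercentDiff:
    def test_equal_values_give_zero(self):
        assert percent_diff(5.0, 5.0) == 0.0

    def test_direct_formula(self):
        assert percent_diff(8.0, 12.0) == pytest.approx(40.0)

    def test_zero_sum_is_nan(self):
        assert np.isnan(percent_diff(1.0, -1.0))

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_bounds_for_positive_pairs(self, a, b):
        d = percent_diff(a, b)
        assert d == pytest.approx(-percent_diff(b, a), rel=1e-12, abs=1e-12)
        assert -200.0 < d < 200.0


class TestICC:
    def test_perfect_repeatability(self):
        v = np.array([[10.0, 10.0], [12.0, 12.0], [8.0, 8.0], [14.0, 14.0]])
        assert icc_oneway(v).icc == pytest.approx(1.0)

    def test_matches_anova_oracle_on_worked_example(self):
        v = np.array([[10, 11], [12, 12], [8, 9], [14, 13], [9, 10.0]])
        assert icc_oneway(v).icc == pytest.approx(icc_anova_oracle(v),
                                                  abs=1e-12)

    def test_matches_anova_oracle_on_1000_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 20))
            v = rng.normal(10, 3, size=(n, 2))
            assert icc_oneway(v).icc == pytest.approx(icc_anova_oracle(v),
                                                      abs=1e-12)

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        v = rng.normal(10, 3, size=(12, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["a", "b"], 12),
            "y": v.ravel()})
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="y")
        icc1 = float(ref.loc[ref.Type == "ICC(1,1)", "ICC"].iloc[0])
        assert icc_oneway(v).icc == pytest.approx(icc1, abs=1e-9)

    def test_printed_denominator_variant(self):
        v = np.array([[10, 11], [12, 12], [8, 9], [14, 13], [9, 10.0]])
        r = icc_oneway(v, denominator="printed")
        expected = (r.msbs - r.msws) / (r.msbs + r.df_ws * r.msws)
        assert r.icc == pytest.approx(expected)
        assert r.icc < icc_oneway(v).icc  # heavier denominator

    @given(arrays(float, (6, 2), elements=st.floats(-100, 100)),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, v, a, b):
        try:
            base = icc_oneway(v).icc
            transformed = icc_oneway(a * v + b).icc
        except ValueError:
            return  # (numerically) zero-variance draw
        assert transformed == pytest.approx(base, rel=1e-6, abs=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            icc_oneway(np.array([[1.0, 2.0], [3.0, 4.0]]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_oneway(np.full((5, 2), 3.0))

    def test_nan_rows_dropped_pairwise(self):
        v = np.array([[10, 11], [np.nan, 12], [8, 9], [14, 13], [9, 10.0]])
        kept = np.array([[10, 11], [8, 9], [14, 13], [9, 10.0]])
        assert icc_oneway(v).icc == pytest.approx(icc_anova_oracle(kept))
        assert icc_oneway(v).n == 4

    def test_good_reliability_threshold_constant(self):
        assert ICC_GOOD_THRESHOLD == 0.75


class TestBSCV:
    def test_identical_subjects_give_zero(self):
        v = np.full((5, 2), 7.0)
        assert between_subject_cv(v) == 0.0

    def test_hand_computed_example(self):
        v = np.array([[8.0, 8.0], [10.0, 10.0], [12.0, 12.0]])
        assert between_subject_cv(v) == pytest.approx(20.0)

    def test_nonpositive_mean_gives_nan(self):
        v = np.array([[-1.0, -1.0], [-2.0, -2.0], [1.0, 1.0]])
        assert np.isnan(between_subject_cv(v))

    def test_per_session_mode(self):
        v = np.array([[8.0, 16.0], [10.0, 20.0], [12.0, 24.0]])
        # each session has CV 20%, averaged 20%
        assert between_subject_cv(v, mode="per_session") == pytest.approx(20.0)


class TestBlandAltman:
    def test_identical_methods(self):
        r = bland_altman([3.0, 4.0], [3.0, 4.0])
        assert np.all(r.difference == 0.0)
        assert r.bias == 0.0

    def test_hand_computed_points(self):
        r = bland_altman([10.0, 12.0], [8.0, 12.0])
        assert np.allclose(r.mean, [9.0, 12.0])
        assert np.allclose(r.difference, [2.0, 0.0])
        assert r.bias == pytest.approx(1.0)
        assert r.loa_high - r.loa_low == pytest.approx(2 * 1.96 * np.sqrt(2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0, 2.0])


class TestHeterogeneityAndInterval:
    def test_identical_regions_ratio_one(self):
        vals = {"pallidum": np.array([3.0, 4.0]), "pons": np.array([3.0, 4.0])}
        assert heterogeneity_ratio(vals) == pytest.approx(1.0)

    def test_missing_region_rejected(self):
        with pytest.raises(KeyError):
            heterogeneity_ratio({"pallidum": np.array([1.0])})

    def test_monotone_diff_gives_perfect_rho(self):
        rho, p, p_adj = interval_correlation([1, 2, 3, 4, 5.0],
                                             [10, 20, 30, 40, 50.0])
        assert rho == pytest.approx(1.0)
        assert p_adj == pytest.approx(min(1.0, p * 8))


class TestReliabilityTable:
    def _cohort_frame(self, n=6, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            base = {"pallidum": 10.8, "pons": 3.0}
            g = rng.lognormal(0, 0.3)
            for session in ("test", "retest"):
                h = rng.lognormal(0, jitter) if jitter else 1.0
                for region, v in base.items():
                    rows.append(dict(subject_id=f"s{s}", session=session,
                                     region_id=region, value=v * g * h))
        return pd.DataFrame(rows)

    def test_zero_within_variance_gives_perfect_table(self):
        tab = build_reliability_table(self._cohort_frame(jitter=0.0))
        assert np.allclose(tab.table["icc"], 1.0)
        assert np.allclose(tab.table["median_pdiff"], 0.0)
        assert tab.ratio == pytest.approx(3.6)

    def test_exclusions_counted(self):
        df = self._cohort_frame(jitter=0.05)
        df.loc[(df.subject_id == "s0") & (df.region_id == "pallidum")
               & (df.session == "test"), "value"] = np.nan
        tab = build_reliability_table(df)
        assert tab.table.loc["pallidum", "n_excluded"] == 1
        assert tab.table.loc["pons", "n_excluded"] == 0

    def test_footer_mean_sd_across_regions(self):
        tab = build_reliability_table(self._cohort_frame(jitter=0.1, seed=3))
        iccs = tab.table["icc"].to_numpy()
        assert tab.footer["mean_icc"] == pytest.approx(np.mean(iccs))
        assert tab.footer["sd_icc"] == pytest.approx(np.std(iccs, ddof=1))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            build_reliability_table(pd.DataFrame({"subject_id": []}))
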