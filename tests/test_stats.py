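"""Reliability/correlation statistics and printed-table regression."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cervikin import datasets
from cervikin.segments import ZeroVarianceError
from cervikin.stats import (
    cv_and_intraindividual_sd,
    icc_absolute_average,
    round_half_away,
    spearman_exact,
    summarize,
)


def _anova_icc_oracle(m: np.ndarray) -> float:
    """Independent ICC(A,k) oracle via pingouin's two-way ANOVA route."""
    import pingouin as pg

    n, k = m.shape
    df = pd.DataFrame({
        "t": np.repeat(np.arange(n), k),
        "r": np.tile(np.arange(k), n),
        "s": m.ravel(),
    })
    icc = pg.intraclass_corr(df, targets="t", raters="r", ratings="s")
    return float(icc.loc[icc["Type"] == "ICC(A,k)", "ICC"].iloc[0])


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        assert icc_absolute_average(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_20_seeded_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, k = int(rng.integers(3, 10)), int(rng.integers(2, 5))
            m = rng.normal(10, 3, (n, k)) + rng.normal(0, 1.5, (n, 1))
            assert icc_absolute_average(m) == pytest.approx(_anova_icc_oracle(m), abs=1e-9)

    def test_no_agreement_is_near_zero(self):
        rng = np.random.default_rng(1)
        vals = np.abs(icc_absolute_average(rng.normal(0, 5, (40, 2))) )
        assert vals < 0.5  # independent columns: no reliability

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            icc_absolute_average(np.full((4, 2), 3.0))

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            icc_absolute_average(m)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman_exact([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        x = np.arange(5.0)
        assert spearman_exact(x, -x).rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.5]
        res = spearman_exact(x, y)
        assert res.method == "exact"
        rho_obs = sps.spearmanr(x, y).statistic
        count = 0
        perms = list(permutations(y))
        for p in perms:
            if abs(sps.spearmanr(x, p).statistic) >= abs(rho_obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / len(perms), abs=1e-12)
        assert res.rho == pytest.approx(rho_obs, abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 3.0, 5.0, 8.0]
        assert spearman_exact(x, y).rho == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_monte_carlo_branch_reproducible(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = spearman_exact(x, y, seed=9)
        b = spearman_exact(x, y, seed=9)
        assert a.method == "monte-carlo"
        assert a.p == b.p
        # sanity: MC p close to the asymptotic p for moderate n
        assert a.p == pytest.approx(sps.spearmanr(x, y).pvalue, abs=0.08)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=7, unique=True))
    def test_rho_invariant_under_monotone_transform(self, xi):
        x = np.asarray(xi, dtype=float)
        rng = np.random.default_rng(0)
        y = rng.permutation(len(x)).astype(float)
        base = spearman_exact(x, y)
        warped = spearman_exact(np.exp(x / 500.0), y)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p == pytest.approx(base.p, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            spearman_exact([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestCV:
    def test_identical_sessions_zero(self):
        sd, cv = cv_and_intraindividual_sd([5.0, 7.0], [5.0, 7.0])
        assert np.allclose(sd, 0) and np.allclose(cv, 0)

    def test_closed_form_pair(self):
        sd, cv = cv_and_intraindividual_sd([20.0], [10.0])
        assert sd[0] == pytest.approx(10.0 / math.sqrt(2.0), abs=1e-12)
        assert cv[0] == pytest.approx((10.0 / math.sqrt(2.0)) / 15.0, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroVarianceError):
            cv_and_intraindividual_sd([1.0, -3.0], [2.0, 3.0])


class TestSummarize:
    def test_single_value(self):
        row = summarize([4.2])
        assert row.mean == row.min == row.max == 4.2

    def test_half_away_rounding(self):
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(-0.25, 1) == -0.3
        assert round_half_away(61.5, 0) == 62.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12))
    def test_permutation_invariant(self, values):
        rng = np.random.default_rng(1)
        shuffled = list(rng.permutation(values))
        a, b = summarize(values), summarize(shuffled)
        assert (a.mean, a.min, a.max) == (b.mean, b.min, b.max)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


# printed column means (one decimal; age and NDI integer); the two cells whose
# printed averages conflict with their own columns are excluded below
PRINTED_ROM_MEANS = {
    ("T1", "trom"): 25.8, ("T1", "srom_c4c5"): 11.1, ("T1", "srom_c5c6"): 7.9,
    ("T2", "trom"): 22.3, ("T2", "srom_c4c5"): 9.3, ("T2", "srom_c5c6"): 7.1,
    ("T2", "srom_c6c7"): 5.9,
}
PRINTED_EXTERNAL_MEANS = {
    ("T1", "trom"): 10.0, ("T1", "srom_c4c5"): 4.6, ("T1", "srom_c5c6"): 2.6,
    ("T1", "srom_c6c7"): 2.8,
    ("T2", "trom"): 11.8, ("T2", "srom_c4c5"): 4.8, ("T2", "srom_c5c6"): 4.3,
}


class TestTableRegression:
    def test_rom_column_means_match_printed(self):
        df = datasets.load_rom()
        for (tp, col), printed in PRINTED_ROM_MEANS.items():
            mean = summarize(df[df["timepoint"] == tp][col]).mean
            assert mean == pytest.approx(printed, abs=0.051), (tp, col)

    def test_external_column_means_match_printed(self):
        df = datasets.load_external()
        for (tp, col), printed in PRINTED_EXTERNAL_MEANS.items():
            mean = summarize(df[df["timepoint"] == tp][col]).mean
            assert mean == pytest.approx(printed, abs=0.051), (tp, col)

    def test_baseline_means_match_printed(self):
        df = datasets.load_baseline()
        assert summarize(df["age"], 0).mean == pytest.approx(61)
        assert summarize(df["ndi_points"], 0).mean == pytest.approx(1)
        assert summarize(df["ks_c4c5"]).mean == pytest.approx(1.5)
        assert summarize(df["ks_c5c6"]).mean == pytest.approx(1.5)
        assert summarize(df["ks_c6c7"]).mean == pytest.approx(1.8)
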