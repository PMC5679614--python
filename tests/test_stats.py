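"""Cohort-statistics tests against independent oracles: brute-force BH
step-up, residualize-then-correlate partial correlations (and pingouin),
and reduction of the ANCOVA to a two-sample t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from r2tstar.stats import (
    BatteryConfig,
    ancova_compare,
    bh_fdr,
    partial_pearson,
    partial_spearman,
    run_correlation_battery,
)
from r2tstar.synthetic import CohortSpec, make_cohort


def bh_oracle(p):
    """Brute-force step-up: q(i) = min_{j>=i} min(1, p(j) m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        cands = [min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_pos, m)]
        q[idx] = min(cands)
    return q


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.03, 0.04]), [0.015, 0.04, 0.04], rtol=1e-12
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.05] * 10), [0.05] * 10, rtol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=25)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), ref, rtol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=80, deadline=None)
    def test_monotone_and_dominating(self, p):
        q = bh_fdr(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def partial_oracle(x, y, cov):
    """Two-stage OLS oracle: residualize each variable on [1, cov] with an
    independent solver, then plain Pearson on residuals."""
    import numpy.linalg as la

    X = np.column_stack([np.ones(len(x)), cov])
    bx = la.solve(X.T @ X, X.T @ x)
    by = la.solve(X.T @ X, X.T @ y)
    return sps.pearsonr(x - X @ bx, y - X @ by)[0]


class TestPartialPearson:
    def test_no_covariates_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 30))
        res = partial_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, rel=1e-10)
        assert res.df == 28

    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        cov = rng.normal(size=(20, 2))
        res = partial_pearson(x, x.copy(), cov)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_worked_dataset_matches_oracle(self, worked_dataset):
        x, y, cov = worked_dataset
        res = partial_pearson(x, y, cov)
        assert res.r == pytest.approx(partial_oracle(x, y, cov), abs=1e-12)
        assert res.df == 8 - 2 - 2

    def test_matches_pingouin(self, worked_dataset):
        pingouin = pytest.importorskip("pingouin")
        x, y, cov = worked_dataset
        df = pd.DataFrame(dict(x=x, y=y, c1=cov[:, 0], c2=cov[:, 1]))
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = partial_pearson(x, y, cov)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_affine_invariance(self, worked_dataset):
        x, y, cov = worked_dataset
        base = partial_pearson(x, y, cov)
        scaled = partial_pearson(3.0 * x - 7.0, 0.5 * y + 2.0,
                                 np.column_stack([2 * cov[:, 0] + 1, cov[:, 1]]))
        assert scaled.r == pytest.approx(base.r, abs=1e-12)

    def test_collinear_covariates_named(self):
        x = np.arange(10.0)
        y = np.arange(10.0)[::-1]
        cov = np.column_stack([np.ones(10), 2 * np.ones(10)])
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_pearson(x, y, cov)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_pearson(np.ones(4), np.ones(4), np.eye(4)[:, :2])


class TestPartialSpearman:
    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=25)
        res = partial_spearman(x, np.exp(x))
        assert res.r == pytest.approx(1.0)

    def test_tie_handling_average_ranks(self):
        assert list(sps.rankdata([1, 2, 2, 3])) == [1.0, 2.5, 2.5, 4.0]
        res = partial_spearman([1, 2, 2, 3, 5, 8], [2, 3, 3, 4, 9, 11])
        ref = sps.spearmanr([1, 2, 2, 3, 5, 8], [2, 3, 3, 4, 9, 11])[0]
        assert res.r == pytest.approx(ref, abs=1e-12)

    def test_worked_dataset_matches_rank_oracle(self, worked_dataset):
        x, y, cov = worked_dataset
        res = partial_spearman(x, y, cov)
        ref = partial_oracle(sps.rankdata(x), sps.rankdata(y), cov)
        assert res.r == pytest.approx(ref, abs=1e-12)

    def test_invariance_to_monotone_transforms(self, worked_dataset):
        x, y, cov = worked_dataset
        a = partial_spearman(x, y, cov)
        b = partial_spearman(np.exp(x / 4), y**3, cov)
        assert b.r == pytest.approx(a.r, abs=1e-12)


class TestAncovaCompare:
    def test_covariate_free_reduces_to_t_test(self, rng):
        """Balanced two-group design without covariates: the group contrast
        equals the two-sample (pooled) t-test."""
        a = rng.normal(10, 1, 20)
        b = rng.normal(11, 1, 20)
        values = np.concatenate([a, b])
        group = ["HC"] * 20 + ["RRMS"] * 20
        res = ancova_compare(values, group)
        t_ref, p_ref = sps.ttest_ind(b, a)
        row = res.contrasts.iloc[0]
        assert row.statistic == pytest.approx(t_ref, rel=1e-10)
        assert row.p_raw == pytest.approx(p_ref, rel=1e-10)

    def test_injected_shift_recovered(self, rng):
        n = 60
        age = rng.uniform(25, 75, n)
        gender = rng.choice(["F", "M"], n)
        group = np.array(["HC"] * 30 + ["SPMS"] * 30)
        values = 17.0 - 0.03 * age + 0.2 * (gender == "M") + rng.normal(0, 0.5, n)
        values[group == "SPMS"] -= 1.0
        res = ancova_compare(values, group, age, gender)
        row = res.contrasts[res.contrasts.contrast == "SPMS-HC"].iloc[0]
        se = 0.5 * np.sqrt(4 / 30)
        assert row.estimate == pytest.approx(-1.0, abs=3 * se)
        assert res.p_omnibus < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="< 3"):
            ancova_compare(
                np.arange(6.0), ["HC", "HC", "HC", "HC", "RRMS", "RRMS"],
                np.arange(6.0), ["F"] * 6,
            )


@pytest.fixture(scope="module")
def cohort_truth():
    return make_cohort(CohortSpec(seed=20260930))


class TestCorrelationBattery:

    def test_designed_correlation_recovered(self, cohort_truth):
        cohort, truth = cohort_truth
        out = run_correlation_battery(truth, cohort)
        cell = out[(out.test_name == "SDMT_z") & (out.region_name == "hippocampus")
                   & (out.hemisphere == "left") & (out.measure == "R2t*")].iloc[0]
        # designed partial rho = 0.4 at n = 80: sampling sd ~ 0.1
        assert cell.estimate == pytest.approx(0.4, abs=0.25)
        assert cell.n == 80

    def test_left_handers_excluded_from_peg_test_only(self, cohort_truth):
        cohort, truth = cohort_truth
        out = run_correlation_battery(truth, cohort)
        n_right = (cohort[cohort.group != "HC"].handedness == "right").sum()
        peg = out[out.test_name == "9HPT"]
        other = out[out.test_name == "EDSS"]
        assert peg.n.max() <= n_right
        assert other.n.max() == 80

    def test_peg_test_lateralization(self, cohort_truth):
        """Dominant-hand times pair with left-hemisphere measures; the left
        and right cells therefore use different score columns."""
        cohort, truth = cohort_truth
        out = run_correlation_battery(truth, cohort)
        lh = out[(out.test_name == "9HPT") & (out.hemisphere == "left")
                 & (out.region_name == "hippocampus") & (out.measure == "R2t*")].iloc[0]
        rh = out[(out.test_name == "9HPT") & (out.hemisphere == "right")
                 & (out.region_name == "hippocampus") & (out.measure == "R2t*")].iloc[0]
        assert lh.estimate != rh.estimate

    def test_fdr_applied_once_per_family(self, cohort_truth):
        cohort, truth = cohort_truth
        out = run_correlation_battery(truth, cohort)
        fam = out[(out.measure == "R2t*") & (out.method == "partial_pearson")]
        ok = fam.p_raw.notna()
        np.testing.assert_allclose(
            fam.loc[ok, "p_fdr"].to_numpy(),
            bh_fdr(fam.loc[ok, "p_raw"].to_numpy()),
            rtol=1e-12,
        )

    def test_missing_covariate_column_reported(self, cohort_truth):
        cohort, truth = cohort_truth
        with pytest.raises(ValueError, match="lesion_load"):
            run_correlation_battery(truth, cohort.drop(columns=["lesion_load"]))

    def test_hc_excluded_by_default(self, cohort_truth):
        cohort, truth = cohort_truth
        out = run_correlation_battery(truth, cohort)
        assert out.n.max() <= 80
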