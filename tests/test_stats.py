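"""Group statistics: percent change, asymmetry, FDR, ANCOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fetalsp.stats import (ai_change_ztest, ancova, assign_trimester_group,
                           asymmetry_index, bh_fdr, homotopic_growth_ztest,
                           lateralization_test, paired_homotopic_test,
                           percent_change)
from fetalsp.cohort import planted_variance_dataset


# ------------------------------------------------------------- grouping

@pytest.mark.parametrize("ga,expected", [
    (22.0, "late2"), (27.0, "late2"), (27.1, "early3"), (32.0, "early3"),
])
def test_trimester_boundary(ga, expected):
    assert assign_trimester_group(ga) == expected


def test_trimester_out_of_range_rejected():
    with pytest.raises(ValueError):
        assign_trimester_group([21.0])


# ------------------------------------------------------------- percent change

def test_percent_change_of_known_means():
    pc = percent_change(np.full(10, 100.0) + np.arange(10) * 1e-9,
                        np.full(12, 150.0) + np.arange(12) * 1e-9)
    assert pc.pc == pytest.approx(50.0, abs=1e-6)


def test_percent_change_equal_groups_is_zero_with_covering_ci(rng):
    v = rng.normal(50.0, 5.0, 30)
    pc = percent_change(v, v)
    assert pc.pc == 0.0
    assert pc.ci95[0] < 0.0 < pc.ci95[1]


def test_nonpositive_baseline_flagged():
    pc = percent_change(np.array([-1.0, 0.5, 0.2]), np.ones(5))
    assert not pc.defined and np.isnan(pc.pc)


def test_delta_method_se_matches_parametric_bootstrap(rng):
    m1, s1, n1 = 100.0, 2.0 * np.sqrt(29), 29
    m2, s2, n2 = 150.0, 3.0 * np.sqrt(39), 39
    draws1 = rng.normal(m1, s1 / np.sqrt(n1), 100_000)
    draws2 = rng.normal(m2, s2 / np.sqrt(n2), 100_000)
    boot_sd = np.std(100.0 * (draws2 - draws1) / draws1)
    se1, se2 = s1 / np.sqrt(n1), s2 / np.sqrt(n2)
    delta = np.sqrt((100.0 / m1) ** 2 * (se2**2 + se1**2 * (m2 / m1) ** 2))
    assert delta == pytest.approx(boot_sd, rel=0.05)


def _pc(pc_val, se, region="r", metric="m", hemi="L"):
    from fetalsp.stats import PercentChange
    return PercentChange(region, hemi, metric, pc_val, se,
                         (pc_val - 1.96 * se, pc_val + 1.96 * se), (10, 10))


def test_homotopic_ztest_arithmetic_and_antisymmetry():
    z, p = homotopic_growth_ztest(_pc(40.0, 3.0), _pc(50.0, 4.0, hemi="R"))
    assert z == pytest.approx(2.0)           # 10 / sqrt(9 + 16)
    z2, _ = homotopic_growth_ztest(_pc(50.0, 4.0), _pc(40.0, 3.0, hemi="R"))
    assert z2 == pytest.approx(-z)
    z0, p0 = homotopic_growth_ztest(_pc(40.0, 3.0), _pc(40.0, 3.0, hemi="R"))
    assert z0 == 0.0 and p0 == pytest.approx(1.0)


# ------------------------------------------------------------- asymmetry

@pytest.mark.parametrize("left,right,expected", [
    (100.0, 100.0, 0.0),
    (90.0, 110.0, 20.0),
    (110.0, 90.0, -20.0),
    (1.0, 2.0, 200.0 / 3.0),
])
def test_asymmetry_index_known_values(left, right, expected):
    assert asymmetry_index(left, right) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
def test_asymmetry_index_bounded_and_antisymmetric(left, right):
    ai = asymmetry_index(left, right)
    assert -200.0 <= ai <= 200.0
    assert asymmetry_index(right, left) == pytest.approx(-ai, abs=1e-9)


def test_asymmetry_index_undefined_for_nonpositive_sum():
    assert np.isnan(asymmetry_index(0.0, 0.0))


def test_lateralization_all_zero_is_degenerate_null():
    res = lateralization_test(np.zeros(20))
    assert res.t_stat == 0.0 and res.p == 1.0 and res.degenerate


def test_lateralization_power_for_planted_effect(rng):
    rejections = sum(
        lateralization_test(rng.normal(20.0, 10.0, 30)).p < 0.05
        for _ in range(300))
    assert rejections / 300 >= 0.99


def test_paired_test_equals_one_sample_on_differences(rng):
    left = rng.normal(10, 2, 25)
    right = left + rng.normal(0.5, 1.0, 25)
    t, p, d = paired_homotopic_test(left, right)
    t_ref, p_ref = sps.ttest_1samp(right - left, 0.0)
    assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
    diff = right - left
    assert d == pytest.approx(diff.mean() / diff.std(ddof=1))


def test_paired_identical_sides_degenerate_zero():
    t, p, d = paired_homotopic_test(np.arange(10.0), np.arange(10.0))
    assert t == 0.0 and p == 1.0


def test_ai_change_ztest_hand_arithmetic():
    a1 = np.array([0.0, 2.0, 4.0] * 10)       # mean 2
    a2 = np.array([5.0, 7.0, 9.0] * 10)       # mean 7
    delta, z, p = ai_change_ztest(a1, a2)
    se1 = a1.std(ddof=1) / np.sqrt(a1.size)
    se2 = a2.std(ddof=1) / np.sqrt(a2.size)
    assert delta == pytest.approx(5.0)
    assert z == pytest.approx(5.0 / np.hypot(se1, se2))
    identical = ai_change_ztest(a1, a1)
    assert identical[0] == 0.0 and identical[1] == 0.0


# ------------------------------------------------------------- BH FDR

def _brute_force_bh(p, alpha):
    """Literal step-up: largest k with p_(k) <= k*alpha/m; reject those."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    rejected = np.zeros(m, bool)
    rejected[order[:k_star]] = True
    return rejected


@settings(derandomize=True, max_examples=300)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
       st.sampled_from([0.01, 0.05, 0.1]))
def test_bh_matches_brute_force_step_up(pvals, alpha):
    q, rejected = bh_fdr(pvals, alpha=alpha)
    np.testing.assert_array_equal(rejected, _brute_force_bh(pvals, alpha))
    # q-values are monotone in p
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_known_cases():
    q, rej = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.05)
    assert rej.all()
    _, rej = bh_fdr([1.0, 1.0, 1.0])
    assert not rej.any()
    _, rej = bh_fdr([0.04])
    assert rej.all()


def test_bh_rejects_bad_pvalues():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_fdr_controls_family_error_under_null(rng):
    any_false = 0
    for _ in range(500):
        p = rng.uniform(size=17)
        _, rej = bh_fdr(p, alpha=0.05)
        any_false += rej.any()
    # BH controls FDR (= FWER under the global null) at alpha
    assert any_false / 500 <= 0.05 + 2.0 * np.sqrt(0.05 * 0.95 / 500)


# ------------------------------------------------------------- ANCOVA

def test_ancova_recovers_planted_variance_fraction():
    df = planted_variance_dataset(n=200, ga_fraction=0.8, seed=4)
    res = ancova(df, response="y", covariates=["ga_weeks"])
    assert res.table.loc["ga_weeks", "partial_eta_sq"] == pytest.approx(0.8, abs=1e-9)


def test_ancova_balanced_two_factor_matches_projection_oracle(rng):
    # balanced orthogonal 2x2 design: effect-coded SS are squared
    # projections onto the (orthogonal) contrast columns
    a = np.repeat([1.0, 1.0, -1.0, -1.0], 10)
    b = np.tile(np.repeat([1.0, -1.0], 10), 2)
    y = 2.0 + 1.5 * a - 0.8 * b + 0.5 * a * b + rng.normal(0, 1.0, 40)
    df = pd.DataFrame({"y": y,
                       "A": np.where(a > 0, "a1", "a2"),
                       "B": np.where(b > 0, "b1", "b2")})
    res = ancova(df, response="y", factors=["A", "B"],
                 interactions=[("A", "B")])
    for name, col in [("A", a), ("B", b), ("A:B", a * b)]:
        ss_oracle = (y @ col) ** 2 / (col @ col)
        assert res.table.loc[name, "sum_sq"] == pytest.approx(ss_oracle)


def test_ancova_null_f_test_level(rng):
    rejections = 0
    for _ in range(400):
        df = pd.DataFrame({"ga_weeks": rng.uniform(22, 32, 50),
                           "y": rng.normal(size=50)})
        res = ancova(df, response="y", covariates=["ga_weeks"])
        rejections += res.table.loc["ga_weeks", "p"] < 0.05
    assert abs(rejections / 400 - 0.05) < 0.03


def test_ancova_missing_sex_dropped():
    df = planted_variance_dataset(n=100, seed=0)
    df.loc[:9, "sex"] = None
    res = ancova(df, response="y", covariates=["ga_weeks"], factors=["sex"])
    assert "sex" in res.table.index


def test_ancova_rank_deficiency_rejected():
    df = planted_variance_dataset(n=50, seed=1)
    df["ga_copy"] = df["ga_weeks"]
    with pytest.raises(ValueError, match="rank"):
        ancova(df, response="y", covariates=["ga_weeks", "ga_copy"])


def test_repeated_measures_strata_and_effect_detection(rng):
    # two regions with different GA slopes nested in subjects
    n = 60
    ga = rng.uniform(22, 32, n)
    rows = []
    for i in range(n):
        base = rng.normal(0, 0.2)
        for region, slope in (("r1", 1.0), ("r2", 1.6)):
            rows.append(dict(subject=f"s{i}", region=region,
                             ga_weeks=ga[i],
                             y=slope * (ga[i] - 27.0) + base
                             + rng.normal(0, 0.1)))
    df = pd.DataFrame(rows)
    res = ancova(df, response="y", covariates=["ga_weeks"],
                 factors=["region"], subject="subject", within=["region"],
                 interactions=[("region", "ga_weeks")])
    assert res.stratum["ga_weeks"] == "between"
    assert res.stratum["region:ga_weeks"] == "within"
    assert res.table.loc["region:ga_weeks", "p"] < 1e-6
    assert 0.0 <= res.table["partial_eta_sq"].max() <= 1.0
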